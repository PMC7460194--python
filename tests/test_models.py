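"""Model assembly, predictor algebra, and Gibbs sampler correctness."""

import dataclasses

import numpy as np
import pytest

import stvcpanel as sp
from stvcpanel.models import block_full_conditional


def make_panel(y, X, time_invariant=None):
    y = np.asarray(y, dtype=float)
    I, T = y.shape
    P = np.shape(X)[2]
    return sp.PanelData(
        area_ids=tuple(f"a{i}" for i in range(I)),
        years=tuple(range(2000, 2000 + T)),
        y=y,
        X=np.asarray(X, dtype=float),
        covariate_names=tuple(f"X{p + 1}" for p in range(P)),
        block_labels=tuple(["SE"] * P),
        time_invariant=time_invariant,
        log_response=True,
    )


def line_graph(I):
    return sp.graph_from_edges(
        [f"a{i}" for i in range(I)], [(i, i + 1) for i in range(I - 1)]
    )


class TestModelSpec:
    def test_model1_blocks(self):
        rng = np.random.default_rng(0)
        panel = make_panel(rng.normal(size=(4, 3)), rng.normal(size=(4, 3, 10)))
        design = sp.build_model(sp.ModelSpec.for_model(1, panel), panel, line_graph(4))
        kinds = [b.kind for b in design.blocks]
        assert kinds.count("global-intercept") == 1
        assert kinds.count("global-slope") == 10
        assert not any(b.gmrf for b in design.blocks)

    def test_model2_adds_si_ti(self):
        rng = np.random.default_rng(0)
        panel = make_panel(rng.normal(size=(4, 3)), rng.normal(size=(4, 3, 2)))
        design = sp.build_model(sp.ModelSpec.for_model(2, panel), panel, line_graph(4))
        kinds = [b.kind for b in design.blocks]
        assert kinds == ["global-intercept"] + ["global-slope"] * 2 + ["SI", "TI"]

    def test_model5_block_structure_with_time_invariant(self):
        """10 covariates of which 2 time-invariant: 10 SC + 8 TC + intercept."""
        rng = np.random.default_rng(1)
        X = rng.normal(size=(6, 4, 10))
        X[:, :, 8] = X[:, :1, 8]  # make last two time-invariant
        X[:, :, 9] = X[:, :1, 9]
        ti = np.array([False] * 8 + [True, True])
        panel = make_panel(rng.normal(size=(6, 4)), X, time_invariant=ti)
        design = sp.build_model(sp.ModelSpec.for_model(5, panel), panel, line_graph(6))
        kinds = [b.kind for b in design.blocks]
        assert kinds.count("SC") == 10 and kinds.count("TC") == 8
        assert kinds.count("global-intercept") == 1 and kinds.count("global-slope") == 0

    def test_tc_for_time_invariant_covariate_rejected(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(4, 3, 1))
        X[:, :, 0] = X[:, :1, 0]
        panel = make_panel(rng.normal(size=(4, 3)), X, time_invariant=np.array([True]))
        spec = sp.ModelSpec(
            model_id=3, include_global_slopes=False, include_si=False,
            include_ti=False, sc_covariates=(), tc_covariates=("X1",),
        )
        with pytest.raises(ValueError, match="time-invariant"):
            sp.build_model(spec, panel, line_graph(4))

    def test_raw_panel_rejected(self):
        rng = np.random.default_rng(3)
        panel = make_panel(rng.normal(size=(4, 3)), rng.normal(size=(4, 3, 1)))
        panel = dataclasses.replace(panel, y=np.exp(panel.y), log_response=False)
        with pytest.raises(ValueError, match="preprocess"):
            sp.build_model(sp.ModelSpec.for_model(1, panel), panel, line_graph(4))

    def test_model3_constraint_scheme(self):
        """TC fields are centered only when a paired term can absorb the
        level: constrained in model 5 (SC pair), free in model 3."""
        rng = np.random.default_rng(4)
        panel = make_panel(rng.normal(size=(5, 4)), rng.normal(size=(5, 4, 2)))
        g = line_graph(5)
        d3 = sp.build_model(sp.ModelSpec.for_model(3, panel), panel, g)
        d5 = sp.build_model(sp.ModelSpec.for_model(5, panel), panel, g)
        assert all(not b.constrained for b in d3.blocks if b.kind == "TC")
        assert all(b.constrained and b.absorb_into == f"sc:{b.covariate}"
                   for b in d5.blocks if b.kind == "TC")


class TestLinearPredictor:
    def test_intercept_only(self):
        rng = np.random.default_rng(0)
        panel = make_panel(rng.normal(size=(3, 2)), rng.normal(size=(3, 2, 1)))
        design = sp.build_model(sp.ModelSpec.for_model(4, panel), panel, line_graph(3))
        state = {"beta0": 2.0, "sc:X1": np.zeros(3)}
        np.testing.assert_allclose(sp.linear_predictor(design, state), 2.0)

    def test_single_sc_hand_arithmetic(self):
        panel = make_panel([[1.0], [1.0]], [[[3.0]], [[5.0]]])
        design = sp.build_model(
            sp.ModelSpec.for_model(4, panel), panel, line_graph(2)
        )
        eta = sp.linear_predictor(design, {"beta0": 0.0, "sc:X1": np.array([1.0, -1.0])})
        np.testing.assert_allclose(eta, [[3.0], [-5.0]])

    def test_matches_dense_loop_oracle(self):
        rng = np.random.default_rng(7)
        I, T, P = 6, 5, 3
        X = rng.normal(size=(I, T, P))
        panel = make_panel(rng.normal(size=(I, T)), X)
        design = sp.build_model(sp.ModelSpec.for_model(5, panel), panel, line_graph(I))
        state = {"beta0": rng.normal()}
        for name in panel.covariate_names:
            state[f"sc:{name}"] = rng.normal(size=I)
            state[f"tc:{name}"] = rng.normal(size=T)
        eta = sp.linear_predictor(design, state)
        oracle = np.empty((I, T))
        for i in range(I):
            for t in range(T):
                v = state["beta0"]
                for p, name in enumerate(panel.covariate_names):
                    v += (state[f"sc:{name}"][i] + state[f"tc:{name}"][t]) * X[i, t, p]
                oracle[i, t] = v
        np.testing.assert_allclose(eta, oracle, atol=1e-12)

    def test_missing_block_rejected(self):
        rng = np.random.default_rng(8)
        panel = make_panel(rng.normal(size=(3, 2)), rng.normal(size=(3, 2, 1)))
        design = sp.build_model(sp.ModelSpec.for_model(4, panel), panel, line_graph(3))
        with pytest.raises(ValueError, match="missing block"):
            sp.linear_predictor(design, {"beta0": 0.0})


class TestFullConditionals:
    """Every Gibbs block on a 3-area x 2-year toy against dense joint
    Gaussian conditioning."""

    def _toy(self, model_id):
        rng = np.random.default_rng(5)
        panel = make_panel(np.exp(rng.normal(size=(3, 2))), rng.normal(size=(3, 2, 1)))
        panel = dataclasses.replace(panel, y=np.log(panel.y))
        graph = line_graph(3)
        design = sp.build_model(sp.ModelSpec.for_model(model_id, panel), panel, graph)
        state = {"beta0": 0.3}
        for b in design.blocks:
            if b.dim == 1 and b.kind == "global-slope":
                state[b.name] = -0.2
            elif b.dim > 1:
                state[b.name] = rng.normal(size=b.dim) * 0.5
        sigma2 = {"sigma2:obs": 0.4}
        for b in design.blocks:
            if b.gmrf is not None:
                sigma2[f"sigma2:{b.name}"] = 0.8
        return design, state, sigma2

    @pytest.mark.parametrize("model_id", [2, 5])
    def test_field_conditionals_match_joint_oracle(self, model_id):
        design, state, sigma2 = self._toy(model_id)
        panel = design.panel
        y = panel.y.reshape(-1)
        # dense joint: latent vector = concat of all blocks
        blocks = design.blocks
        dims = [b.dim for b in blocks]
        offsets = np.cumsum([0] + dims)
        Zcols = []
        for b in blocks:
            if b.dim == 1:
                from stvcpanel.models import _block_contribution

                Zcols.append(_block_contribution(design, b, 1.0).reshape(-1, 1))
            else:
                cols = []
                for j in range(b.dim):
                    e = np.zeros(b.dim)
                    e[j] = 1.0
                    from stvcpanel.models import _block_contribution

                    cols.append(_block_contribution(design, b, e).reshape(-1))
                Zcols.append(np.column_stack(cols))
        Z = np.hstack(Zcols)
        n_lat = Z.shape[1]
        Pjoint = Z.T @ Z / sigma2["sigma2:obs"]
        for k, b in enumerate(blocks):
            if b.gmrf is not None:
                sl = slice(offsets[k], offsets[k + 1])
                Pjoint[sl, sl] += b.gmrf.structure.toarray() / sigma2[f"sigma2:{b.name}"]
        bjoint = Z.T @ y / sigma2["sigma2:obs"]
        theta = np.concatenate(
            [np.atleast_1d(np.asarray(state[b.name], dtype=float)) for b in blocks]
        )
        eta = sp.linear_predictor(design, state)
        for k, b in enumerate(blocks):
            if b.gmrf is None:
                continue
            sl = slice(offsets[k], offsets[k + 1])
            P, rhs = block_full_conditional(design, b, state, sigma2, panel.y, eta)
            # joint conditioning: P_SS, b_S - P_S,rest theta_rest
            rest = np.setdiff1d(np.arange(n_lat), np.arange(offsets[k], offsets[k + 1]))
            P_expected = Pjoint[sl, sl]
            rhs_expected = bjoint[sl] - Pjoint[sl, :][:, rest] @ theta[rest]
            np.testing.assert_allclose(P, P_expected, atol=1e-8)
            np.testing.assert_allclose(rhs, rhs_expected, atol=1e-8)


class TestFitGibbs:
    def test_intercept_only_conjugate(self):
        rng = np.random.default_rng(9)
        y = rng.normal(3.0, 0.5, size=(10, 6))
        panel = make_panel(y, rng.normal(size=(10, 6, 1)))
        spec = sp.ModelSpec(
            model_id=1, include_global_slopes=False, include_si=False,
            include_ti=False, sc_covariates=(), tc_covariates=(),
        )
        design = sp.build_model(spec, panel, line_graph(10))
        fit = sp.fit_gibbs(design, sp.McmcConfig(chains=2, iterations=1000, burn_in=500, seed=0))
        b0 = fit.stacked("beta0")
        post_sd = y.std() / np.sqrt(y.size)
        assert b0.mean() == pytest.approx(y.mean(), abs=3 * post_sd)

    def test_model1_matches_ols(self):
        """Flat-prior model 1 posterior means sit on the least-squares fit."""
        rng = np.random.default_rng(10)
        I, T, P = 100, 5, 3
        X = rng.normal(size=(I, T, P))
        beta = np.array([2.0, -1.5, 1.0])
        y = 1.7 + X @ beta + rng.normal(0, 0.3, size=(I, T))
        panel = make_panel(y, X)
        design = sp.build_model(sp.ModelSpec.for_model(1, panel), panel, line_graph(I))
        fit = sp.fit_gibbs(design, sp.McmcConfig(chains=2, iterations=1500, burn_in=750, seed=3))
        Zd = np.column_stack([np.ones(I * T)] + [X[:, :, p].reshape(-1) for p in range(P)])
        ols = np.linalg.lstsq(Zd, y.reshape(-1), rcond=None)[0]
        post = np.array(
            [fit.stacked("beta0").mean()]
            + [fit.stacked(f"beta:X{p + 1}").mean() for p in range(P)]
        )
        np.testing.assert_allclose(post, ols, rtol=0.02)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(11)
        panel = make_panel(rng.normal(size=(6, 4)), rng.normal(size=(6, 4, 1)))
        design = sp.build_model(sp.ModelSpec.for_model(5, panel), panel, line_graph(6))
        cfg = sp.McmcConfig(chains=2, iterations=200, burn_in=100, seed=21)
        f1 = sp.fit_gibbs(design, cfg)
        f2 = sp.fit_gibbs(design, dataclasses.replace(cfg))
        for k in f1.draws:
            np.testing.assert_array_equal(f1.draws[k], f2.draws[k])

    def test_constrained_blocks_sum_to_zero_in_every_draw(self, stvc_fit):
        fit, pp, truth, graph = stvc_fit
        for b in fit.design.blocks:
            if b.constrained:
                sums = fit.stacked(b.name).sum(axis=1)
                np.testing.assert_allclose(sums, 0, atol=1e-8)

    def test_all_draws_finite(self, stvc_fit):
        fit = stvc_fit[0]
        for k, v in fit.draws.items():
            assert np.isfinite(v).all(), k

    def test_recovery_on_study_panel(self, stvc_fit):
        fit, pp, truth, graph = stvc_fit
        for name in pp.covariate_names:
            r_sc = np.corrcoef(
                fit.stacked(f"sc:{name}").mean(axis=0), truth.sc_fields[name]
            )[0, 1]
            assert r_sc > 0.6
        b0 = fit.stacked("beta0").mean()
        assert b0 == pytest.approx(truth.beta0, abs=0.1)

    def test_si_ti_fit_runs_and_centers(self):
        cfg = sp.GeneratorConfig(
            rows=5, cols=5, T=6, n_se=1, n_ex=1, n_time_invariant=0,
            si_scale=0.3, ti_scale=0.2, seed=17,
        )
        panel, truth = sp.generate_panel(cfg)
        pp = sp.preprocess(panel)
        g = sp.make_lattice_graph(5, 5)
        design = sp.build_model(sp.ModelSpec.for_model(2, pp), pp, g)
        fit = sp.fit_gibbs(design, sp.McmcConfig(chains=2, iterations=400, burn_in=200, seed=1))
        np.testing.assert_allclose(fit.stacked("si").sum(axis=1), 0, atol=1e-8)
        np.testing.assert_allclose(fit.stacked("ti").sum(axis=1), 0, atol=1e-8)


class TestIdentifiability:
    def test_centering_with_absorption_preserves_predictor(self):
        rng = np.random.default_rng(12)
        I, T = 5, 4
        panel = make_panel(rng.normal(size=(I, T)), rng.normal(size=(I, T, 2)))
        design = sp.build_model(sp.ModelSpec.for_model(5, panel), panel, line_graph(I))
        state = {"beta0": 1.0}
        for name in panel.covariate_names:
            state[f"sc:{name}"] = rng.normal(size=I)
            state[f"tc:{name}"] = rng.normal(size=T)
        eta = sp.linear_predictor(design, state)
        moved = dict(state)
        for name in panel.covariate_names:
            c = moved[f"tc:{name}"].mean()
            moved[f"tc:{name}"] = moved[f"tc:{name}"] - c
            moved[f"sc:{name}"] = moved[f"sc:{name}"] + c
        np.testing.assert_allclose(sp.linear_predictor(design, moved), eta, atol=1e-10)

    def test_nested_consistency_when_fields_are_null(self):
        """With zero SC/TC scales the truth is a global regression: models 1
        and 5 must deliver the same posterior-mean predictor up to Monte
        Carlo error."""
        cfg = sp.GeneratorConfig(
            rows=6, cols=6, T=6, n_se=2, n_ex=0, n_time_invariant=0,
            sc_scale=0.0, tc_scale=0.0, coef_mean_scale=0.4,
            missing_fraction=0.0, seed=19,
        )
        panel, truth = sp.generate_panel(cfg)
        pp = sp.preprocess(panel)
        g = sp.make_lattice_graph(6, 6)
        etas = {}
        for m in (1, 5):
            design = sp.build_model(sp.ModelSpec.for_model(m, pp), pp, g)
            fit = sp.fit_gibbs(
                design, sp.McmcConfig(chains=2, iterations=800, burn_in=400, seed=2)
            )
            etas[m] = fit.eta_draws().mean(axis=0)
        rmse = np.sqrt(np.mean((etas[1] - etas[5]) ** 2))
        assert rmse < 0.5 * cfg.sigma_obs


class TestPosteriorSummary:
    def _fake_fit(self, draws_beta0):
        from conftest import make_intercept_fit

        y = np.full((2, 3), 1.0)
        return make_intercept_fit(y, draws_beta0, np.ones_like(draws_beta0))

    def test_constant_draws(self):
        fit = self._fake_fit(np.full(50, 4.2))
        row = sp.posterior_summary(fit).loc["beta0"]
        assert row["mean"] == pytest.approx(4.2)
        assert row["sd"] == pytest.approx(0, abs=1e-12)
        assert row["lower"] == row["upper"] == pytest.approx(4.2)

    def test_normal_draws_quantiles(self):
        rng = np.random.default_rng(3)
        fit = self._fake_fit(rng.standard_normal(100_000))
        row = sp.posterior_summary(fit).loc["beta0"]
        assert row["lower"] == pytest.approx(-1.96, abs=0.02)
        assert row["upper"] == pytest.approx(1.96, abs=0.02)
        assert not row["significant"]

    def test_positive_draws_flagged_significant(self):
        fit = self._fake_fit(np.abs(np.random.default_rng(4).normal(5, 1, 500)))
        assert bool(sp.posterior_summary(fit).loc["beta0", "significant"])
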