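"""DIC / WAIC / CPO-LS / R^2 against closed forms and brute-force oracles."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from conftest import make_intercept_fit

import stvcpanel as sp
from stvcpanel.evaluation import ModelScorecard


def intercept_spec():
    return sp.ModelSpec(
        model_id=1, include_global_slopes=False, include_si=False,
        include_ti=False, sc_covariates=(), tc_covariates=(),
    )


class TestPointwiseLoglik:
    def test_gaussian_at_its_mode(self):
        v = 0.37
        fit = make_intercept_fit(np.array([[2.0]]), [2.0], [v])
        ll = sp.pointwise_loglik(fit)
        assert ll.shape == (1, 1)
        assert ll[0, 0] == pytest.approx(math.log(1.0 / math.sqrt(2 * math.pi * v)))

    def test_shape_is_draws_by_observed_cells(self):
        y = np.arange(6, dtype=float).reshape(2, 3) + 1
        y[0, 1] = np.nan
        fit = make_intercept_fit(y, np.linspace(1, 2, 8), np.full(8, 0.5))
        assert sp.pointwise_loglik(fit).shape == (8, 5)

    def test_matches_scalar_loop_oracle(self):
        y = np.array([[1.0, 2.0, 0.5]])
        b0 = np.array([0.9, 1.4, 2.0, 0.1])
        s2 = np.array([0.3, 0.8, 1.1, 0.6])
        ll = sp.pointwise_loglik(make_intercept_fit(y, b0, s2))
        for s in range(4):
            for c in range(3):
                expected = -0.5 * math.log(2 * math.pi * s2[s]) - 0.5 * (
                    y[0, c] - b0[s]
                ) ** 2 / s2[s]
                assert ll[s, c] == pytest.approx(expected, abs=1e-12)


class TestDic:
    def test_degenerate_posterior_collapses(self):
        y = np.array([[1.0, 2.0], [0.5, 1.5]])
        fit = make_intercept_fit(y, np.full(30, 1.2), np.full(30, 0.4))
        ll = sp.pointwise_loglik(fit)
        dic, p_dic = sp.compute_dic(ll, fit)
        assert p_dic == pytest.approx(0.0, abs=1e-8)
        assert dic == pytest.approx(float(-2 * ll[0].sum()), abs=1e-8)

    def test_normal_normal_effective_parameters(self):
        """Known-variance Gaussian mean with N(0, tau^2) prior: p_DIC equals
        n * Var_post(mu) / sigma^2 (the posterior-shrinkage count)."""
        rng = np.random.default_rng(0)
        sigma2, tau2, n = 1.0, 0.5, 24
        y = rng.normal(0.7, math.sqrt(sigma2), size=(n, 1))
        post_var = 1.0 / (n / sigma2 + 1.0 / tau2)
        post_mean = post_var * y.sum() / sigma2
        draws = rng.normal(post_mean, math.sqrt(post_var), size=40_000)
        fit = make_intercept_fit(y, draws, np.full_like(draws, sigma2))
        _, p_dic = sp.compute_dic(sp.pointwise_loglik(fit), fit)
        assert p_dic == pytest.approx(n * post_var / sigma2, rel=0.05)

    def test_dic_prefers_model_with_true_covariate(self):
        """Adding the generating covariate lowers DIC (and LS) in >= 9/10
        seeded replicates."""
        wins_dic = wins_ls = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            I, T = 20, 5
            X = rng.normal(size=(I, T, 1))
            y = 1.0 + 2.0 * X[:, :, 0] + rng.normal(0, 0.5, size=(I, T))
            panel = sp.PanelData(
                area_ids=tuple(f"a{i}" for i in range(I)),
                years=tuple(range(T)),
                y=y, X=X, covariate_names=("X1",), block_labels=("SE",),
                log_response=True,
            )
            graph = sp.graph_from_edges(
                panel.area_ids, [(i, i + 1) for i in range(I - 1)]
            )
            cards = {}
            for label, spec in (
                ("null", intercept_spec()),
                ("true", sp.ModelSpec.for_model(1, panel)),
            ):
                design = sp.build_model(spec, panel, graph)
                fit = sp.fit_gibbs(
                    design, sp.McmcConfig(chains=2, iterations=400, burn_in=200, seed=seed)
                )
                cards[label] = sp.score_model(fit)
            wins_dic += cards["true"].dic < cards["null"].dic
            wins_ls += cards["true"].ls < cards["null"].ls
        assert wins_dic >= 9
        assert wins_ls >= 9


class TestWaic:
    def test_degenerate_posterior_collapses(self):
        y = np.array([[1.0, 2.0], [0.5, 1.5]])
        fit = make_intercept_fit(y, np.full(30, 1.2), np.full(30, 0.4))
        ll = sp.pointwise_loglik(fit)
        waic, p_waic = sp.compute_waic(ll)
        assert p_waic == pytest.approx(0.0, abs=1e-10)
        assert waic == pytest.approx(float(-2 * ll[0].sum()), abs=1e-8)

    def test_penalty_nonnegative(self):
        rng = np.random.default_rng(1)
        ll = rng.normal(size=(200, 17))
        _, p_waic = sp.compute_waic(ll)
        assert p_waic >= 0

    def test_matches_high_precision_oracle(self):
        rng = np.random.default_rng(2)
        ll = rng.normal(-1.0, 0.8, size=(40, 5))
        waic, p_waic = sp.compute_waic(ll)
        llq = ll.astype(np.longdouble)
        lppd = float(np.sum(np.log(np.exp(llq).mean(axis=0))))
        pw = float(np.sum(llq.var(axis=0, ddof=1)))
        assert p_waic == pytest.approx(pw, abs=1e-10)
        assert waic == pytest.approx(-2 * (lppd - pw), abs=1e-10)


class TestCpoLs:
    def test_degenerate_posterior_is_negative_mean_loglik(self):
        y = np.array([[1.0, 2.0], [0.5, 1.5]])
        fit = make_intercept_fit(y, np.full(30, 1.2), np.full(30, 0.4))
        ll = sp.pointwise_loglik(fit)
        ls, n_unstable = sp.compute_cpo_ls(ll)
        assert ls == pytest.approx(float(-ll[0].mean()), abs=1e-10)

    def test_harmonic_estimate_matches_exact_loo_refits(self):
        """12-cell toy, 2 areas: the harmonic-mean CPO log score must agree
        with brute-force leave-one-out refitting within Monte Carlo error."""
        rng = np.random.default_rng(3)
        I, T = 2, 6
        y = rng.normal(2.0, 0.6, size=(I, T))
        X = np.zeros((I, T, 1))
        panel = sp.PanelData(
            area_ids=("a0", "a1"), years=tuple(range(T)), y=y, X=X,
            covariate_names=("X1",), block_labels=("SE",), log_response=True,
        )
        graph = sp.graph_from_edges(panel.area_ids, [(0, 1)])
        cfg = sp.McmcConfig(chains=2, iterations=3000, burn_in=1000, seed=5)
        design = sp.build_model(intercept_spec(), panel, graph)
        full = sp.fit_gibbs(design, cfg)
        ls_harmonic, _ = sp.compute_cpo_ls(sp.pointwise_loglik(full))

        logs = []
        for i in range(I):
            for t in range(T):
                held = panel.y.copy()
                held[i, t] = np.nan
                loo_panel = dataclasses.replace(panel, y=held)
                loo_design = sp.build_model(intercept_spec(), loo_panel, graph)
                loo = sp.fit_gibbs(loo_design, dataclasses.replace(cfg, seed=7 + i * T + t))
                eta = loo.eta_draws()[:, i, t]
                s2 = loo.stacked("sigma2:obs")
                dens = np.exp(
                    -0.5 * np.log(2 * np.pi * s2) - 0.5 * (y[i, t] - eta) ** 2 / s2
                )
                logs.append(np.log(dens.mean()))
        ls_exact = -float(np.mean(logs))
        assert ls_harmonic == pytest.approx(ls_exact, abs=0.05)


class TestR2:
    def _sc_fit(self, y, x, b0, sc, s2=1.0, n_draws=3):
        panel = sp.PanelData(
            area_ids=("a0", "a1"), years=(0, 1), y=np.asarray(y, dtype=float),
            X=np.asarray(x, dtype=float)[:, :, None],
            covariate_names=("X1",), block_labels=("SE",), log_response=True,
        )
        graph = sp.graph_from_edges(panel.area_ids, [(0, 1)])
        design = sp.build_model(
            sp.ModelSpec(model_id=4, include_global_slopes=False, include_si=False,
                         include_ti=False, sc_covariates=("X1",), tc_covariates=()),
            panel, graph,
        )
        draws = {
            "beta0": np.full((1, n_draws), b0),
            "sc:X1": np.tile(np.asarray(sc, dtype=float), (1, n_draws, 1)),
            "sigma2:obs": np.full((1, n_draws), s2),
            "sigma2:sc:X1": np.full((1, n_draws), 1.0),
        }
        return sp.PosteriorFit(
            design=design, draws=draws, mcmc_config=sp.McmcConfig(),
            diagnostics=pd.DataFrame(),
        )

    def test_perfect_fit_is_one(self):
        x = [[1.0, 2.0], [3.0, 4.0]]
        sc = [0.5, -0.5]
        b0 = 1.0
        y = [[1.5, 2.0], [-0.5, -1.0]]  # exactly b0 + sc_i * x
        assert sp.compute_r2(self._sc_fit(y, x, b0, sc)) == 1.0

    def test_mean_predictor_is_zero(self):
        y = np.array([[1.0, 2.0], [3.0, 4.0]])
        fit = make_intercept_fit(y, np.full(10, y.mean()), np.ones(10))
        assert sp.compute_r2(fit) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_four_cell_toy(self):
        x = [[1.0, 2.0], [3.0, 4.0]]
        y = [[2.0, 2.0], [0.0, -1.0]]
        fit = self._sc_fit(y, x, 1.0, [0.5, -0.5])
        # eta = [[1.5, 2.0], [-0.5, -1.0]]; SSE = 0.5, SST = 6.75
        assert sp.compute_r2(fit) == pytest.approx(1 - 0.5 / 6.75, abs=1e-12)

    def test_zero_total_variance_rejected(self):
        fit = make_intercept_fit(np.full((2, 2), 3.0), np.ones(5), np.ones(5))
        with pytest.raises(ValueError, match="variance"):
            sp.compute_r2(fit)


class TestCompare:
    def _card(self, m, base):
        return ModelScorecard(
            model_id=m, dic=base, waic=base + 1, p_dic=base / 10,
            p_waic=base / 10, ls=base / 100, r2=1.0 / (1 + base),
        )

    def test_dominating_model_flagged_everywhere(self):
        table = sp.compare_models([self._card(1, 10.0), self._card(2, 20.0)])
        assert set(table.loc[0, "best_on"].split(", ")) == {
            "DIC", "WAIC", "P_DIC", "P_WAIC", "LS", "R2",
        }
        assert table.loc[1, "best_on"] == ""

    def test_row_order_is_input_order(self):
        table = sp.compare_models([self._card(5, 30.0), self._card(2, 10.0)])
        assert list(table["model"]) == [5, 2]

    def test_criteria_invariant_to_draw_order(self):
        rng = np.random.default_rng(5)
        ll = rng.normal(size=(100, 9))
        perm = rng.permutation(100)
        assert sp.compute_waic(ll) == pytest.approx(sp.compute_waic(ll[perm]))
        assert sp.compute_cpo_ls(ll)[0] == pytest.approx(sp.compute_cpo_ls(ll[perm])[0])
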