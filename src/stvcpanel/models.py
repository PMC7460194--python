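"""The five nested Bayesian hierarchical models and their Gibbs sampler.

Model structure (all on the log-response scale, Gaussian observation noise):

1. ordinary multivariate regression: eta_it = b0 + sum_p b_p x_p,it
2. spatiotemporal multivariate:      model 1 + SI_i + TI_t
3. temporally varying coefficients:  eta_it = b0 + sum_p TC_p,t x_p,it
4. spatially varying coefficients:   eta_it = b0 + sum_p SC_p,i x_p,it
5. spatiotemporally varying (STVC):  eta_it = b0 + sum_p (SC_p,i + TC_p,t) x_p,it

SC and SI fields carry intrinsic CAR priors on the areal graph; TC and TI
carry RW1 priors in time; global terms carry flat (improper uniform) priors;
each precision 1/sigma^2 carries a diffuse Gamma prior. Time-invariant
covariates never receive a TC field (a constant covariate carries no
temporal contrast), so models 3 and 5 give them TC terms only where the
covariate actually varies in time.

Identifiability. Adding a constant c to a TC path and subtracting the
matching term from its paired SC field leaves the predictor unchanged, so
exactly one of each pair is constrained: TC, SI and TI fields are centered
to zero (per graph component for SI) after every update, with the removed
mean absorbed by the paired SC field, the matching global slope, or the
intercept. A TC field with no paired term (model 3) is left unconstrained —
it alone carries its covariate's overall effect level. SC fields are never
centered: they absorb the covariate's overall effect (the predictor has no
global slopes in models 4 and 5).

Inference is blocked Gibbs sampling: after the log transform the likelihood
is Gaussian, so every latent block has an exact Gaussian full conditional
(prior structure matrix over its variance, plus a diagonal likelihood term)
and every variance has a conjugate Gamma full conditional. Missing response
cells are imputed from the current posterior predictive each sweep (data
augmentation), which is what makes posterior response surfaces at
unobserved cells available downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import linalg

from .gmrf import DEFAULT_PRECISION_PRIOR, GMRFSpec, icar_structure, rw1_structure
from .io import AreaGraph, PanelData

logger = logging.getLogger("stvcpanel")

__all__ = [
    "ModelSpec",
    "Block",
    "ModelDesign",
    "McmcConfig",
    "PosteriorFit",
    "build_model",
    "linear_predictor",
    "fit_gibbs",
    "posterior_summary",
    "MODEL_NAMES",
]

MODEL_NAMES = {
    1: "ordinary multivariate",
    2: "spatiotemporal multivariate",
    3: "TVC",
    4: "SVC",
    5: "STVC",
}


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Which of the five nested models is being fitted."""

    model_id: int
    include_global_slopes: bool
    include_si: bool
    include_ti: bool
    sc_covariates: tuple[str, ...]
    tc_covariates: tuple[str, ...]
    likelihood: str = "log-gaussian"

    @classmethod
    def for_model(cls, model_id: int, panel: PanelData) -> "ModelSpec":
        """Canonical specification of models 1-5 for a given panel."""
        if model_id not in MODEL_NAMES:
            raise ValueError(f"model_id must be 1-5, got {model_id}")
        names = panel.covariate_names
        ti_flags = (
            panel.time_invariant
            if panel.time_invariant is not None
            else np.zeros(len(names), dtype=bool)
        )
        time_varying = tuple(n for n, f in zip(names, ti_flags) if not f)
        return cls(
            model_id=model_id,
            include_global_slopes=model_id in (1, 2),
            include_si=model_id == 2,
            include_ti=model_id == 2,
            sc_covariates=names if model_id in (4, 5) else (),
            tc_covariates=time_varying if model_id in (3, 5) else (),
        )


@dataclass(frozen=True)
class Block:
    """One latent block of the structured additive predictor."""

    name: str
    kind: str  # global-intercept | global-slope | SC | TC | SI | TI
    dim: int
    covariate: str | None = None
    cov_index: int | None = None
    gmrf: GMRFSpec | None = None
    constrained: bool = False
    absorb_into: str | None = None  # block that receives a removed mean


@dataclass
class ModelDesign:
    """A model bound to a preprocessed panel and an areal graph."""

    spec: ModelSpec
    panel: PanelData
    graph: AreaGraph
    blocks: list[Block]
    obs_precision_prior: tuple[float, float] = DEFAULT_PRECISION_PRIOR

    @property
    def global_block_names(self) -> list[str]:
        return [b.name for b in self.blocks if b.kind in ("global-intercept", "global-slope")]

    def block(self, name: str) -> Block:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(name)


def build_model(spec: ModelSpec, panel: PanelData, graph: AreaGraph) -> ModelDesign:
    """Assemble the latent block list for ``spec`` on ``panel`` and ``graph``."""
    if not panel.log_response:
        raise ValueError("panel must be preprocessed (log response) before model building")
    if tuple(panel.area_ids) != tuple(graph.area_ids):
        raise ValueError("panel and graph area ids disagree (order matters)")
    ti_flags = (
        panel.time_invariant
        if panel.time_invariant is not None
        else np.zeros(panel.n_covariates, dtype=bool)
    )
    cov_index = {n: p for p, n in enumerate(panel.covariate_names)}
    for name in spec.sc_covariates + spec.tc_covariates:
        if name not in cov_index:
            raise ValueError(f"unknown covariate {name!r} in model spec")
    for name in spec.tc_covariates:
        if ti_flags[cov_index[name]]:
            raise ValueError(
                f"covariate {name!r} is time-invariant and cannot carry a TC field"
            )

    I, T = panel.n_areas, panel.n_years
    blocks: list[Block] = [Block(name="beta0", kind="global-intercept", dim=1)]
    if spec.include_global_slopes:
        blocks += [
            Block(name=f"beta:{n}", kind="global-slope", dim=1, covariate=n, cov_index=cov_index[n])
            for n in panel.covariate_names
        ]
    for n in spec.sc_covariates:
        blocks.append(
            Block(
                name=f"sc:{n}",
                kind="SC",
                dim=I,
                covariate=n,
                cov_index=cov_index[n],
                gmrf=icar_structure(graph),
                constrained=False,  # SC absorbs the covariate's overall effect level
            )
        )
    for n in spec.tc_covariates:
        if n in spec.sc_covariates:
            absorb = f"sc:{n}"
        elif spec.include_global_slopes:
            absorb = f"beta:{n}"
        else:
            absorb = None  # model 3: the TC field itself carries the level
        blocks.append(
            Block(
                name=f"tc:{n}",
                kind="TC",
                dim=T,
                covariate=n,
                cov_index=cov_index[n],
                gmrf=rw1_structure(T),
                constrained=absorb is not None,
                absorb_into=absorb,
            )
        )
    if spec.include_si:
        blocks.append(
            Block(
                name="si", kind="SI", dim=I, gmrf=icar_structure(graph),
                constrained=True, absorb_into="beta0",
            )
        )
    if spec.include_ti:
        blocks.append(
            Block(
                name="ti", kind="TI", dim=T, gmrf=rw1_structure(T),
                constrained=True, absorb_into="beta0",
            )
        )
    return ModelDesign(spec=spec, panel=panel, graph=graph, blocks=blocks)


# ---------------------------------------------------------------------------
# Predictor algebra (single source, shared with the synthetic generator)
# ---------------------------------------------------------------------------


def _block_contribution(design: ModelDesign, block: Block, value) -> np.ndarray:
    I, T = design.panel.n_areas, design.panel.n_years
    X = design.panel.X
    if block.kind == "global-intercept":
        return np.full((I, T), float(value))
    if block.kind == "global-slope":
        return float(value) * X[:, :, block.cov_index]
    if block.kind == "SC":
        return np.asarray(value)[:, None] * X[:, :, block.cov_index]
    if block.kind == "TC":
        return np.asarray(value)[None, :] * X[:, :, block.cov_index]
    if block.kind == "SI":
        return np.broadcast_to(np.asarray(value)[:, None], (I, T)).copy()
    if block.kind == "TI":
        return np.broadcast_to(np.asarray(value)[None, :], (I, T)).copy()
    raise ValueError(f"unknown block kind {block.kind!r}")


def linear_predictor(design: ModelDesign, state: dict) -> np.ndarray:
    """Evaluate the structured additive predictor eta (I x T) at ``state``.

    ``state`` maps block names to values (scalars for global terms, length-I
    or length-T vectors for fields); every block of the design must be
    present with a matching dimension.
    """
    I, T = design.panel.n_areas, design.panel.n_years
    eta = np.zeros((I, T))
    for block in design.blocks:
        if block.name not in state:
            raise ValueError(f"state is missing block {block.name!r}")
        value = state[block.name]
        if block.dim > 1 and np.shape(np.asarray(value)) != (block.dim,):
            raise ValueError(
                f"block {block.name!r} expects length {block.dim}, got {np.shape(value)}"
            )
        eta += _block_contribution(design, block, value)
    return eta


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------


@dataclass
class McmcConfig:
    chains: int = 2
    iterations: int = 5000
    burn_in: int = 2500
    thin: int = 1
    seed: int = 0
    rhat_threshold: float = 1.05

    def validate(self) -> None:
        if self.chains < 1:
            raise ValueError("need at least one chain")
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("burn_in must lie in [0, iterations)")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class PosteriorFit:
    """MCMC draws of every latent block, variances, and diagnostics.

    ``draws`` maps block/variance names to arrays shaped (chains, kept, dim)
    — dim omitted for scalars. Constrained blocks sum to zero (per graph
    component) in every stored draw.
    """

    design: ModelDesign
    draws: dict[str, np.ndarray]
    mcmc_config: McmcConfig
    diagnostics: pd.DataFrame
    warnings: list[str] = dc_field(default_factory=list)

    def stacked(self, name: str) -> np.ndarray:
        """Draws of ``name`` with chains concatenated: (S,) or (S, dim)."""
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])

    @property
    def n_draws(self) -> int:
        return self.draws["beta0"].shape[0] * self.draws["beta0"].shape[1]

    def eta_draws(self) -> np.ndarray:
        """Per-draw linear predictor, shape (S, I, T), chains concatenated."""
        design = self.design
        I, T = design.panel.n_areas, design.panel.n_years
        S = self.n_draws
        eta = np.zeros((S, I, T))
        X = design.panel.X
        for block in design.blocks:
            v = self.stacked(block.name)
            if block.kind == "global-intercept":
                eta += v[:, None, None]
            elif block.kind == "global-slope":
                eta += v[:, None, None] * X[None, :, :, block.cov_index]
            elif block.kind == "SC":
                eta += v[:, :, None] * X[None, :, :, block.cov_index]
            elif block.kind == "TC":
                eta += v[:, None, :] * X[None, :, :, block.cov_index]
            elif block.kind == "SI":
                eta += v[:, :, None]
            elif block.kind == "TI":
                eta += v[:, None, :]
        return eta

    def posterior_mean_state(self) -> dict:
        """Posterior means of every block, as a state dict."""
        out = {}
        for block in self.design.blocks:
            v = self.stacked(block.name).mean(axis=0)
            out[block.name] = float(v) if block.dim == 1 else v
        return out


def _likelihood_diag_and_rhs(
    design: ModelDesign, block: Block, resid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Diagonal likelihood precision weight and rhs for a field block.

    ``resid`` is y_aug - eta + (this block's contribution); both returned
    arrays are on the unit-observation-variance scale (divide by sigma2_obs
    at the call site). With data augmentation every cell contributes.
    """
    X = design.panel.X
    if block.kind == "SC":
        x = X[:, :, block.cov_index]
        return (x**2).sum(axis=1), (x * resid).sum(axis=1)
    if block.kind == "TC":
        x = X[:, :, block.cov_index]
        return (x**2).sum(axis=0), (x * resid).sum(axis=0)
    if block.kind == "SI":
        T = design.panel.n_years
        return np.full(design.panel.n_areas, float(T)), resid.sum(axis=1)
    if block.kind == "TI":
        I = design.panel.n_areas
        return np.full(design.panel.n_years, float(I)), resid.sum(axis=0)
    raise ValueError(f"{block.kind} is not a field block")


def block_full_conditional(
    design: ModelDesign,
    block: Block,
    state: dict,
    sigma2: dict,
    y_aug: np.ndarray,
    eta: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian full conditional of a field block: (precision matrix, rhs b).

    The conditional is N(P^{-1} b, P^{-1}) with
    P = Q / sigma2_field + diag(d) / sigma2_obs, b = r / sigma2_obs.
    Exposed separately from the sweep so the sampler can be audited against
    dense joint-Gaussian conditioning.
    """
    resid = y_aug - eta + _block_contribution(design, block, state[block.name])
    d, r = _likelihood_diag_and_rhs(design, block, resid)
    s2_obs = sigma2["sigma2:obs"]
    Q = block.gmrf.structure.toarray()
    P = Q / sigma2[f"sigma2:{block.name}"] + np.diag(d / s2_obs)
    return P, r / s2_obs


def _draw_gaussian(P: np.ndarray, b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw from N(P^{-1} b, P^{-1}) via Cholesky of the precision."""
    c, low = linalg.cho_factor(P, lower=False)
    mean = linalg.cho_solve((c, low), b)
    z = rng.standard_normal(len(b))
    # upper Cholesky U with U'U = P  =>  solve U x = z gives cov P^{-1}
    dev = linalg.solve_triangular(c, z, lower=False)
    return mean + dev


def _init_state(design: ModelDesign) -> tuple[dict, dict]:
    panel = design.panel
    obs = panel.observed
    ybar = float(panel.y[obs].mean()) if obs.any() else 0.0
    state: dict = {}
    for block in design.blocks:
        if block.kind == "global-intercept":
            state[block.name] = ybar
        elif block.dim == 1:
            state[block.name] = 0.0
        else:
            state[block.name] = np.zeros(block.dim)
    sigma2 = {"sigma2:obs": float(np.var(panel.y[obs])) if obs.sum() > 1 else 1.0}
    sigma2["sigma2:obs"] = max(sigma2["sigma2:obs"], 1e-4)
    for block in design.blocks:
        if block.gmrf is not None:
            sigma2[f"sigma2:{block.name}"] = 0.1
    return state, sigma2


def _run_chain(
    design: ModelDesign, config: McmcConfig, chain_seed: int
) -> dict[str, np.ndarray]:
    panel = design.panel
    I, T = panel.n_areas, panel.n_years
    obs = panel.observed
    missing = ~obs
    rng = np.random.default_rng(chain_seed)

    state, sigma2 = _init_state(design)
    y_aug = np.where(obs, panel.y, state["beta0"])

    # precomputed pieces for the joint flat-prior global update
    global_names = design.global_block_names
    q = len(global_names)
    Zcols = []
    for name in global_names:
        block = design.block(name)
        if block.kind == "global-intercept":
            Zcols.append(np.ones(I * T))
        else:
            Zcols.append(panel.X[:, :, block.cov_index].reshape(-1))
    Z = np.column_stack(Zcols)
    ZtZ = Z.T @ Z

    field_blocks = [b for b in design.blocks if b.gmrf is not None]
    Qdense = {b.name: b.gmrf.structure.toarray() for b in field_blocks}
    like_diag = {}
    for b in field_blocks:
        d, _ = _likelihood_diag_and_rhs(design, b, np.zeros((I, T)))
        like_diag[b.name] = d

    a0, b0 = design.obs_precision_prior
    n_cells = I * T
    kept = (config.iterations - config.burn_in + config.thin - 1) // config.thin
    store: dict[str, np.ndarray] = {}
    for block in design.blocks:
        shape = (kept,) if block.dim == 1 else (kept, block.dim)
        store[block.name] = np.empty(shape)
    for name in sigma2:
        store[name] = np.empty(kept)

    eta = linear_predictor(design, state)
    k = 0
    for it in range(config.iterations):
        # --- joint update of all flat-prior global terms
        resid_flat = (y_aug - eta).reshape(-1)
        cur = np.array([state[n] for n in global_names])
        resid_flat = resid_flat + Z @ cur
        s2 = sigma2["sigma2:obs"]
        P = ZtZ / s2
        bvec = Z.T @ resid_flat / s2
        new = _draw_gaussian(P, bvec, rng)
        for n, v in zip(global_names, new):
            state[n] = float(v)
        eta += (Z @ (new - cur)).reshape(I, T)

        # --- field blocks
        for block in field_blocks:
            old = state[block.name]
            resid = y_aug - eta + _block_contribution(design, block, old)
            _, r = _likelihood_diag_and_rhs(design, block, resid)
            s2f = sigma2[f"sigma2:{block.name}"]
            P = Qdense[block.name] / s2f + np.diag(like_diag[block.name] / s2)
            new = _draw_gaussian(P, r / s2, rng)
            eta -= _block_contribution(design, block, old)
            if block.constrained:
                if block.kind == "SI":
                    # per-component centering; the size-weighted global mean is
                    # absorbed by the intercept (component-level offsets beyond
                    # it are not representable and are discarded — connected
                    # graphs lose nothing)
                    comps = design.graph.components
                    removed = 0.0
                    for label in np.unique(comps):
                        idx = comps == label
                        c = new[idx].mean()
                        new[idx] -= c
                        removed += c * idx.sum() / block.dim
                    state["beta0"] = float(state["beta0"] + removed)
                    eta += removed
                elif block.kind == "TI":
                    c = new.mean()
                    new = new - c
                    state["beta0"] = float(state["beta0"] + c)
                    eta += c
                else:  # TC paired with an SC field or a global slope
                    c = new.mean()
                    new = new - c
                    target = design.block(block.absorb_into)
                    eta -= _block_contribution(design, target, state[target.name])
                    if target.dim == 1:
                        state[target.name] = float(state[target.name] + c)
                    else:
                        state[target.name] = state[target.name] + c
                    eta += _block_contribution(design, target, state[target.name])
            state[block.name] = new
            eta += _block_contribution(design, block, new)

        # --- conjugate Gamma updates of all precisions
        for block in field_blocks:
            x = state[block.name]
            quad = float(x @ (Qdense[block.name] @ x))
            af, bf = block.gmrf.precision_prior
            shape = af + 0.5 * block.gmrf.rank
            rate = bf + 0.5 * quad
            sigma2[f"sigma2:{block.name}"] = 1.0 / rng.gamma(shape, 1.0 / rate)
        sse = float(((y_aug - eta) ** 2).sum())
        sigma2["sigma2:obs"] = 1.0 / rng.gamma(a0 + 0.5 * n_cells, 1.0 / (b0 + 0.5 * sse))

        if not np.isfinite(eta).all():
            raise FloatingPointError(
                f"non-finite predictor at iteration {it} "
                f"(model {design.spec.model_id}); check inputs and scales"
            )

        # --- data augmentation at missing cells
        if missing.any():
            y_aug[missing] = eta[missing] + np.sqrt(sigma2["sigma2:obs"]) * rng.standard_normal(
                int(missing.sum())
            )

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            for block in design.blocks:
                store[block.name][k] = state[block.name]
            for name, v in sigma2.items():
                store[name][k] = v
            k += 1
    return store


def fit_gibbs(design: ModelDesign, config: McmcConfig | None = None) -> PosteriorFit:
    """Fit ``design`` by blocked Gibbs sampling; deterministic under the seed.

    Runs ``config.chains`` independent chains, keeps post-burn-in draws, and
    attaches split-Rhat / effective-sample-size diagnostics for all global
    terms and variance components (a warning is recorded when any Rhat
    exceeds the configured threshold).
    """
    config = config or McmcConfig()
    config.validate()
    if not design.panel.observed.any():
        raise ValueError("cannot fit a panel with no observed response cells")
    root = np.random.default_rng(config.seed)
    chain_seeds = [int(root.integers(2**31)) for _ in range(config.chains)]
    chains = [_run_chain(design, config, s) for s in chain_seeds]

    draws = {
        name: np.stack([c[name] for c in chains], axis=0) for name in chains[0]
    }
    diag_names = [
        b.name for b in design.blocks if b.dim == 1
    ] + [n for n in draws if n.startswith("sigma2:")]
    diagnostics = _convergence_diagnostics(draws, diag_names)
    fit_warnings: list[str] = []
    if config.chains >= 2 and len(diagnostics):
        bad = diagnostics[diagnostics["rhat"] > config.rhat_threshold]
        if len(bad):
            msg = (
                f"split-Rhat above {config.rhat_threshold} for: "
                + ", ".join(f"{n} ({v:.3f})" for n, v in bad["rhat"].items())
            )
            fit_warnings.append(msg)
            warnings.warn(msg, stacklevel=2)
    return PosteriorFit(
        design=design,
        draws=draws,
        mcmc_config=config,
        diagnostics=diagnostics,
        warnings=fit_warnings,
    )


def _convergence_diagnostics(draws: dict[str, np.ndarray], names: list[str]) -> pd.DataFrame:
    import arviz as az

    rows = {}
    for name in names:
        arr = draws[name]
        if arr.ndim != 2:  # diagnostics reported for scalar quantities
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ds = az.convert_to_dataset(arr)
            rhat = float(az.rhat(ds)["x"].values)
            ess = float(az.ess(ds)["x"].values)
        rows[name] = {"rhat": rhat, "ess": ess}
    return pd.DataFrame.from_dict(rows, orient="index")


def posterior_summary(fit: PosteriorFit, level: float = 0.95) -> pd.DataFrame:
    """Posterior mean, sd and equal-tailed credible interval per quantity.

    One row per scalar quantity (field elements get ``name[index]`` rows);
    ``significant`` flags quantities whose credible interval excludes zero.
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    lo_q, hi_q = 0.5 * (1 - level), 1 - 0.5 * (1 - level)
    rows = []
    for name in fit.draws:
        arr = fit.stacked(name)
        if arr.ndim == 1:
            arr = arr[:, None]
            labels = [name]
        else:
            labels = [f"{name}[{j}]" for j in range(arr.shape[1])]
        mean = arr.mean(axis=0)
        sd = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros(arr.shape[1])
        lo = np.quantile(arr, lo_q, axis=0)
        hi = np.quantile(arr, hi_q, axis=0)
        for j, lab in enumerate(labels):
            rows.append(
                {
                    "quantity": lab,
                    "mean": mean[j],
                    "sd": sd[j],
                    "lower": lo[j],
                    "upper": hi[j],
                    "significant": bool(lo[j] > 0 or hi[j] < 0),
                }
            )
    return pd.DataFrame(rows).set_index("quantity")
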