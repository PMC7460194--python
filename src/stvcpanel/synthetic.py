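"""Synthetic county x year panels with known spatiotemporal ground truth.

The generator emulates the statistical structure the STVC analysis assumes,
at a desk scale: a planar lattice of areas standing in for a county
contiguity map, a block of "socioeconomic" covariates varying in space and
time plus an "environmental" block of which several are time-invariant,
spatially autocorrelated true coefficient surfaces (drawn from the
constrained intrinsic CAR itself, so recovery tests are well-specified),
smooth random-walk temporal coefficient paths, and a positive log-Gaussian
response with missing cells.

The response is assembled through the same ``linear_predictor`` code path the
models use, evaluated at the truth, so there is a single source of the
predictor algebra. Everything is fully deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .gmrf import icar_structure
from .io import AreaGraph, PanelData, graph_from_edges

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "make_lattice_graph",
    "sample_icar_field",
    "sample_rw1_path",
    "generate_panel",
]


def make_lattice_graph(rows: int, cols: int) -> AreaGraph:
    """Rook-contiguity grid graph with ``rows * cols`` areas (one component)."""
    if rows < 1 or cols < 1:
        raise ValueError(f"lattice dimensions must be positive, got {rows}x{cols}")
    idx = lambda r, c: r * cols + c
    edges = []
    for r in range(rows):
        for c in range(cols):
            if c + 1 < cols:
                edges.append((idx(r, c), idx(r, c + 1)))
            if r + 1 < rows:
                edges.append((idx(r, c), idx(r + 1, c)))
    ids = [f"A{idx(r, c):04d}" for r in range(rows) for c in range(cols)]
    return graph_from_edges(ids, edges)


@lru_cache(maxsize=16)
def _icar_sampling_basis(graph: AreaGraph) -> tuple[np.ndarray, np.ndarray, float]:
    """Eigenbasis of the ICAR structure restricted to its row space.

    Returns (V, 1/sqrt(lambda), c) where columns of V are the eigenvectors
    with nonzero eigenvalue and c normalizes the average marginal variance of
    the constrained field to 1 over non-isolated areas.
    """
    spec = icar_structure(graph)
    lam, vec = np.linalg.eigh(spec.structure.toarray())
    keep = lam > 1e-9 * max(lam[-1], 1.0)
    V = vec[:, keep]
    inv_sqrt = 1.0 / np.sqrt(lam[keep])
    marg_var = (V**2 * inv_sqrt**2).sum(axis=1)
    active = graph.m > 0
    c = float(np.sqrt(marg_var[active].mean())) if active.any() else 1.0
    return V, inv_sqrt, c


def sample_icar_field(
    graph: AreaGraph, scale: float, seed: int, size: int | None = None
) -> np.ndarray:
    """Draw from the intrinsic CAR restricted to its sum-to-zero subspace.

    The draw has covariance proportional to the pseudo-inverse of the Besag
    structure matrix, normalized so the average marginal standard deviation
    across (non-isolated) areas equals ``scale``. Sums to zero within every
    connected component; isolated areas are pinned to 0.

    With ``size`` given, returns a ``(size, n_areas)`` array of independent
    draws; otherwise a single length-I vector.
    """
    if scale < 0:
        raise ValueError("scale must be nonnegative")
    n_draws = 1 if size is None else size
    rng = np.random.default_rng(seed)
    V, inv_sqrt, c = _icar_sampling_basis(graph)
    z = rng.standard_normal((n_draws, V.shape[1]))
    draws = (z * inv_sqrt) @ V.T * (scale / c if c > 0 else 0.0)
    draws[:, graph.m == 0] = 0.0
    if (graph.m == 0).any():
        import logging

        logging.getLogger("stvcpanel").info(
            "sample_icar_field: %d isolated area(s) pinned to 0",
            int((graph.m == 0).sum()),
        )
    return draws[0] if size is None else draws


def sample_rw1_path(
    T: int, scale: float, seed: int, size: int | None = None
) -> np.ndarray:
    """Centered first-order random-walk path of length ``T``.

    ``scale`` is the standard deviation of the Gaussian increments; the
    cumulative sum is centered to zero mean, which leaves the increments
    untouched. Yields smooth, possibly nonlinear trends.
    """
    if T < 2:
        raise ValueError(f"RW1 path needs T >= 2, got {T}")
    if scale < 0:
        raise ValueError("scale must be nonnegative")
    n_draws = 1 if size is None else size
    rng = np.random.default_rng(seed)
    inc = rng.standard_normal((n_draws, T - 1)) * scale
    paths = np.concatenate([np.zeros((n_draws, 1)), np.cumsum(inc, axis=1)], axis=1)
    paths -= paths.mean(axis=1, keepdims=True)
    return paths[0] if size is None else paths


# ---------------------------------------------------------------------------
# Full panel generator
# ---------------------------------------------------------------------------


@dataclass
class GeneratorConfig:
    """Settings of the synthetic panel generator.

    Defaults produce a miniature of the motivating study panel: a 10x10
    lattice (I=100) over T=10 years with 5 socioeconomic ("SE") and 5
    environmental ("EX") covariates, the last 2 of the EX block
    time-invariant. ``beta0`` = log 30 puts the exp-scale response in a
    realistic 5-100 beds-per-10,000 range given the default field scales.
    """

    rows: int = 10
    cols: int = 10
    T: int = 10
    first_year: int = 2002
    n_se: int = 5
    n_ex: int = 5
    n_time_invariant: int = 2  # trailing covariates of the EX block
    covariate_rho: float = 0.3  # exchangeable cross-correlation within a block
    covariate_spatial_w: float = 0.5  # weight of the spatial component of each covariate
    covariate_temporal_w: float = 0.3
    beta0: float = float(np.log(30.0))
    coef_mean_scale: float = 0.15  # sd of the per-covariate global effect level
    sc_scale: float = 0.2  # marginal sd of true spatial coefficient fields
    tc_scale: float = 0.08  # increment sd of true temporal coefficient paths
    si_scale: float = 0.0  # space-intercept field (off under pure STVC truth)
    ti_scale: float = 0.0  # time-intercept path
    sigma_obs: float = 0.2  # observation noise sd on the log scale
    missing_fraction: float = 0.05
    misspecified_sc: bool = False  # draw SC truth iid Gaussian instead of ICAR
    seed: int = 0

    @property
    def n_covariates(self) -> int:
        return self.n_se + self.n_ex

    def validate(self) -> None:
        if self.n_covariates < 1:
            raise ValueError("need at least one covariate")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must lie in [0, 1)")
        if self.n_time_invariant > self.n_ex:
            raise ValueError("time-invariant covariates must fit inside the EX block")
        if self.T < 2:
            raise ValueError("T must be >= 2")
        if not 0 <= self.covariate_rho < 1:
            raise ValueError("covariate_rho must lie in [0, 1)")


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside a generated panel."""

    beta0: float
    sc_fields: dict[str, np.ndarray]  # covariate -> length-I spatial coefficients
    tc_paths: dict[str, np.ndarray]  # covariate -> length-T paths (time-varying only)
    si_field: np.ndarray | None
    ti_path: np.ndarray | None
    sigma_obs: float
    field_scales: dict[str, float]
    seed: int
    eta: np.ndarray = field(repr=False, default=None)  # I x T pre-noise predictor

    def to_jsonable(self) -> dict:
        return {
            "beta0": self.beta0,
            "sc_fields": {k: v.tolist() for k, v in self.sc_fields.items()},
            "tc_paths": {k: v.tolist() for k, v in self.tc_paths.items()},
            "si_field": None if self.si_field is None else self.si_field.tolist(),
            "ti_path": None if self.ti_path is None else self.ti_path.tolist(),
            "sigma_obs": self.sigma_obs,
            "field_scales": self.field_scales,
            "seed": self.seed,
            "eta": self.eta.tolist(),
        }


def _standardize(panel_block: np.ndarray) -> np.ndarray:
    flat = panel_block.reshape(-1)
    sd = flat.std()
    if sd == 0:
        return np.zeros_like(panel_block)
    return (panel_block - flat.mean()) / sd


def _correlated_mix(fields: np.ndarray, rho: float) -> np.ndarray:
    """Mix standardized fields (P x I x T) to exchangeable cross-correlation rho."""
    P = fields.shape[0]
    if P < 2 or rho == 0:
        return fields
    R = np.full((P, P), rho) + (1 - rho) * np.eye(P)
    L = np.linalg.cholesky(R)
    return np.einsum("pq,qit->pit", L, fields)


def generate_panel(config: GeneratorConfig) -> tuple[PanelData, SyntheticTruth]:
    """Generate a raw panel (positive response, unstandardized covariates) + truth.

    The log response is assembled as
    ``beta0 + sum_p (SC_p,i + TC_p,t) * x_p,it + SI_i + TI_t + noise``
    with x the pooled-z-scored covariates, and emitted as ``y = exp(.)`` so
    all responses are positive; a ``missing_fraction`` of cells is masked
    completely at random. The recorded truth refers to the standardized
    covariate scale (the scale on which the models operate after
    :func:`stvcpanel.io.preprocess`).
    """
    from .models import ModelSpec, build_model, linear_predictor  # local: avoid cycle

    config.validate()
    root = np.random.default_rng(config.seed)
    # independent named substreams, each seeded below 2**31
    sub = {
        name: int(root.integers(2**31))
        for name in ("covariates", "sc", "tc", "si", "ti", "coef_means", "noise", "missing", "units")
    }

    graph = make_lattice_graph(config.rows, config.cols)
    I, T, P = graph.n_areas, config.T, config.n_covariates
    years = tuple(range(config.first_year, config.first_year + T))
    names = tuple(
        [f"SE{p + 1}" for p in range(config.n_se)] + [f"EX{k + 1}" for k in range(config.n_ex)]
    )
    blocks = tuple(["SE"] * config.n_se + ["EX"] * config.n_ex)
    time_invariant = np.zeros(P, dtype=bool)
    if config.n_time_invariant:
        time_invariant[P - config.n_time_invariant :] = True

    # --- covariates: spatial + temporal + white components, block-wise mixing
    cov_rng = np.random.default_rng(sub["covariates"])
    w_s, w_t = config.covariate_spatial_w, config.covariate_temporal_w
    w_w = max(1.0 - w_s - w_t, 0.05)
    base = np.empty((P, I, T))
    for p in range(P):
        sp = sample_icar_field(graph, 1.0, int(cov_rng.integers(2**31)))
        if time_invariant[p]:
            area_noise = cov_rng.standard_normal(I)
            f = w_s * sp[:, None] + w_w * area_noise[:, None] + np.zeros((I, T))
        else:
            tm = sample_rw1_path(T, 1.0, int(cov_rng.integers(2**31)))
            f = (
                w_s * sp[:, None]
                + w_t * tm[None, :]
                + w_w * cov_rng.standard_normal((I, T))
            )
        base[p] = _standardize(f)
    # cross-correlation cannot mix time-varying into time-invariant covariates,
    # so each group is mixed within itself
    tv = ~time_invariant
    base[tv] = _correlated_mix(base[tv], config.covariate_rho)
    base[time_invariant] = _correlated_mix(base[time_invariant], config.covariate_rho)
    Z = np.stack([_standardize(base[p]) for p in range(P)], axis=-1)  # I x T x P

    # --- true coefficient structures
    mean_rng = np.random.default_rng(sub["coef_means"])
    coef_means = mean_rng.standard_normal(P) * config.coef_mean_scale
    sc_rng = np.random.default_rng(sub["sc"])
    tc_rng = np.random.default_rng(sub["tc"])
    sc_fields: dict[str, np.ndarray] = {}
    tc_paths: dict[str, np.ndarray] = {}
    for p, name in enumerate(names):
        if config.misspecified_sc:
            dev = sc_rng.standard_normal(I) * config.sc_scale
            dev -= dev.mean()
        else:
            dev = sample_icar_field(graph, config.sc_scale, int(sc_rng.integers(2**31)))
        sc_fields[name] = coef_means[p] + dev
        if not time_invariant[p]:
            tc_paths[name] = sample_rw1_path(T, config.tc_scale, int(tc_rng.integers(2**31)))
    si_field = (
        sample_icar_field(graph, config.si_scale, sub["si"]) if config.si_scale > 0 else None
    )
    ti_path = (
        sample_rw1_path(T, config.ti_scale, sub["ti"]) if config.ti_scale > 0 else None
    )

    # --- assemble the predictor through the models' own code path
    std_panel = PanelData(
        area_ids=graph.area_ids,
        years=years,
        y=np.full((I, T), np.nan),
        X=Z,
        covariate_names=names,
        block_labels=blocks,
        time_invariant=time_invariant,
        log_response=True,
    )
    spec = ModelSpec.for_model(5, std_panel)
    if si_field is not None or ti_path is not None:
        spec = ModelSpec(
            model_id=5,
            include_global_slopes=False,
            include_si=si_field is not None,
            include_ti=ti_path is not None,
            sc_covariates=spec.sc_covariates,
            tc_covariates=spec.tc_covariates,
        )
    design = build_model(spec, std_panel, graph)
    state: dict[str, np.ndarray | float] = {"beta0": config.beta0}
    for name in names:
        state[f"sc:{name}"] = sc_fields[name]
        if name in tc_paths:
            state[f"tc:{name}"] = tc_paths[name]
    if si_field is not None:
        state["si"] = si_field
    if ti_path is not None:
        state["ti"] = ti_path
    eta = linear_predictor(design, state)

    noise_rng = np.random.default_rng(sub["noise"])
    log_y = eta + noise_rng.standard_normal((I, T)) * config.sigma_obs
    y = np.exp(log_y)
    if config.missing_fraction > 0:
        miss_rng = np.random.default_rng(sub["missing"])
        mask = miss_rng.random((I, T)) < config.missing_fraction
        y = np.where(mask, np.nan, y)

    # --- emit covariates on an arbitrary raw unit so preprocessing is exercised;
    # pooled z-scoring of loc + scale*Z returns exactly Z
    unit_rng = np.random.default_rng(sub["units"])
    locs = unit_rng.uniform(10.0, 100.0, size=P)
    scales = unit_rng.uniform(1.0, 20.0, size=P)
    X_raw = Z * scales + locs

    panel = PanelData(
        area_ids=graph.area_ids,
        years=years,
        y=y,
        X=X_raw,
        covariate_names=names,
        block_labels=blocks,
        time_invariant=time_invariant,
        log_response=False,
    )
    truth = SyntheticTruth(
        beta0=config.beta0,
        sc_fields=sc_fields,
        tc_paths=tc_paths,
        si_field=si_field,
        ti_path=ti_path,
        sigma_obs=config.sigma_obs,
        field_scales={
            "sc": config.sc_scale,
            "tc": config.tc_scale,
            "si": config.si_scale,
            "ti": config.ti_scale,
        },
        seed=config.seed,
        eta=eta,
    )
    return panel, truth
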