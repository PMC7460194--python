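"""Two-step covariate screening: iterative VIF filter, then forest importance.

Step 1 removes multicollinearity within each covariate block separately
(socioeconomic and environmental factors are screened against their own
block): compute every column's variance inflation factor, drop the worst
column while the maximum exceeds the threshold (default 5, a deliberately
strict standard), recompute, repeat. Step 2 ranks the survivors by two
random-forest importances — impurity-based MDI and out-of-bag permutation
MDA — and keeps the intersection of the two top-k sets.

Screening operates on pooled space-time rows: each (area, year) cell is one
observation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.utils import check_random_state

logger = logging.getLogger("stvcpanel")

__all__ = [
    "ForestConfig",
    "ScreeningResult",
    "compute_vif",
    "iterative_vif_filter",
    "forest_importance",
    "select_covariates",
    "screen_panel",
]


# ---------------------------------------------------------------------------
# VIF
# ---------------------------------------------------------------------------


def compute_vif(X: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Variance inflation factor of every column of ``X``.

    VIF_j = 1 / (1 - R2_j) where R2_j comes from the least-squares
    regression of column j on all other columns plus an intercept. Perfect
    collinearity (R2_j = 1 within 1e-12) yields +inf rather than an error.
    Depends only on the correlation structure, so it is invariant to affine
    rescaling of any column.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    n, p = X.shape
    if p < 2:
        raise ValueError("VIF needs at least two columns")
    if n <= p:
        raise ValueError(f"VIF needs more rows than columns (n={n}, p={p})")
    sd = X.std(axis=0)
    if (sd == 0).any():
        raise ValueError("constant column: VIF undefined")
    vif = np.empty(p)
    for j in range(p):
        yj = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        sst = float(np.sum((yj - yj.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / sst
        vif[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return vif


def iterative_vif_filter(
    X: pd.DataFrame,
    threshold: float = 5.0,
    block_labels: dict[str, str] | None = None,
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Greedy within-block VIF elimination.

    Within each block independently: compute VIFs; while the maximum exceeds
    ``threshold``, drop the covariate with the largest VIF (ties drop the
    one later in canonical = column order) and recompute. A block reduced to
    a single covariate retains it unconditionally (VIF is undefined for
    p=1). Returns ``(retained-per-block, vif_table)`` where the table logs
    every elimination round (columns: block, round, covariate, vif,
    dropped).
    """
    if threshold <= 1:
        raise ValueError("threshold must exceed 1 (VIF >= 1 always)")
    block_labels = block_labels or {c: "ALL" for c in X.columns}
    blocks: dict[str, list[str]] = {}
    for c in X.columns:
        blocks.setdefault(block_labels.get(c, "ALL"), []).append(c)

    rows = []
    retained: dict[str, list[str]] = {}
    for block, cols in blocks.items():
        keep = list(cols)
        rnd = 0
        while len(keep) >= 2:
            rnd += 1
            vif = compute_vif(X[keep].to_numpy())
            worst = None
            if np.max(vif) > threshold:
                # ties broken toward the later column in canonical order
                worst = int(max(range(len(keep)), key=lambda j: (vif[j], j)))
            for j, c in enumerate(keep):
                rows.append(
                    {
                        "block": block,
                        "round": rnd,
                        "covariate": c,
                        "vif": vif[j],
                        "dropped": worst is not None and j == worst,
                    }
                )
            if worst is None:
                break
            logger.info(
                "VIF filter [%s] round %d: dropping %s (VIF=%.3f)",
                block, rnd, keep[worst], vif[worst],
            )
            del keep[worst]
        if len(keep) == 1 and len(cols) > 1:
            logger.info(
                "VIF filter [%s]: single covariate %s retained unconditionally",
                block, keep[0],
            )
        retained[block] = keep
    table = pd.DataFrame(rows, columns=["block", "round", "covariate", "vif", "dropped"])
    return retained, table


# ---------------------------------------------------------------------------
# Random-forest importance
# ---------------------------------------------------------------------------


@dataclass
class ForestConfig:
    n_trees: int = 500
    max_features: float | str | int = 1.0 / 3.0  # ~ceil(p/3) features per split
    n_permutation_repeats: int = 10
    seed: int = 0


def _bootstrap_indices(tree, n_samples: int) -> np.ndarray:
    """Bootstrap sample indices of one forest tree, re-derived from its seed.

    A tree's bootstrap sample is drawn as ``randint(0, n, n)`` from the RNG
    seeded with the tree's ``random_state`` — the forest's own sampling
    procedure (sklearn exposes the same thing privately as
    ``_generate_sample_indices``).
    """
    try:  # prefer sklearn's own generator when present
        from sklearn.ensemble._forest import _generate_sample_indices

        return _generate_sample_indices(tree.random_state, n_samples, n_samples)
    except Exception:  # pragma: no cover - version drift fallback
        rng = check_random_state(tree.random_state)
        return rng.randint(0, n_samples, n_samples)


def forest_importance(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    config: ForestConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """MDI and out-of-bag permutation MDA of a regression random forest.

    MDI is the forest's impurity-based importance — for a continuous
    response the impurity is the split variance, and the vector is
    normalized to sum to 1. MDA for feature j is the mean increase in
    out-of-bag squared error when column j is permuted, averaged over
    ``n_permutation_repeats`` permutations (each sample is predicted only by
    the trees whose bootstrap missed it). Deterministic under the seed.
    """
    config = config or ForestConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 30:
        raise ValueError(f"forest importance needs n >= 30, got {n}")
    if np.var(y) == 0:
        raise ValueError("constant response: importance undefined")

    forest = RandomForestRegressor(
        n_estimators=config.n_trees,
        max_features=config.max_features,
        bootstrap=True,
        random_state=config.seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    mdi = forest.feature_importances_.copy()

    oob_masks = []
    for tree in forest.estimators_:
        in_bag = np.zeros(n, dtype=bool)
        in_bag[_bootstrap_indices(tree, n)] = True
        oob_masks.append(~in_bag)

    def oob_mse(Xeval: np.ndarray) -> float:
        pred_sum = np.zeros(n)
        count = np.zeros(n)
        for tree, oob in zip(forest.estimators_, oob_masks):
            if oob.any():
                pred_sum[oob] += tree.predict(Xeval[oob])
                count[oob] += 1
        has = count > 0
        return float(np.mean((y[has] - pred_sum[has] / count[has]) ** 2))

    base = oob_mse(X)
    rng = np.random.default_rng(config.seed)
    mda = np.zeros(p)
    for j in range(p):
        increases = []
        for _ in range(config.n_permutation_repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(n), j]
            increases.append(oob_mse(Xp) - base)
        mda[j] = float(np.mean(increases))
    return mdi, mda


def select_covariates(
    mdi: np.ndarray,
    mda: np.ndarray,
    k: int,
    names: list[str] | tuple[str, ...] | None = None,
) -> list[str]:
    """Intersection of the top-k covariates by MDI and by MDA.

    The result is ordered by mean rank across the two indicators; a tie in
    either ranking is broken by the other indicator, then by canonical
    (input) order. An empty intersection is returned empty with a warning —
    the caller decides what to do.
    """
    mdi = np.asarray(mdi, dtype=float)
    mda = np.asarray(mda, dtype=float)
    p = len(mdi)
    if len(mda) != p:
        raise ValueError("mdi and mda must have equal length")
    if not 1 <= k <= p:
        raise ValueError(f"k must lie in [1, {p}], got {k}")
    names = list(names) if names is not None else [f"X{j}" for j in range(p)]

    def ranks(primary: np.ndarray, secondary: np.ndarray) -> np.ndarray:
        # descending by primary, ties by secondary, then canonical order
        order = sorted(range(p), key=lambda j: (-primary[j], -secondary[j], j))
        r = np.empty(p, dtype=int)
        for pos, j in enumerate(order):
            r[j] = pos
        return r

    r_mdi = ranks(mdi, mda)
    r_mda = ranks(mda, mdi)
    top_mdi = {j for j in range(p) if r_mdi[j] < k}
    top_mda = {j for j in range(p) if r_mda[j] < k}
    chosen = top_mdi & top_mda
    if not chosen:
        logger.warning("select_covariates: top-%d MDI and MDA sets do not intersect", k)
        return []
    mean_rank = (r_mdi + r_mda) / 2.0
    ordered = sorted(chosen, key=lambda j: (mean_rank[j], r_mdi[j], j))
    return [names[j] for j in ordered]


# ---------------------------------------------------------------------------
# Panel-level driver
# ---------------------------------------------------------------------------


@dataclass
class ScreeningResult:
    """Audit trail of the two screening steps."""

    vif_table: pd.DataFrame
    retained_after_vif: dict[str, list[str]]
    mdi: pd.Series
    mda: pd.Series
    selected: list[str]
    config: dict = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        return {
            "vif_table": self.vif_table.to_dict(orient="records"),
            "retained_after_vif": self.retained_after_vif,
            "mdi": self.mdi.to_dict(),
            "mda": self.mda.to_dict(),
            "selected": self.selected,
            "config": self.config,
        }


def screen_panel(
    panel,
    vif_threshold: float = 5.0,
    k: int | None = None,
    forest_config: ForestConfig | None = None,
) -> ScreeningResult:
    """Run both screening steps on a preprocessed panel.

    Rows are the observed (area, year) cells; the response is the (log)
    panel response. ``k`` defaults to ceil(p/2) over the VIF survivors.
    """
    forest_config = forest_config or ForestConfig()
    obs = panel.observed
    long_X = panel.X[obs]  # cells x P
    y = panel.y[obs]
    names = list(panel.covariate_names)
    Xdf = pd.DataFrame(long_X, columns=names)
    labels = dict(zip(names, panel.block_labels))

    retained, vif_table = iterative_vif_filter(Xdf, vif_threshold, labels)
    survivors = [c for c in names if any(c in v for v in retained.values())]
    if k is None:
        k = int(np.ceil(len(survivors) / 2))
    mdi, mda = forest_importance(Xdf[survivors].to_numpy(), y, forest_config)
    selected = select_covariates(mdi, mda, k, survivors)
    return ScreeningResult(
        vif_table=vif_table,
        retained_after_vif=retained,
        mdi=pd.Series(mdi, index=survivors, name="mdi"),
        mda=pd.Series(mda, index=survivors, name="mda"),
        selected=selected,
        config={
            "vif_threshold": vif_threshold,
            "k": k,
            "n_trees": forest_config.n_trees,
            "max_features": forest_config.max_features,
            "n_permutation_repeats": forest_config.n_permutation_repeats,
            "seed": forest_config.seed,
        },
    )
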