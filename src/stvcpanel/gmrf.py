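"""Latent Gaussian building blocks: intrinsic CAR on an areal graph, RW1 in time.

Both priors are improper Gaussian Markov random fields specified through a
sparse, symmetric, positive-semidefinite structure matrix Q with Q 1 = 0:

* ICAR (Besag): Q_ii = m_i (neighbor count), Q_ij = -1 iff i ~ j. Each value
  is conditionally Normal around the mean of its neighbors with variance
  sigma^2 / m_i. Rank deficiency = number of connected components.
* RW1: tridiagonal Q with diagonal (1, 2, ..., 2, 1) and off-diagonal -1,
  penalizing squared successive differences. Rank deficiency = 1.

The quadratic form x' Q x equals the sum of squared differences over edges
(ICAR) or over successive time points (RW1). Densities are unnormalized and
invariant to adding a constant within each connected component, which is why
identifiability downstream needs sum-to-zero constraints on some fields.

No scaling of Q by its generalized variance is applied: the variance
component sigma^2 is interpreted on the raw structure matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .io import AreaGraph

logger = logging.getLogger("stvcpanel")

__all__ = [
    "GMRFSpec",
    "icar_structure",
    "rw1_structure",
    "icar_full_conditional",
    "gmrf_log_density",
    "apply_sum_to_zero",
    "DEFAULT_PRECISION_PRIOR",
]

# Gamma(shape, rate) hyperprior on each precision 1/sigma^2; a diffuse choice
# matching common Bayesian areal-model defaults.
DEFAULT_PRECISION_PRIOR: tuple[float, float] = (1.0, 5e-5)


@dataclass(frozen=True)
class GMRFSpec:
    """An improper GMRF prior: structure matrix, deficiency, constraint.

    ``components`` labels the blocks within which the density is
    shift-invariant (graph components for ICAR; a single block for RW1).
    ``constraint`` is ``"sum-to-zero"`` (applied per component) or ``"none"``.
    """

    structure: sparse.csr_matrix
    rank_deficiency: int
    constraint: str
    components: np.ndarray
    precision_prior: tuple[float, float] = DEFAULT_PRECISION_PRIOR

    def __post_init__(self) -> None:
        if self.constraint not in ("none", "sum-to-zero"):
            raise ValueError(f"unknown constraint {self.constraint!r}")
        n = self.structure.shape[0]
        if self.structure.shape != (n, n):
            raise ValueError("structure matrix must be square")
        if len(self.components) != n:
            raise ValueError("component labels must match structure dimension")

    @property
    def dim(self) -> int:
        return self.structure.shape[0]

    @property
    def rank(self) -> int:
        return self.dim - self.rank_deficiency


def icar_structure(graph: AreaGraph) -> GMRFSpec:
    """Structure matrix of the intrinsic CAR prior on ``graph``.

    Q_ii = m_i, Q_ij = -1 iff i ~ j. Isolated areas (m_i = 0) get an all-zero
    row/column; they carry no prior information and are pinned to 0 by the
    samplers. Rank deficiency equals the number of connected components,
    counting each isolated area as its own component.
    """
    adj = graph.adjacency()
    Q = sparse.diags(graph.m.astype(float)) - adj
    return GMRFSpec(
        structure=Q.tocsr(),
        rank_deficiency=graph.n_components,
        constraint="sum-to-zero",
        components=graph.components.copy(),
    )


def rw1_structure(T: int) -> GMRFSpec:
    """Structure matrix of the first-order random-walk prior on T time points."""
    if T < 2:
        raise ValueError(f"RW1 needs at least 2 time points, got {T}")
    diag = np.full(T, 2.0)
    diag[0] = diag[-1] = 1.0
    Q = sparse.diags(
        [np.full(T - 1, -1.0), diag, np.full(T - 1, -1.0)], offsets=[-1, 0, 1]
    )
    return GMRFSpec(
        structure=Q.tocsr(),
        rank_deficiency=1,
        constraint="sum-to-zero",
        components=np.zeros(T, dtype=np.int64),
    )


def icar_full_conditional(
    values: np.ndarray, i: int, graph: AreaGraph, sigma2: float
) -> tuple[float, float]:
    """Conditional law of area ``i`` given all other areas under the ICAR prior.

    Returns ``(mean, variance)`` = (average of neighbor values, sigma2 / m_i).
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    nbrs = graph.neighbors[i]
    if not nbrs:
        raise ValueError(
            f"area {i} is isolated (m_i = 0): ICAR conditional undefined; "
            "isolated areas are pinned to 0"
        )
    values = np.asarray(values, dtype=float)
    return float(values[list(nbrs)].mean()), sigma2 / len(nbrs)


def gmrf_log_density(x: np.ndarray, spec: GMRFSpec, sigma2: float) -> float:
    """Unnormalized log-density -(1/(2 sigma2)) x' Q x of the improper prior."""
    x = np.asarray(x, dtype=float)
    if x.shape != (spec.dim,):
        raise ValueError(f"x has shape {x.shape}, expected ({spec.dim},)")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    return float(-0.5 / sigma2 * (x @ (spec.structure @ x)))


def export_mtx(spec: GMRFSpec, path) -> None:
    """Write the structure matrix in MatrixMarket format (debugging aid)."""
    from scipy.io import mmwrite

    mmwrite(str(path), spec.structure)


def apply_sum_to_zero(x: np.ndarray, spec: GMRFSpec) -> np.ndarray:
    """Center ``x`` to zero mean within each component of ``spec``.

    Idempotent; the removed means must be absorbed elsewhere by the caller
    (the sampler adds them to the paired unconstrained block).
    """
    if spec.constraint != "sum-to-zero":
        raise ValueError("spec does not carry a sum-to-zero constraint")
    x = np.asarray(x, dtype=float).copy()
    for label in np.unique(spec.components):
        idx = spec.components == label
        x[idx] -= x[idx].mean()
    return x
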