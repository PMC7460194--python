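"""Areal graphs and space-time panels: containers, file formats, preprocessing.

The two core containers are :class:`AreaGraph` (the areal adjacency structure
on which the intrinsic CAR prior lives) and :class:`PanelData` (the I x T
observation table of a positive response — hospital beds per 10,000 people in
the motivating application — together with its covariate array).

Adjacency is exchanged in the GAL spatial-weights dialect; panels in
long-format CSV with one row per (area, year).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger("stvcpanel")

__all__ = [
    "AreaGraph",
    "PanelData",
    "GalFormatError",
    "PanelFormatError",
    "read_gal",
    "write_gal",
    "graph_from_edges",
    "read_panel_csv",
    "preprocess",
]


class GalFormatError(ValueError):
    """Raised when a GAL file cannot be parsed."""


class PanelFormatError(ValueError):
    """Raised when a long-format panel CSV violates the schema contract."""


# ---------------------------------------------------------------------------
# AreaGraph
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AreaGraph:
    """Symmetric, self-loop-free areal adjacency over ``n_areas`` areas.

    Attributes
    ----------
    area_ids:
        Ordered area identifiers (strings); index position is the canonical
        area index used everywhere downstream.
    neighbors:
        Tuple of sorted integer index tuples, one per area.
    """

    area_ids: tuple[str, ...]
    neighbors: tuple[tuple[int, ...], ...]
    m: np.ndarray = field(init=False, repr=False, compare=False)
    components: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.area_ids)
        if len(self.neighbors) != n:
            raise ValueError("neighbors list length must equal number of areas")
        for i, nbrs in enumerate(self.neighbors):
            if i in nbrs:
                raise ValueError(f"self-loop at area index {i}")
            for j in nbrs:
                if not 0 <= j < n:
                    raise ValueError(f"neighbor index {j} out of range at area {i}")
                if i not in self.neighbors[j]:
                    raise ValueError(f"asymmetric adjacency between {i} and {j}")
        m = np.array([len(nbrs) for nbrs in self.neighbors], dtype=np.int64)
        object.__setattr__(self, "m", m)
        _, labels = connected_components(self.adjacency(), directed=False)
        object.__setattr__(self, "components", labels)

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def n_components(self) -> int:
        return int(self.components.max()) + 1 if self.n_areas else 0

    def adjacency(self) -> sparse.csr_matrix:
        """Binary adjacency matrix (CSR)."""
        n = self.n_areas
        rows = [i for i, nbrs in enumerate(self.neighbors) for _ in nbrs]
        cols = [j for nbrs in self.neighbors for j in nbrs]
        data = np.ones(len(rows))
        return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))

    def edges(self) -> list[tuple[int, int]]:
        """Undirected edge list with i < j."""
        return [
            (i, j)
            for i, nbrs in enumerate(self.neighbors)
            for j in nbrs
            if i < j
        ]


def graph_from_edges(
    area_ids: list[str] | tuple[str, ...], edges: list[tuple[int, int]]
) -> AreaGraph:
    """Build an :class:`AreaGraph` from an undirected edge list of indices."""
    n = len(area_ids)
    nbrs: list[set[int]] = [set() for _ in range(n)]
    for i, j in edges:
        if i == j:
            raise ValueError(f"self-loop edge ({i}, {j})")
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"edge ({i}, {j}) out of range for {n} areas")
        nbrs[i].add(j)
        nbrs[j].add(i)
    return AreaGraph(
        area_ids=tuple(str(a) for a in area_ids),
        neighbors=tuple(tuple(sorted(s)) for s in nbrs),
    )


# ---------------------------------------------------------------------------
# GAL reader / writer
# ---------------------------------------------------------------------------


def read_gal(path) -> AreaGraph:
    """Read a GAL spatial-weights file.

    The dialect: an optional leading header of up to four tokens whose last
    (or only) numeric token is the area count, then per area a line
    ``<id> <neighbor count>`` followed by a line of that many neighbor ids.
    Areas listing zero neighbors are kept as isolated nodes. An asymmetric
    listing is symmetrized with a logged warning; a neighbor id that never
    appears as an area is a parse error.
    """
    with open(path) as fh:
        tokens_by_line = [
            (lineno, line.split())
            for lineno, line in enumerate(fh, start=1)
            if line.strip() and not line.lstrip().startswith("#")
        ]
    if not tokens_by_line:
        raise GalFormatError(f"{path}: empty GAL file")

    lineno, header = tokens_by_line[0]
    # Header is either "n" or the 4-token "0 n shapefile idvar" variant.
    try:
        n = int(header[1] if len(header) == 4 else header[0])
    except (ValueError, IndexError) as exc:
        raise GalFormatError(f"{path}:{lineno}: malformed GAL header {header!r}") from exc
    if n <= 0:
        raise GalFormatError(f"{path}:{lineno}: nonpositive area count {n}")

    flat: list[tuple[int, str]] = [
        (lineno, tok) for lineno, toks in tokens_by_line[1:] for tok in toks
    ]
    pos = 0
    raw: dict[str, list[str]] = {}
    order: list[str] = []
    while pos < len(flat):
        lineno, area_id = flat[pos]
        if pos + 1 >= len(flat):
            raise GalFormatError(f"{path}:{lineno}: truncated record for area {area_id!r}")
        try:
            k = int(flat[pos + 1][1])
        except ValueError as exc:
            raise GalFormatError(
                f"{path}:{flat[pos + 1][0]}: expected neighbor count after area "
                f"{area_id!r}, got {flat[pos + 1][1]!r}"
            ) from exc
        if k < 0:
            raise GalFormatError(f"{path}:{lineno}: negative neighbor count for {area_id!r}")
        nbr_toks = flat[pos + 2 : pos + 2 + k]
        if len(nbr_toks) < k:
            raise GalFormatError(f"{path}:{lineno}: truncated neighbor list for {area_id!r}")
        if area_id in raw:
            raise GalFormatError(f"{path}:{lineno}: duplicate area id {area_id!r}")
        raw[area_id] = [tok for _, tok in nbr_toks]
        order.append(area_id)
        pos += 2 + k

    if len(order) != n:
        raise GalFormatError(
            f"{path}: header declares {n} areas but {len(order)} records found"
        )
    index = {a: i for i, a in enumerate(order)}
    nbrs: list[set[int]] = [set() for _ in range(n)]
    for area_id, nbr_ids in raw.items():
        i = index[area_id]
        for nid in nbr_ids:
            if nid not in index:
                raise GalFormatError(
                    f"{path}: area {area_id!r} lists unknown neighbor {nid!r}"
                )
            j = index[nid]
            if i == j:
                raise GalFormatError(f"{path}: area {area_id!r} lists itself as neighbor")
            nbrs[i].add(j)
    sym = 0
    for i in range(n):
        for j in list(nbrs[i]):
            if i not in nbrs[j]:
                nbrs[j].add(i)
                sym += 1
    if sym:
        logger.warning("read_gal: symmetrized %d one-directional listings in %s", sym, path)
    return AreaGraph(
        area_ids=tuple(order), neighbors=tuple(tuple(sorted(s)) for s in nbrs)
    )


def write_gal(graph: AreaGraph, path) -> None:
    """Write ``graph`` in the plain GAL dialect understood by :func:`read_gal`."""
    with open(path, "w") as fh:
        fh.write(f"{graph.n_areas}\n")
        for i, area_id in enumerate(graph.area_ids):
            nbrs = graph.neighbors[i]
            fh.write(f"{area_id} {len(nbrs)}\n")
            if nbrs:
                fh.write(" ".join(graph.area_ids[j] for j in nbrs) + "\n")


# ---------------------------------------------------------------------------
# PanelData
# ---------------------------------------------------------------------------


@dataclass
class PanelData:
    """Space-time observation panel.

    ``y`` is I x T with NaN at missing cells (``observed`` is the boolean
    mask of non-missing cells); ``X`` is I x T x P and must be complete.
    On the raw scale the response is strictly positive; :func:`preprocess`
    replaces it with its natural log and z-scores every covariate, recording
    the standardization so effects can be reported per original unit.
    """

    area_ids: tuple[str, ...]
    years: tuple[int, ...]
    y: np.ndarray
    X: np.ndarray
    covariate_names: tuple[str, ...]
    block_labels: tuple[str, ...]
    time_invariant: np.ndarray | None = None
    standardization: pd.DataFrame | None = None
    log_response: bool = False

    def __post_init__(self) -> None:
        I, T = len(self.area_ids), len(self.years)
        P = len(self.covariate_names)
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.y.shape != (I, T):
            raise ValueError(f"y shape {self.y.shape} != ({I}, {T})")
        if self.X.shape != (I, T, P):
            raise ValueError(f"X shape {self.X.shape} != ({I}, {T}, {P})")
        if len(self.block_labels) != P:
            raise ValueError("block_labels length must equal covariate count")
        if any(b not in ("SE", "EX") for b in self.block_labels):
            raise ValueError("block labels must be 'SE' or 'EX'")
        if np.isnan(self.X).any():
            raise PanelFormatError("covariates must be complete (no missing cells)")
        if self.time_invariant is not None:
            self.time_invariant = np.asarray(self.time_invariant, dtype=bool)
            if self.time_invariant.shape != (P,):
                raise ValueError("time_invariant must have one flag per covariate")
        if not self.log_response:
            obs = self.y[self.observed]
            if obs.size and (obs <= 0).any():
                raise PanelFormatError(
                    "raw response must be strictly positive (log transform pending)"
                )

    @property
    def observed(self) -> np.ndarray:
        return ~np.isnan(self.y)

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_covariates(self) -> int:
        return len(self.covariate_names)

    def to_long(self) -> pd.DataFrame:
        """Long-format view: one row per (area, year), NaN response at missing cells."""
        I, T, P = self.X.shape
        rows = {
            "area_id": np.repeat(self.area_ids, T),
            "year": np.tile(self.years, I),
            "y": self.y.reshape(-1),
        }
        for p, name in enumerate(self.covariate_names):
            rows[name] = self.X[:, :, p].reshape(-1)
        return pd.DataFrame(rows)


def read_panel_csv(
    path,
    area_col: str = "area_id",
    year_col: str = "year",
    response_col: str = "y",
    covariate_cols: list[str] | None = None,
    block_labels: dict[str, str] | None = None,
) -> PanelData:
    """Read a long-format panel CSV into a :class:`PanelData`.

    Absent (area, year) rows become missing response cells; covariates must
    be complete over the rows that are present (a NaN covariate in a present
    row is an error). Covariate cells left undefined by wholly absent rows
    are filled from the area's own covariate mean, with a logged note.

    ``block_labels`` maps covariate name to "SE" (socioeconomic) or "EX"
    (environmental); unmapped covariates default to "SE". Block membership
    only matters to screening (blocks are screened separately) and to the
    generator; the models treat both blocks identically.
    """
    df = pd.read_csv(path)
    for col in (area_col, year_col, response_col):
        if col not in df.columns:
            raise PanelFormatError(f"{path}: required column {col!r} missing")
    if covariate_cols is None:
        covariate_cols = [
            c for c in df.columns if c not in (area_col, year_col, response_col)
        ]
    for col in covariate_cols:
        if col not in df.columns:
            raise PanelFormatError(f"{path}: covariate column {col!r} missing")

    dup = df.duplicated(subset=[area_col, year_col])
    if dup.any():
        first = df.loc[dup, [area_col, year_col]].iloc[0]
        raise PanelFormatError(
            f"{path}: duplicate (area, year) pair ({first[area_col]!r}, {first[year_col]!r})"
        )
    if (pd.to_numeric(df[response_col], errors="coerce") <= 0).any():
        raise PanelFormatError(
            f"{path}: nonpositive response value found; the log transform of the "
            "response requires y > 0"
        )
    if df[covariate_cols].isna().any().any():
        raise PanelFormatError(f"{path}: missing covariate cells are not permitted")

    area_ids = tuple(sorted(df[area_col].astype(str).unique()))
    years = tuple(sorted(int(v) for v in df[year_col].unique()))
    grid = pd.MultiIndex.from_product([area_ids, years], names=[area_col, year_col])
    wide = (
        df.assign(**{area_col: df[area_col].astype(str), year_col: df[year_col].astype(int)})
        .set_index([area_col, year_col])
        .reindex(grid)
    )
    I, T, P = len(area_ids), len(years), len(covariate_cols)
    y = wide[response_col].to_numpy(dtype=float).reshape(I, T)
    X = np.stack(
        [wide[c].to_numpy(dtype=float).reshape(I, T) for c in covariate_cols], axis=-1
    )
    if np.isnan(X).any():
        # A wholly absent (area, year) row legitimately yields a missing
        # response cell but leaves covariates undefined there; fill those
        # cells from the area's own covariate mean (they only ever feed the
        # posterior predictive at the missing cell). NaN covariates in a
        # present row remain an error.
        absent = np.isnan(y)
        undefined = np.isnan(X)
        if (undefined & ~absent[:, :, None]).any():
            raise PanelFormatError(f"{path}: missing covariate cells are not permitted")
        for p in range(P):
            col = X[:, :, p]
            area_mean = np.nanmean(col, axis=1, keepdims=True)
            col[np.isnan(col)] = np.broadcast_to(area_mean, col.shape)[np.isnan(col)]
        if np.isnan(X).any():  # area with no rows at all
            raise PanelFormatError(f"{path}: area with no observations at any year")
        logger.info(
            "read_panel_csv: filled covariates at %d absent rows from area means",
            int((undefined.any(axis=2)).sum()),
        )
    labels = tuple((block_labels or {}).get(c, "SE") for c in covariate_cols)
    return PanelData(
        area_ids=area_ids,
        years=years,
        y=y,
        X=X,
        covariate_names=tuple(covariate_cols),
        block_labels=labels,
    )


def write_panel_csv(panel: PanelData, path) -> None:
    """Write a panel as long-format CSV, dropping missing-response rows."""
    long = panel.to_long()
    long[long["y"].notna()].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def detect_time_invariant(X: np.ndarray, atol: float = 0.0) -> np.ndarray:
    """Per-covariate flag: identical values at all years within every area."""
    return np.array(
        [np.allclose(X[:, :, p], X[:, :1, p], atol=atol, rtol=0.0) for p in range(X.shape[2])]
    )


def preprocess(panel: PanelData) -> PanelData:
    """Log-transform the response and z-score every covariate.

    The z-score pools mean and standard deviation over the full space-time
    panel (one mean/sd per covariate, ddof=0), so all covariate effects live
    on a single comparable scale. Standardization metadata is stored on the
    returned panel; applying :func:`preprocess` to an already-preprocessed
    panel re-centers by ~0 and re-scales by ~1, i.e. it is idempotent on the
    covariate block up to floating-point tolerance.
    """
    if panel.log_response:
        y = panel.y.copy()
    else:
        y = np.full(panel.y.shape, np.nan)
        np.log(panel.y, out=y, where=panel.observed)

    I, T, P = panel.X.shape
    flat = panel.X.reshape(I * T, P)
    mean = flat.mean(axis=0)
    sd = flat.std(axis=0, ddof=0)
    zero_var = sd <= 0
    if zero_var.any():
        bad = [panel.covariate_names[p] for p in np.flatnonzero(zero_var)]
        raise ValueError(f"zero-variance covariate(s) {bad}: z-score undefined")
    X = (panel.X - mean) / sd

    prior = panel.standardization
    if prior is not None:
        # Compose with any earlier standardization so metadata always maps
        # back to the original unit.
        mean = prior["mean"].to_numpy() + mean * prior["sd"].to_numpy()
        sd = prior["sd"].to_numpy() * sd
    meta = pd.DataFrame(
        {"mean": mean, "sd": sd}, index=pd.Index(panel.covariate_names, name="covariate")
    )
    return replace(
        panel,
        y=y,
        X=X,
        time_invariant=detect_time_invariant(panel.X),
        standardization=meta,
        log_response=True,
    )
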