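"""Downstream products of a fit: TC/SC tables, hot spots, response surfaces.

* :func:`extract_tc_table` / :func:`extract_sc_table` tabulate the posterior
  temporal and spatial coefficient fields with credible bands, on the
  standardized-covariate scale.
* :func:`getis_ord_gstar` classifies a per-area surface into hot/cold spots
  with the local Getis-Ord Gi* statistic under self-inclusive binary
  contiguity weights.
* :func:`estimate_response_maps` back-transforms the fitted model to the
  original beds-per-10,000 scale, including at missing cells, using the full
  log-normal mean E[exp(eta + eps)] = mean_s exp(eta_s + sigma_s^2 / 2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import AreaGraph, PanelData
from .models import PosteriorFit

logger = logging.getLogger("stvcpanel")

__all__ = [
    "HotspotResult",
    "extract_tc_table",
    "extract_sc_table",
    "getis_ord_gstar",
    "estimate_response_maps",
    "hotspot_geojson_properties",
]

# |z| thresholds of the 90/95/99% two-sided classification bands
_THRESHOLDS = (1.645, 1.960, 2.576)
_CLASSES = ("hot-90", "hot-95", "hot-99", "cold-90", "cold-95", "cold-99", "not-significant")


def _field_table(
    fit: PosteriorFit, kind: str, index_labels, index_name: str, level: float
) -> pd.DataFrame:
    lo_q, hi_q = 0.5 * (1 - level), 1 - 0.5 * (1 - level)
    blocks = [b for b in fit.design.blocks if b.kind == kind]
    if not blocks:
        raise ValueError(f"model {fit.design.spec.model_id} has no {kind} blocks")
    rows = []
    for block in blocks:
        draws = fit.stacked(block.name)  # S x dim
        mean = draws.mean(axis=0)
        lo = np.quantile(draws, lo_q, axis=0)
        hi = np.quantile(draws, hi_q, axis=0)
        for j, lab in enumerate(index_labels):
            rows.append(
                {
                    "covariate": block.covariate,
                    index_name: lab,
                    "mean": mean[j],
                    "lower": lo[j],
                    "upper": hi[j],
                }
            )
    return pd.DataFrame(rows)


def extract_tc_table(fit: PosteriorFit, level: float = 0.95) -> pd.DataFrame:
    """Posterior time-coefficient paths: one row per (covariate, year)."""
    return _field_table(fit, "TC", fit.design.panel.years, "year", level)


def extract_sc_table(fit: PosteriorFit, level: float = 0.95) -> pd.DataFrame:
    """Posterior space-coefficient fields: one row per (covariate, area).

    Areas appear in canonical panel order; the table is joinable to a
    GeoJSON FeatureCollection on ``area_id``.
    """
    return _field_table(fit, "SC", fit.design.panel.area_ids, "area_id", level)


@dataclass(frozen=True)
class HotspotResult:
    """Per-area Gi* z-scores and hot/cold classification."""

    z: np.ndarray
    classes: tuple[str, ...]
    area_ids: tuple[str, ...]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"area_id": self.area_ids, "z": self.z, "class": self.classes}
        )


def _classify(z: np.ndarray, fdr: bool = False) -> tuple[str, ...]:
    if fdr:
        # Benjamini-Hochberg on two-sided p-values; classification keeps the
        # band implied by each area's own z but drops non-discoveries
        p = 2.0 * stats.norm.sf(np.abs(z))
        order = np.argsort(p)
        n = len(p)
        passed = np.zeros(n, dtype=bool)
        thresh = 0.10 * (np.arange(1, n + 1)) / n
        below = p[order] <= thresh
        if below.any():
            passed[order[: np.max(np.flatnonzero(below)) + 1]] = True
    else:
        passed = np.ones(len(z), dtype=bool)
    out = []
    for zi, ok in zip(z, passed):
        a = abs(zi)
        if not ok or a < _THRESHOLDS[0]:
            out.append("not-significant")
        else:
            band = "99" if a >= _THRESHOLDS[2] else "95" if a >= _THRESHOLDS[1] else "90"
            out.append(("hot-" if zi > 0 else "cold-") + band)
    return tuple(out)


def getis_ord_gstar(
    values: np.ndarray, graph: AreaGraph, fdr: bool = False
) -> HotspotResult:
    """Local Getis-Ord Gi* of a per-area surface.

    Uses self-inclusive binary rook-contiguity weights (the "star"
    convention, w_i = m_i + 1):

        z_i = (S_i - xbar w_i) / (s sqrt((n w_i - w_i^2) / (n - 1)))

    with S_i the sum of ``values`` over area i and its neighbors, and xbar,
    s the global mean and (population) standard deviation. A constant field
    has no local structure: all z are set to 0 with a warning and every area
    is not-significant. Classification bands at |z| >= 1.645 / 1.960 / 2.576
    (90/95/99%); ``fdr=True`` additionally applies a Benjamini-Hochberg
    filter across areas (off by default, mirroring descriptive use).
    """
    values = np.asarray(values, dtype=float)
    n = graph.n_areas
    if values.shape != (n,):
        raise ValueError(f"values must have length {n}")
    if n < 2:
        raise ValueError("Gi* needs at least two areas")
    s = float(values.std(ddof=0))
    if s == 0:
        logger.warning("getis_ord_gstar: constant field, all areas not-significant")
        z = np.zeros(n)
        return HotspotResult(z=z, classes=_classify(z), area_ids=graph.area_ids)
    xbar = float(values.mean())
    w = graph.m + 1.0
    S = values.copy()
    for i, nbrs in enumerate(graph.neighbors):
        if nbrs:
            S[i] += values[list(nbrs)].sum()
    denom = s * np.sqrt((n * w - w**2) / (n - 1.0))
    z = (S - xbar * w) / denom
    return HotspotResult(z=z, classes=_classify(z, fdr=fdr), area_ids=graph.area_ids)


def estimate_response_maps(
    fit: PosteriorFit, panel: PanelData | None = None, level: float = 0.95
) -> dict[str, np.ndarray]:
    """Posterior response surfaces on the original positive scale.

    Returns ``{"mean", "lower", "upper"}`` I x T arrays. Each draw's cell
    value is the log-normal mean exp(eta_s + sigma_s^2 / 2); the posterior
    surface averages these over draws and the bands are equal-tailed
    quantiles across draws. Missing cells are filled from the same posterior
    predictive, and area-level extreme outliers are smoothed by construction
    (cells are shrunk toward the structured predictor).
    """
    panel = panel or fit.design.panel
    eta = fit.eta_draws()
    sigma2 = fit.stacked("sigma2:obs")[:, None, None]
    surf = np.exp(eta + 0.5 * sigma2)
    lo_q, hi_q = 0.5 * (1 - level), 1 - 0.5 * (1 - level)
    return {
        "mean": surf.mean(axis=0),
        "lower": np.quantile(surf, lo_q, axis=0),
        "upper": np.quantile(surf, hi_q, axis=0),
    }


def hotspot_geojson_properties(
    features: list[dict],
    hotspots: dict[str, HotspotResult],
    id_property: str = "area_id",
) -> list[dict]:
    """Attach per-surface Gi* classes and z-scores to GeoJSON features.

    ``hotspots`` maps a surface name (e.g. a covariate) to its result;
    features whose ``id_property`` is unknown to the graph are left
    untouched.
    """
    index = {}
    for name, res in hotspots.items():
        index[name] = {a: i for i, a in enumerate(res.area_ids)}
    out = []
    for feat in features:
        feat = dict(feat)
        props = dict(feat.get("properties") or {})
        aid = str(props.get(id_property, feat.get("id", "")))
        for name, res in hotspots.items():
            i = index[name].get(aid)
            if i is not None:
                props[f"{name}_z"] = float(res.z[i])
                props[f"{name}_class"] = res.classes[i]
        feat["properties"] = props
        out.append(feat)
    return out
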