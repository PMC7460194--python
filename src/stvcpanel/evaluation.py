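"""Model-comparison suite: DIC, WAIC, leave-one-out log score via CPO, R^2.

All criteria are computed from the draws x observed-cells matrix of
pointwise Gaussian log-likelihoods. Conventions:

* DIC = Dhat + 2 * p_DIC with p_DIC = Dbar - Dhat, where Dbar is the
  posterior-mean deviance and Dhat the deviance at the plug-in
  (posterior-mean linear predictor and posterior-mean observation variance).
* WAIC = -2 * (lppd - p_WAIC); lppd uses a stable log-sum-exp over draws and
  p_WAIC is the summed posterior variance of the pointwise log-likelihood.
* CPO_c is estimated by the harmonic mean of the pointwise likelihood over
  draws; LS = -(1/C) sum_c log CPO_c, smaller is better. Cells whose
  harmonic-mean estimate rests on a low effective sample size are counted
  and reported, not dropped.
* R^2 = 1 - SS_res / SS_tot on the log (model) scale at the posterior-mean
  predictor, clamped to [0, 1].

Smaller is better for DIC, WAIC, p_DIC, p_WAIC and LS; larger for R^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .io import PanelData
from .models import PosteriorFit

__all__ = [
    "ModelScorecard",
    "pointwise_loglik",
    "compute_dic",
    "compute_waic",
    "compute_cpo_ls",
    "compute_r2",
    "score_model",
    "compare_models",
]

_LOWER_BETTER = ("dic", "waic", "p_dic", "p_waic", "ls")


@dataclass(frozen=True)
class ModelScorecard:
    """The six comparison statistics for one fitted model."""

    model_id: int
    dic: float
    waic: float
    p_dic: float
    p_waic: float
    ls: float
    r2: float
    n_unstable_cpo: int = 0

    def as_row(self) -> dict[str, float]:
        return {
            "model": self.model_id,
            "DIC": self.dic,
            "WAIC": self.waic,
            "P_DIC": self.p_dic,
            "P_WAIC": self.p_waic,
            "LS": self.ls,
            "R2": self.r2,
        }


def _gaussian_loglik(y: np.ndarray, mu: np.ndarray, sigma2) -> np.ndarray:
    sigma2 = np.asarray(sigma2, dtype=float)
    return -0.5 * (np.log(2.0 * np.pi * sigma2) + (y - mu) ** 2 / sigma2)


def pointwise_loglik(fit: PosteriorFit, panel: PanelData | None = None) -> np.ndarray:
    """Per-draw, per-observed-cell Gaussian log-likelihood, shape (S, C).

    Columns cover exactly the observed (non-missing) cells of the panel, in
    row-major (area, year) order. ``panel`` defaults to the panel the model
    was fitted to.
    """
    panel = panel or fit.design.panel
    if not panel.log_response:
        raise ValueError("panel must be on the log scale")
    obs = panel.observed
    if not obs.any():
        raise ValueError("no observed cells")
    y = panel.y[obs]
    eta = fit.eta_draws()[:, obs]
    sigma2 = fit.stacked("sigma2:obs")[:, None]
    return _gaussian_loglik(y[None, :], eta, sigma2)


def compute_dic(loglik: np.ndarray, fit: PosteriorFit, panel: PanelData | None = None):
    """DIC and its effective-parameter count p_DIC.

    The plug-in deviance is evaluated at the posterior mean of the linear
    predictor and of the observation variance (not of all hyperparameters).
    """
    loglik = np.asarray(loglik, dtype=float)
    if loglik.ndim != 2 or loglik.shape[0] < 1:
        raise ValueError("loglik must be a draws x cells matrix")
    panel = panel or fit.design.panel
    obs = panel.observed
    dbar = float(np.mean(-2.0 * loglik.sum(axis=1)))
    eta_hat = fit.eta_draws().mean(axis=0)[obs]
    sigma2_hat = float(fit.stacked("sigma2:obs").mean())
    dhat = float(-2.0 * _gaussian_loglik(panel.y[obs], eta_hat, sigma2_hat).sum())
    p_dic = dbar - dhat
    return dhat + 2.0 * p_dic, p_dic


def compute_waic(loglik: np.ndarray) -> tuple[float, float]:
    """WAIC and p_WAIC from the pointwise log-likelihood matrix."""
    loglik = np.asarray(loglik, dtype=float)
    if loglik.ndim != 2 or loglik.shape[0] < 2:
        raise ValueError("WAIC needs >= 2 draws")
    S = loglik.shape[0]
    lppd = float(np.sum(logsumexp(loglik, axis=0) - np.log(S)))
    p_waic = float(np.sum(np.var(loglik, axis=0, ddof=1)))
    return -2.0 * (lppd - p_waic), p_waic


def compute_cpo_ls(
    loglik: np.ndarray, min_ess: float = 10.0
) -> tuple[float, int]:
    """Leave-one-out logarithmic score from conditional predictive ordinates.

    CPO_c = [mean_s exp(-loglik_sc)]^{-1} (harmonic mean of the pointwise
    likelihood), computed in log space; LS = -(1/C) sum_c log CPO_c. Returns
    ``(ls, n_unstable)`` where the second element counts cells whose
    harmonic-mean importance weights have effective sample size below
    ``min_ess`` (reported, never dropped).
    """
    loglik = np.asarray(loglik, dtype=float)
    if loglik.ndim != 2 or loglik.shape[0] < 2:
        raise ValueError("CPO needs >= 2 draws")
    S = loglik.shape[0]
    neg = -loglik  # importance weights are exp(-loglik)
    log_cpo = np.log(S) - logsumexp(neg, axis=0)
    lw = neg - logsumexp(neg, axis=0)
    ess = np.exp(-logsumexp(2.0 * lw, axis=0))
    n_unstable = int((ess < min_ess).sum())
    ls = float(-np.mean(log_cpo))
    return ls, n_unstable


def compute_r2(fit: PosteriorFit, panel: PanelData | None = None) -> float:
    """1 - SS_res/SS_tot on the log scale at the posterior-mean predictor."""
    panel = panel or fit.design.panel
    obs = panel.observed
    y = panel.y[obs]
    if y.size < 2 or np.var(y) == 0:
        raise ValueError("R^2 undefined: zero total variance in the response")
    eta_hat = fit.eta_draws().mean(axis=0)[obs]
    r2 = 1.0 - float(np.sum((y - eta_hat) ** 2) / np.sum((y - y.mean()) ** 2))
    return float(np.clip(r2, 0.0, 1.0))


def score_model(fit: PosteriorFit, panel: PanelData | None = None) -> ModelScorecard:
    """Compute the full six-statistic scorecard for one fitted model."""
    panel = panel or fit.design.panel
    ll = pointwise_loglik(fit, panel)
    dic, p_dic = compute_dic(ll, fit, panel)
    waic, p_waic = compute_waic(ll)
    ls, n_unstable = compute_cpo_ls(ll)
    r2 = compute_r2(fit, panel)
    return ModelScorecard(
        model_id=fit.design.spec.model_id,
        dic=dic,
        waic=waic,
        p_dic=p_dic,
        p_waic=p_waic,
        ls=ls,
        r2=r2,
        n_unstable_cpo=n_unstable,
    )


def compare_models(scorecards: list[ModelScorecard]) -> pd.DataFrame:
    """Comparison table, one row per model in input order.

    Adds a ``best_on`` column listing the criteria each model wins
    (smaller-better for DIC/WAIC/P_DIC/P_WAIC/LS, larger-better for R2).
    """
    if len(scorecards) < 2:
        raise ValueError("need at least two scorecards to compare")
    df = pd.DataFrame([s.as_row() for s in scorecards])
    winners: dict[str, int] = {}
    for col in ("DIC", "WAIC", "P_DIC", "P_WAIC", "LS"):
        winners[col] = int(df[col].idxmin())
    winners["R2"] = int(df["R2"].idxmax())
    df["best_on"] = [
        ", ".join(col for col, row in winners.items() if row == i) for i in df.index
    ]
    return df
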