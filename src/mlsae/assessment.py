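"""Model comparison and SAE-versus-direct diagnostics.

WAIC and DIC are computed from the stored draws of the linear predictor
under the Gaussian likelihood with known diagonal Sigma.  Parameter
summaries report the posterior mean / sd ratio ("t-value") with
normal-approximation significance flags at the 5% and 1% levels.  The
four model-assessment measures compare model-based (SAE) and direct
(DIR) estimates aggregated to a common margin:

    RB   = 100 * mean_c (SAE_c - DIR_c) / DIR_c
    ARB  = 100 * mean_c |SAE_c - DIR_c| / DIR_c
    RRSE = 100 * mean_c (SE_DIR_c - SE_SAE_c) / SE_DIR_c
    CVR  = mean_c CV_SAE_c / CV_DIR_c

with cells whose direct estimate or direct SE is zero excluded (and
counted).  Unweighted means over cells; a weight vector can be passed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

from .components import ModelSpec
from .sampler import PosteriorDraws

__all__ = ["waic", "dic", "t_values", "sae_diagnostics", "SaeDiagnostics"]


def _loglik_matrix(draws: PosteriorDraws, model: ModelSpec) -> np.ndarray:
    """(total draws, D) pointwise Gaussian log-likelihoods."""
    eta = draws.stacked(draws.eta)
    if eta.shape[0] < 2:
        raise ValueError("need at least 2 stored draws")
    sd = np.sqrt(model.sigma2_e)
    return norm.logpdf(model.y[None, :], loc=eta, scale=sd[None, :])


def waic(draws: PosteriorDraws, model: ModelSpec) -> float:
    """Widely applicable information criterion, -2(lppd - p_waic).

    lppd sums the log of the draw-averaged pointwise likelihood; the
    effective-parameter penalty p_waic sums the per-domain variance of
    the pointwise log-likelihood over draws.
    """
    ll = _loglik_matrix(draws, model)
    S = ll.shape[0]
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(S)))
    p_waic = float(np.sum(np.var(ll, axis=0, ddof=1)))
    return -2.0 * (lppd - p_waic)


def dic(draws: PosteriorDraws, model: ModelSpec) -> float:
    """Deviance information criterion, Dbar + pD.

    Dbar is the posterior-mean deviance and pD = Dbar - D(eta_bar) the
    effective number of parameters at the posterior-mean predictor.
    """
    ll = _loglik_matrix(draws, model)
    dbar = float(np.mean(-2.0 * ll.sum(axis=1)))
    eta_bar = draws.stacked(draws.eta).mean(axis=0)
    d_hat = float(
        -2.0 * norm.logpdf(model.y, loc=eta_bar, scale=np.sqrt(model.sigma2_e)).sum()
    )
    return dbar + (dbar - d_hat)


def t_values(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior mean / sd summaries with significance stars.

    Stars follow the normal approximation on t = mean/sd: '**' for
    p < 0.01, '*' for p < 0.05.  Parameters with zero posterior sd get
    an undefined (NaN) t and no flag.
    """
    rows = []
    params = {
        f"beta[{lab}]": draws.stacked(draws.beta)[:, j]
        for j, lab in enumerate(draws.beta_labels)
    }
    for name, arr in draws.variances.items():
        flat = draws.stacked(arr)
        for k in range(flat.shape[1]):
            params[f"sigma2_{name}[{k}]"] = flat[:, k]
    for name, x in params.items():
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=1))
        t = mean / sd if sd > 0 else np.nan
        pval = 2 * norm.sf(abs(t)) if np.isfinite(t) else np.nan
        stars = "**" if pval < 0.01 else ("*" if pval < 0.05 else "")
        rows.append(
            {"parameter": name, "mean": mean, "sd": sd, "t": t, "p": pval, "sig": stars}
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SaeDiagnostics:
    rb: float
    arb: float
    rrse: float
    cv_ratio: float
    n_cells: int
    n_excluded: int


def sae_diagnostics(
    sae_est: np.ndarray,
    sae_se: np.ndarray,
    dir_est: np.ndarray,
    dir_se: np.ndarray,
    weights: np.ndarray | None = None,
) -> SaeDiagnostics:
    """RB / ARB / RRSE / CV-ratio over one margin's cells.

    Inputs are margin-cell-aligned arrays (same cell order for SAE and
    direct).  Cells with a zero direct estimate or zero direct SE are
    excluded from every measure and counted in ``n_excluded``.
    """
    sae_est, sae_se = np.asarray(sae_est, float), np.asarray(sae_se, float)
    dir_est, dir_se = np.asarray(dir_est, float), np.asarray(dir_se, float)
    if not (len(sae_est) == len(sae_se) == len(dir_est) == len(dir_se)):
        raise ValueError("cell arrays must be aligned")
    keep = (dir_est > 0) & (dir_se > 0) & (sae_est > 0)
    n_excluded = int((~keep).sum())
    if not keep.any():
        raise ValueError("no usable cells after exclusions")
    if weights is None:
        w = np.ones(keep.sum())
    else:
        w = np.asarray(weights, float)[keep]
    w = w / w.sum()
    rel = (sae_est[keep] - dir_est[keep]) / dir_est[keep]
    rrse = (dir_se[keep] - sae_se[keep]) / dir_se[keep]
    cvr = (sae_se[keep] / sae_est[keep]) / (dir_se[keep] / dir_est[keep])
    return SaeDiagnostics(
        rb=float(100 * np.sum(w * rel)),
        arb=float(100 * np.sum(w * np.abs(rel))),
        rrse=float(100 * np.sum(w * rrse)),
        cv_ratio=float(np.sum(w * cvr)),
        n_cells=int(keep.sum()),
        n_excluded=n_excluded,
    )
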