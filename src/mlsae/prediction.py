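"""Back-transformation, draw-level aggregation, and map classification.

The model is fitted on the sqrt scale, so every stored draw of the
linear predictor is clipped to [0, 1] and squared to give a prevalence
draw; the point estimate is the posterior mean of the *squared* draws,
i.e. mean(s)^2 + var(s) — the bias correction relative to naively
squaring the posterior mean.  Aggregation to any margin is done draw by
draw with population weights, which makes national, division and
district summaries numerically consistent with the detailed-level
estimates by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BackTransformResult",
    "back_transform",
    "aggregate_draws",
    "summarize",
    "bivariate_classes",
]


@dataclass
class BackTransformResult:
    """Prevalence draws plus bias-corrected point summaries."""

    draws: np.ndarray  # (S, D) prevalence draws
    estimate: np.ndarray  # (D,) posterior mean of s^2
    se: np.ndarray  # (D,) posterior sd of s^2
    clip_fraction: float  # share of draws clipped into [0, 1]


def back_transform(s_draws: np.ndarray) -> BackTransformResult:
    """Square clipped sqrt-scale draws; report the exact posterior mean.

    The estimate mean_s(s^2) equals mean(s)^2 + var(s), the canonical
    small bias correction on the sqrt scale.  The clip fraction is a
    model-health metric: frequent clipping signals a poorly fitted
    surface.
    """
    s = np.atleast_2d(np.asarray(s_draws, float))
    clipped = np.clip(s, 0.0, 1.0)
    clip_fraction = float(np.mean(clipped != s))
    p = clipped**2
    return BackTransformResult(
        draws=p,
        estimate=p.mean(axis=0),
        se=p.std(axis=0, ddof=0),
        clip_fraction=clip_fraction,
    )


def aggregate_draws(
    p_draws: np.ndarray,
    cells: pd.Series | np.ndarray,
    weights: np.ndarray,
) -> pd.DataFrame:
    """Weighted-mean aggregation of prevalence draws to margin cells.

    Returns a (draws x cells) DataFrame whose columns are the cell
    labels in first-appearance (canonical) order.  Aggregating draws —
    not summaries — is what makes two-path aggregation exact.
    """
    p = np.atleast_2d(np.asarray(p_draws, float))
    cells = pd.Series(np.asarray(cells), name="cell")
    weights = np.asarray(weights, float)
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    if len(cells) != p.shape[1] or len(weights) != p.shape[1]:
        raise ValueError("cells/weights must align with the draw columns")
    out = {}
    for label in cells.unique():
        idx = np.flatnonzero(cells.to_numpy() == label)
        w = weights[idx]
        total = w.sum()
        if total <= 0:
            raise ValueError(f"cell {label!r} has zero total weight")
        out[label] = p[:, idx] @ (w / total)
    return pd.DataFrame(out)


def summarize(cell_draws: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Per-cell prevalence summaries in percent.

    Columns: estimate, se, cv (100*se/estimate where estimate > 0), and
    the equal-tailed credible interval.
    """
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    est = cell_draws.mean(axis=0) * 100
    se = cell_draws.std(axis=0, ddof=0) * 100
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(est > 0, 100 * se / est, np.nan)
    out = pd.DataFrame(
        {
            "estimate": est,
            "se": se,
            "cv": cv,
            "ci_lower": cell_draws.quantile(lo_q) * 100,
            "ci_upper": cell_draws.quantile(hi_q) * 100,
        }
    )
    out.index.name = "cell"
    return out


def bivariate_classes(
    estimates: np.ndarray, ses: np.ndarray
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Tercile-by-tercile classes for a bivariate choropleth.

    Estimates and SEs are each cut at their empirical terciles; the
    class is the pair (estimate tercile, SE tercile) in {1,2,3}^2, class
    (1,1) being "low estimate, high accuracy".  Returns the class table
    and the cut points.  All-equal inputs collapse to a single tercile
    and are flagged in the table's ``degenerate`` attribute.
    """
    est = np.asarray(estimates, float)
    se = np.asarray(ses, float)
    if len(est) < 3 or len(se) != len(est):
        raise ValueError("need >= 3 aligned cells")

    def _terciles(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cuts = np.quantile(x, [1 / 3, 2 / 3])
        return np.searchsorted(cuts, x, side="left") + 1, cuts

    est_t, est_cuts = _terciles(est)
    se_t, se_cuts = _terciles(se)
    table = pd.DataFrame(
        {"estimate": est, "se": se, "estimate_tercile": est_t, "se_tercile": se_t}
    )
    table["class"] = list(zip(est_t, se_t))
    table.attrs["degenerate"] = bool(np.ptp(est) == 0 or np.ptp(se) == 0)
    cuts = {"estimate": est_cuts, "se": se_cuts}
    return table, cuts
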