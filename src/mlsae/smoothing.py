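"""Sqrt transformation and generalized-variance-function SE smoothing.

Design-based SEs of small-domain proportions are noisy and strongly
correlated with the estimates themselves.  The sqrt transform stabilises
the variance and weakens that correlation; the remaining noise in the
SEs is removed by a generalized variance function (GVF): a per-stratum
log-linear regression of the sqrt-scale sampling variance on sample
size,

    log SE^2 = a + b log n,

fitted by OLS on the non-degenerate domains and used to predict an SE
for every domain — including the zero/one estimates whose design-based
SE is zero.  The smoothed SEs become the fixed diagonal Sigma of the
area-level model, so every entry must be strictly positive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data import DirectEstimateTable

__all__ = ["GvfFit", "to_sqrt_scale", "fit_gvf", "smooth_se", "plot_gvf"]


def to_sqrt_scale(table: DirectEstimateTable) -> DirectEstimateTable:
    """Delta-method transform to the sqrt scale.

    estimate' = sqrt(p_hat); SE' = SE / (2 sqrt(p_hat)) for p_hat > 0
    with SE > 0.  Degenerate domains (p_hat = 0, or SE = 0 at the
    boundaries) get SE' = NaN, to be replaced by the GVF prediction.
    """
    if table.scale != "original":
        raise ValueError("table is already on the sqrt scale")
    p = table.estimate
    if np.any(p < 0):
        raise ValueError("negative estimates")
    est = np.sqrt(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = table.se / (2 * est)
    se = np.where((p > 0) & (table.se > 0), se, np.nan)
    return table.replace(estimate=est, se=se, scale="sqrt")


@dataclass
class GvfFit:
    """Per-stratum GVF coefficients for log SE^2 = a + b log n."""

    coef: dict[str, tuple[float, float]]  # stratum -> (intercept, slope)
    r2: dict[str, float]
    n_used: dict[str, int]

    def predict_se(self, stratum: str, n: np.ndarray) -> np.ndarray:
        a, b = self.coef[stratum]
        out = np.sqrt(np.exp(a + b * np.log(np.asarray(n, float))))
        if np.any(~np.isfinite(out)) or np.any(out <= 0):
            raise ValueError("GVF predicted a non-positive variance")
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"coef": self.coef, "r2": self.r2, "n_used": self.n_used}, indent=2)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GvfFit":
        doc = json.loads(Path(path).read_text())
        return cls(
            coef={k: tuple(v) for k, v in doc["coef"].items()},
            r2=doc["r2"],
            n_used=doc["n_used"],
        )


def fit_gvf(
    table: DirectEstimateTable,
    strata: np.ndarray,
    min_rows: int = 10,
) -> GvfFit:
    """OLS of log(SE'^2) on log(n), separately per stratum.

    Only rows with a finite positive sqrt-scale SE enter the fit; each
    stratum needs at least ``min_rows`` of them.
    """
    if table.scale != "sqrt":
        raise ValueError("GVF is fitted on the sqrt scale")
    strata = np.asarray(strata)
    se, n = table.se, table.n
    usable = np.isfinite(se) & (se > 0)
    coef: dict[str, tuple[float, float]] = {}
    r2: dict[str, float] = {}
    n_used: dict[str, int] = {}
    for s in pd_unique(strata):
        mask = usable & (strata == s)
        count = int(mask.sum())
        if count < min_rows:
            raise ValueError(
                f"stratum {s!r}: only {count} usable rows (< {min_rows}) for the GVF fit"
            )
        x = np.log(n[mask])
        z = np.log(se[mask] ** 2)
        A = np.column_stack([np.ones_like(x), x])
        (a, b), *_ = np.linalg.lstsq(A, z, rcond=None)
        resid = z - (a + b * x)
        sst = np.sum((z - z.mean()) ** 2)
        r2[str(s)] = float(1 - resid @ resid / sst) if sst > 0 else 1.0
        coef[str(s)] = (float(a), float(b))
        n_used[str(s)] = count
    return GvfFit(coef=coef, r2=r2, n_used=n_used)


def pd_unique(values: np.ndarray) -> list:
    """Unique values in first-appearance order."""
    seen: list = []
    for v in values:
        if v not in seen:
            seen.append(v)
    return seen


def smooth_se(
    fit: GvfFit, table: DirectEstimateTable, strata: np.ndarray
) -> DirectEstimateTable:
    """Replace every row's SE by its GVF prediction.

    Applies to all rows (not just the degenerate ones): the model treats
    the smoothed variances as known, so a single smooth function of n
    per stratum replaces the noisy design-based values wholesale.
    """
    if table.scale != "sqrt":
        raise ValueError("smoothing operates on the sqrt scale")
    strata = np.asarray(strata)
    missing = [s for s in pd_unique(strata) if str(s) not in fit.coef]
    if missing:
        raise ValueError(f"GVF fit does not cover strata: {missing}")
    se = np.empty(table.n_domains)
    for s in pd_unique(strata):
        mask = strata == s
        se[mask] = fit.predict_se(str(s), table.n[mask])
    return table.replace(se=se)


def plot_gvf(
    raw_sqrt: DirectEstimateTable,
    smoothed: DirectEstimateTable,
    strata: np.ndarray,
    path: str | Path | None = None,
):
    """Diagnostic scatter of raw vs GVF-smoothed SEs against the
    sqrt-scale estimates, one panel per stratum."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    strata = np.asarray(strata)
    levels = pd_unique(strata)
    fig, axes = plt.subplots(1, len(levels), figsize=(5 * len(levels), 4), squeeze=False)
    for ax, s in zip(axes[0], levels):
        mask = strata == s
        ax.scatter(raw_sqrt.estimate[mask], raw_sqrt.se[mask], s=12, marker="D",
                   facecolors="none", edgecolors="tab:orange", label="direct SE")
        ax.scatter(smoothed.estimate[mask], smoothed.se[mask], s=12,
                   color="tab:blue", label="GVF SE")
        ax.set_title(str(s))
        ax.set_xlabel("sqrt-scale estimate")
        ax.set_ylabel("SE")
        ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
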