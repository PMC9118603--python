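"""Tabular containers shared across the pipeline.

:class:`DirectEstimateTable` holds per-domain design-based estimates with
their standard errors, sample sizes and aggregation weights, aligned to a
:class:`~mlsae.lattice.DomainLattice`'s canonical ordering, on either the
original proportion scale or the variance-stabilising sqrt scale.
:class:`TruthTable` records the latent prevalence surface behind a
synthetic dataset together with the realised random effects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["DirectEstimateTable", "TruthTable"]

_SCALES = ("original", "sqrt")


@dataclass
class DirectEstimateTable:
    """Per-domain direct estimates in canonical domain order.

    ``frame`` columns: ``estimate``, ``se``, ``n``, ``weight``.  On the
    sqrt scale, domains whose delta-method SE is undefined (degenerate
    zero/one estimates) carry ``se = NaN`` until a GVF prediction
    replaces it; on the original scale ``se = 0`` marks those domains.
    """

    frame: pd.DataFrame
    scale: str = "original"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ValueError(f"scale must be one of {_SCALES}")
        required = {"estimate", "se", "n"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if "weight" not in self.frame.columns:
            self.frame = self.frame.assign(weight=1.0)
        est = self.frame["estimate"].to_numpy(float)
        if self.scale == "original":
            if np.any(est < 0) or np.any(est > 1):
                raise ValueError("original-scale estimates must lie in [0, 1]")
        se = self.frame["se"].to_numpy(float)
        if np.any(se[np.isfinite(se)] < 0):
            raise ValueError("standard errors must be non-negative")
        if np.any(self.frame["n"].to_numpy(float) < 1):
            raise ValueError("sample sizes must be >= 1")
        if np.any(self.frame["weight"].to_numpy(float) <= 0):
            raise ValueError("weights must be positive")

    @property
    def n_domains(self) -> int:
        return len(self.frame)

    @property
    def estimate(self) -> np.ndarray:
        return self.frame["estimate"].to_numpy(float)

    @property
    def se(self) -> np.ndarray:
        return self.frame["se"].to_numpy(float)

    @property
    def n(self) -> np.ndarray:
        return self.frame["n"].to_numpy(float)

    @property
    def weight(self) -> np.ndarray:
        return self.frame["weight"].to_numpy(float)

    def replace(self, **cols: np.ndarray) -> "DirectEstimateTable":
        scale = cols.pop("scale", self.scale)
        frame = self.frame.copy()
        for name, values in cols.items():
            frame[name] = values
        return DirectEstimateTable(frame=frame, scale=scale, meta=dict(self.meta))

    def to_csv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out["scale"] = self.scale
        out.to_csv(path, index=False)
        meta_path = Path(path).with_suffix(".meta.json")
        meta_path.write_text(json.dumps(self.meta, indent=2, default=str))

    @classmethod
    def from_csv(cls, path: str | Path) -> "DirectEstimateTable":
        frame = pd.read_csv(path)
        scale = "original"
        if "scale" in frame.columns:
            scale = str(frame.pop("scale").iloc[0])
        meta_path = Path(path).with_suffix(".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(frame=frame, scale=scale, meta=meta)


@dataclass
class TruthTable:
    """Latent truth behind a synthetic survey: per-domain sqrt-scale
    linear predictor ``s`` (clipped), prevalence ``p = s**2``, and the
    realised random-effect vectors keyed by component name."""

    s: np.ndarray
    effects: dict[str, np.ndarray]
    beta: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        s = np.asarray(self.s, float)
        if np.any(s < 0) or np.any(s > 1):
            raise ValueError("sqrt-scale truth must lie in [0, 1]")
        self.s = s

    @property
    def p(self) -> np.ndarray:
        return self.s**2

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"s": self.s, "p": self.p}).to_csv(path, index=False)
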