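"""Blocked Gibbs sampler for the Gaussian area-level model.

All full conditionals are conjugate because the sampling covariance
Sigma is fixed and diagonal and every prior is Gaussian or
inverse-gamma:

* beta | .          ~ N(m, P^-1),  P = X' Sigma^-1 X (flat prior on beta)
* v^(i) | .         ~ N(m_i, P_i^-1),
                      P_i = Z' Sigma^-1 Z + Q_A (x) V^-1
* sigma^2_k | v^(i) ~ InvGamma(a0 + l_eff/2, b0 + u_k' Q_A u_k / 2)

where u_k is the V-level-k subvector of v^(i) and l_eff = rank(Q_A)
(l for identity Q_A, l - 1 for the intrinsic CAR).  Because every
incidence matrix Z has one 1 per row, Z' Sigma^-1 Z is diagonal; the
effect update is therefore O(q) for exchangeable components and a dense
l x l solve only for the spatial component.  The improper ICAR prior is
identified by re-centring the spatial effects to sum to zero after
every draw.

Chains are seeded deterministically from the master seed through
``numpy.random.SeedSequence.spawn``, so a run is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg

from .components import ModelSpec, RandomEffectComponent

__all__ = [
    "SamplerConfig",
    "PosteriorDraws",
    "sample_beta",
    "sample_effects",
    "sample_variances",
    "run_chains",
    "convergence",
]


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC settings.

    ``fixed_variances`` (component name -> per-V-level variances) pins
    the variance parameters and skips their Gibbs step — used by the
    closed-form oracles; ``sample_variances=False`` requires it.
    """

    n_chains: int = 3
    n_iter: int = 5000
    n_burn: int = 2500
    thin: int = 1
    seed: int = 0
    sample_variances: bool = True
    fixed_variances: dict | None = None
    init_variance: float = 0.01

    def __post_init__(self) -> None:
        if not (self.n_iter > self.n_burn >= 0):
            raise ValueError("need n_iter > n_burn >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if not self.sample_variances and self.fixed_variances is None:
            raise ValueError("fixed_variances required when variance sampling is off")


@dataclass
class PosteriorDraws:
    """Post-burn-in, thinned draws with shape (chain, draw, ...)."""

    beta: np.ndarray
    beta_labels: tuple[str, ...]
    effects: dict[str, np.ndarray]
    variances: dict[str, np.ndarray]
    eta: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.beta.shape[1]

    def stacked(self, arr: np.ndarray) -> np.ndarray:
        """Merge the chain and draw axes."""
        return arr.reshape(-1, *arr.shape[2:])

    def variance_frame(self) -> pd.DataFrame:
        """Flat (draws x parameter) table of variance draws."""
        cols = {}
        for name, arr in self.variances.items():
            flat = self.stacked(arr)
            for k in range(flat.shape[1]):
                cols[f"{name}[{k}]"] = flat[:, k]
        return pd.DataFrame(cols)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {"beta": self.beta, "eta": self.eta}
        arrays.update({f"effects__{k}": v for k, v in self.effects.items()})
        arrays.update({f"variances__{k}": v for k, v in self.variances.items()})
        np.savez_compressed(path.with_suffix(".npz"), **arrays)
        meta = {"beta_labels": list(self.beta_labels), **self.meta}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=str))

    @classmethod
    def load(cls, path: str | Path) -> "PosteriorDraws":
        path = Path(path)
        with np.load(path.with_suffix(".npz")) as npz:
            arrays = {k: npz[k] for k in npz.files}
        meta = json.loads(path.with_suffix(".json").read_text())
        labels = tuple(meta.pop("beta_labels"))
        effects = {k.split("__", 1)[1]: v for k, v in arrays.items() if k.startswith("effects__")}
        variances = {k.split("__", 1)[1]: v for k, v in arrays.items() if k.startswith("variances__")}
        return cls(
            beta=arrays["beta"],
            beta_labels=labels,
            effects=effects,
            variances=variances,
            eta=arrays["eta"],
            meta=meta,
        )


def _chol_draw(P: np.ndarray, b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw from N(P^-1 b, P^-1) via the Cholesky factor of P."""
    L = linalg.cholesky(P, lower=True)
    m = linalg.cho_solve((L, True), b)
    z = rng.standard_normal(len(b))
    return m + linalg.solve_triangular(L.T, z, lower=False)


def sample_beta(
    model: ModelSpec,
    effects: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> np.ndarray:
    """Conjugate Gaussian update of the fixed effects under a flat prior."""
    X = model.design.X
    w = 1.0 / model.sigma2_e
    resid = model.y.copy()
    for comp in model.components:
        resid -= comp.project(effects[comp.name])
    P = (X * w[:, None]).T @ X
    b = X.T @ (w * resid)
    try:
        return _chol_draw(P, b, rng)
    except np.linalg.LinAlgError as err:  # pragma: no cover - guarded by design check
        raise ValueError("singular fixed-effects precision (rank-deficient design)") from err


def sample_effects(
    model: ModelSpec,
    comp: RandomEffectComponent,
    beta: np.ndarray,
    effects: dict[str, np.ndarray],
    variances: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Conjugate Gaussian update of one component's effect vector.

    The residual excludes the component itself.  Exchangeable components
    have a diagonal full-conditional precision and are drawn in O(q);
    the ICAR component needs a dense l x l Cholesky and is re-centred to
    sum to zero afterwards.
    """
    w = 1.0 / model.sigma2_e
    resid = model.y - model.design.X @ beta
    for other in model.components:
        if other.name != comp.name:
            resid -= other.project(effects[other.name])
    ztwz = comp.crossprod(w)
    ztwr = comp.crossprod(w * resid)
    if not np.all(np.isfinite(ztwr)):
        raise ValueError(f"non-finite precision input for component {comp.name}")
    if comp.Q_A is None:
        prec = ztwz + 1.0 / comp.variances_per_effect(variances)
        mean = ztwr / prec
        return mean + rng.standard_normal(comp.q) / np.sqrt(prec)
    P = np.diag(ztwz) + comp.prior_precision(variances)
    v = _chol_draw(P, ztwr, rng)
    # sum-to-zero identification of the intrinsic CAR, per V-level
    for k in range(comp.d):
        v[k :: comp.d] -= v[k :: comp.d].mean()
    return v


def sample_variances(
    comp: RandomEffectComponent,
    v: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Conjugate inverse-gamma update of the component's V diagonal."""
    out = np.empty(comp.n_parameters)
    l_eff = comp.l - 1 if comp.is_icar else comp.l
    for k in range(comp.n_parameters):
        u = v[k :: comp.d]
        quad = float(u @ comp.Q_A @ u) if comp.is_icar else float(u @ u)
        shape = comp.prior_shape + 0.5 * l_eff
        rate = comp.prior_rate + 0.5 * quad
        out[k] = rate / rng.gamma(shape)
    return out


def _init_state(model: ModelSpec, config: SamplerConfig):
    X, w = model.design.X, 1.0 / model.sigma2_e
    P = (X * w[:, None]).T @ X
    beta = linalg.solve(P, X.T @ (w * model.y), assume_a="pos")
    effects = {c.name: np.zeros(c.q) for c in model.components}
    variances = {}
    for c in model.components:
        if config.fixed_variances and c.name in config.fixed_variances:
            variances[c.name] = np.broadcast_to(
                np.atleast_1d(np.asarray(config.fixed_variances[c.name], float)),
                (c.n_parameters,),
            ).copy()
        else:
            variances[c.name] = np.full(c.n_parameters, config.init_variance)
    return beta, effects, variances


def run_chains(model: ModelSpec, config: SamplerConfig) -> PosteriorDraws:
    """Systematic-scan Gibbs: beta, each v^(i), each variance block.

    Burn-in is discarded and thinning applied before storage; the
    linear predictor eta is stored per kept draw.  Raises on a
    non-finite state, reporting the iteration index.
    """
    n_keep = (config.n_iter - config.n_burn) // config.thin
    p, D = model.design.p, model.n_domains
    beta_out = np.empty((config.n_chains, n_keep, p))
    eta_out = np.empty((config.n_chains, n_keep, D))
    eff_out = {c.name: np.empty((config.n_chains, n_keep, c.q)) for c in model.components}
    var_out = {c.name: np.empty((config.n_chains, n_keep, c.n_parameters)) for c in model.components}

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    sample_var = {
        c.name: config.sample_variances
        and not (config.fixed_variances and c.name in config.fixed_variances)
        for c in model.components
    }
    for chain, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        beta, effects, variances = _init_state(model, config)
        kept = 0
        for it in range(config.n_iter):
            beta = sample_beta(model, effects, rng)
            for comp in model.components:
                effects[comp.name] = sample_effects(
                    model, comp, beta, effects, variances[comp.name], rng
                )
                if sample_var[comp.name]:
                    variances[comp.name] = sample_variances(comp, effects[comp.name], rng)
            if not np.all(np.isfinite(beta)):
                raise RuntimeError(f"sampler diverged at iteration {it} (chain {chain})")
            if it >= config.n_burn and (it - config.n_burn) % config.thin == 0:
                beta_out[chain, kept] = beta
                eta_out[chain, kept] = model.eta(beta, effects)
                for comp in model.components:
                    eff_out[comp.name][chain, kept] = effects[comp.name]
                    var_out[comp.name][chain, kept] = variances[comp.name]
                kept += 1
    return PosteriorDraws(
        beta=beta_out,
        beta_labels=model.design.labels,
        effects=eff_out,
        variances=var_out,
        eta=eta_out,
        meta={"config": asdict(config), "n_domains": D},
    )


def convergence(draws: PosteriorDraws, rhat_threshold: float = 1.05) -> pd.DataFrame:
    """Split R-hat and bulk ESS per scalar parameter (via arviz).

    Covers the fixed effects and every variance parameter.  Requires at
    least two chains.
    """
    if draws.n_chains < 2:
        raise ValueError("convergence diagnostics need >= 2 chains")
    import arviz as az

    rows = []
    params = {
        f"beta[{lab}]": draws.beta[:, :, j]
        for j, lab in enumerate(draws.beta_labels)
    }
    for name, arr in draws.variances.items():
        for k in range(arr.shape[2]):
            params[f"sigma2_{name}[{k}]"] = arr[:, :, k]
    for name, arr in params.items():
        ds = az.convert_to_dataset(np.asarray(arr))
        rows.append(
            {
                "parameter": name,
                "rhat": float(az.rhat(ds)["x"].values),
                "ess_bulk": float(az.ess(ds)["x"].values),
            }
        )
    out = pd.DataFrame(rows)
    out["flagged"] = out["rhat"] > rhat_threshold
    return out
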