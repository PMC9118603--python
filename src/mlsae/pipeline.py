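"""End-to-end wiring: smooth, fit, predict, assess.

These functions connect the stage modules into the standard workflow —
from a table of direct estimates to margin-level prevalence summaries —
and provide the simulation-based parameter-recovery harness that
validates the whole chain against a known truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .assessment import SaeDiagnostics, sae_diagnostics
from .components import (
    ModelSpec,
    assemble_model,
    build_component,
    fixed_design,
)
from .data import DirectEstimateTable
from .lattice import AdjacencyGraph, DomainLattice, margin_map
from .prediction import aggregate_draws, back_transform, summarize
from .sampler import PosteriorDraws, SamplerConfig, run_chains
from .smoothing import fit_gvf, smooth_se, to_sqrt_scale
from .synthetic import GenerativeParams, draw_truth, population_weights, simulate_direct

__all__ = [
    "SaeFit",
    "prepare_inputs",
    "fit_model",
    "prevalence_at",
    "direct_at",
    "diagnostics_by_margin",
    "coverage_experiment",
]


@dataclass
class SaeFit:
    """A fitted model with its inputs and posterior draws."""

    model: ModelSpec
    draws: PosteriorDraws
    table_sqrt: DirectEstimateTable
    lattice: DomainLattice


def prepare_inputs(
    table: DirectEstimateTable, lattice: DomainLattice
) -> tuple[DirectEstimateTable, np.ndarray]:
    """Sqrt-transform and GVF-smooth a direct-estimate table.

    Returns the smoothed sqrt-scale table and the residence strata used
    for the per-stratum GVF fits.
    """
    strata = lattice.frame["residence"].to_numpy()
    sqrt_table = to_sqrt_scale(table)
    gvf = fit_gvf(sqrt_table, strata)
    return smooth_se(gvf, sqrt_table, strata), strata


def fit_model(
    table: DirectEstimateTable,
    lattice: DomainLattice,
    graph: AdjacencyGraph | None,
    components: Sequence[str],
    config: SamplerConfig,
) -> SaeFit:
    """Full fit: smoothing, model assembly, Gibbs sampling."""
    smoothed, _ = prepare_inputs(table, lattice)
    design = fixed_design(lattice)
    comps = [build_component(name, lattice, graph) for name in components]
    model = assemble_model(
        smoothed.estimate, comps, design, smoothed.se**2, lattice=lattice
    )
    draws = run_chains(model, config)
    return SaeFit(model=model, draws=draws, table_sqrt=smoothed, lattice=lattice)


def prevalence_at(
    fit: SaeFit,
    margin: Sequence[str],
    weights: np.ndarray,
) -> pd.DataFrame:
    """Model-based prevalence summaries (percent) at a margin."""
    bt = back_transform(fit.draws.stacked(fit.draws.eta))
    cells = margin_map(fit.lattice, margin)
    return summarize(aggregate_draws(bt.draws, cells, weights))


def direct_at(
    table: DirectEstimateTable,
    lattice: DomainLattice,
    margin: Sequence[str],
    weights: np.ndarray,
) -> pd.DataFrame:
    """Design-based margin estimates (percent).

    Weighted means of the domain estimates; SEs combine independently,
    SE_c = sqrt(sum w^2 SE^2) / sum w.
    """
    if table.scale != "original":
        raise ValueError("direct aggregation expects the original scale")
    cells = margin_map(lattice, margin)
    weights = np.asarray(weights, float)
    rows = {}
    for label in cells.unique():
        idx = np.flatnonzero(cells.to_numpy() == label)
        w = weights[idx] / weights[idx].sum()
        est = float(w @ table.estimate[idx])
        se = float(np.sqrt(np.sum((w * table.se[idx]) ** 2)))
        rows[label] = {"estimate": 100 * est, "se": 100 * se}
    out = pd.DataFrame(rows).T
    out.index.name = "cell"
    return out


def diagnostics_by_margin(
    fit: SaeFit,
    table: DirectEstimateTable,
    weights: np.ndarray,
    margins: Sequence[Sequence[str]] = ((), ("district",), ("district", "residence", "age_group", "sex")),
) -> pd.DataFrame:
    """RB/ARB/RRSE/CV-ratio per margin, coarse to fine."""
    rows = []
    for margin in margins:
        sae = prevalence_at(fit, margin, weights)
        direct = direct_at(table, fit.lattice, margin, weights)
        direct = direct.loc[sae.index]
        diag: SaeDiagnostics = sae_diagnostics(
            sae["estimate"].to_numpy(),
            sae["se"].to_numpy(),
            direct["estimate"].to_numpy(),
            direct["se"].to_numpy(),
        )
        rows.append(
            {
                "margin": "national" if not margin else "x".join(margin),
                "rb": diag.rb,
                "arb": diag.arb,
                "rrse": diag.rrse,
                "cv_ratio": diag.cv_ratio,
                "n_cells": diag.n_cells,
                "n_excluded": diag.n_excluded,
            }
        )
    return pd.DataFrame(rows)


def coverage_experiment(
    lattice: DomainLattice,
    graph: AdjacencyGraph,
    params: GenerativeParams,
    components: Sequence[str],
    config: SamplerConfig,
    n_replicates: int = 50,
    seed: int = 0,
    level: float = 0.95,
) -> pd.DataFrame:
    """Simulation-based credible-interval coverage of the fixed effects.

    For each replicate: draw a truth surface and direct estimates with
    known beta, run the full pipeline (sqrt + GVF + Gibbs), and check
    whether each true fixed effect lies inside its equal-tailed
    credible interval.  Returns per-coefficient coverage over
    replicates — the pipeline's calibration certificate.
    """
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    master = np.random.SeedSequence(seed)
    hits: np.ndarray | None = None
    labels: tuple[str, ...] | None = None
    beta_true: np.ndarray | None = None
    for rep, ss in enumerate(master.spawn(n_replicates)):
        children = ss.spawn(3)
        rng_truth = np.random.default_rng(children[0])
        rng_survey = np.random.default_rng(children[1])
        chain_seed = int(children[2].generate_state(1)[0] % (2**31 - 1))
        truth = draw_truth(lattice, graph, params, components=components, rng=rng_truth)
        table = simulate_direct(truth, lattice, params, rng=rng_survey)
        fit = fit_model(
            table,
            lattice,
            graph,
            components,
            SamplerConfig(
                n_chains=config.n_chains,
                n_iter=config.n_iter,
                n_burn=config.n_burn,
                thin=config.thin,
                seed=chain_seed,
                sample_variances=config.sample_variances,
                fixed_variances=config.fixed_variances,
                init_variance=config.init_variance,
            ),
        )
        beta = fit.draws.stacked(fit.draws.beta)
        lo = np.quantile(beta, lo_q, axis=0)
        hi = np.quantile(beta, hi_q, axis=0)
        inside = (truth.beta >= lo) & (truth.beta <= hi)
        if hits is None:
            hits = np.zeros(len(inside))
            labels = fit.draws.beta_labels
            beta_true = truth.beta
        hits += inside
    assert hits is not None
    return pd.DataFrame(
        {
            "parameter": list(labels),
            "beta_true": beta_true,
            "coverage": hits / n_replicates,
        }
    )
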