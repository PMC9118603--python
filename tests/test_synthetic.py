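"""Synthetic survey generator: truth surface, direct estimates, weights."""

import numpy as np
import pandas as pd
import pytest

import mlsae
from mlsae.synthetic import GenerativeParams


@pytest.fixture(scope="module")
def lattice():
    return mlsae.example_lattice(8, 2, n_ages=5)


@pytest.fixture(scope="module")
def graph(lattice):
    return mlsae.grid_adjacency(lattice.districts)


def _zero_variance_params(**kw):
    zeros = {name: (0.0,) * 5 for name in mlsae.COMPONENT_NAMES}
    defaults = dict(
        intercept=0.5,
        age_contrasts=(0.0,),
        division_contrasts=(0.0,),
        urban_contrast=0.0,
        male_contrast=0.0,
        component_values=zeros,
        seed=0,
    )
    defaults.update(kw)
    return GenerativeParams(**defaults)


def test_truth_is_flat_quarter_when_all_variation_off(lattice, graph):
    params = _zero_variance_params()
    truth = mlsae.draw_truth(lattice, graph, params)
    np.testing.assert_allclose(truth.p, 0.25)
    np.testing.assert_allclose(truth.s, 0.5)


def test_toddler_age_group_has_maximal_mean_truth(lattice, graph):
    """The 24-35 month contrast is the largest age effect, so with the
    random effects off the truth surface peaks there in every
    district x residence x sex cell."""
    params = _zero_variance_params(
        intercept=0.396, age_contrasts=(0.127, 0.169, 0.147, 0.088)
    )
    truth = mlsae.draw_truth(lattice, graph, params)
    frame = lattice.frame.assign(p=truth.p)
    peak = frame.groupby(["district", "residence", "sex"], sort=False).apply(
        lambda g: g.loc[g["p"].idxmax(), "age_group"], include_groups=False
    )
    assert (peak == "24-35").all()


def test_spatial_component_variance_matches_pseudoinverse_oracle():
    """Monte-Carlo district variance under SP_DIST alone must match the
    diagonal of sigma^2 Q^+ (the ICAR's proper-part covariance)."""
    lat = mlsae.example_lattice(10, 2, n_ages=2)
    graph = mlsae.grid_adjacency(lat.districts)
    sigma2 = 0.02
    # centre the surface at s = 0.5 so the [0, 1] clip never bites
    params = _zero_variance_params(
        intercept=0.5,
        component_values={"SP_DIST": (np.sqrt(sigma2),)},
        zero_floor=0.0,
    )
    Q = mlsae.car_precision(graph, order=lat.districts)
    target = np.mean(np.diag(sigma2 * np.linalg.pinv(Q)))
    rng = np.random.default_rng(123)
    reps = []
    district_code = lat.codes("district")
    for _ in range(200):
        truth = mlsae.draw_truth(lat, graph, params, components=("SP_DIST",), rng=rng)
        by_district = pd.Series(truth.s - 0.5).groupby(district_code).mean()
        reps.append(np.mean(by_district.to_numpy() ** 2))  # mean 0 by constraint
    mc = np.mean(reps)
    assert abs(mc - target) < 4 * np.std(reps) / np.sqrt(len(reps)) + 0.1 * target


def test_direct_estimates_all_zero_when_truth_is_zero(lattice, graph):
    params = _zero_variance_params(intercept=0.0, zero_floor=0.0)
    truth = mlsae.draw_truth(lattice, graph, params)
    table = mlsae.simulate_direct(truth, lattice, params)
    assert (table.estimate == 0).all()
    assert (table.se == 0).all()


def test_large_samples_concentrate_on_truth(lattice, graph):
    params = _zero_variance_params(
        deff=1.0, n_range_rural=(10**6, 10**6), n_range_urban=(10**6, 10**6)
    )
    truth = mlsae.draw_truth(lattice, graph, params)
    table = mlsae.simulate_direct(truth, lattice, params)
    # binomial tail: P(|p_hat - .25| >= .005) < 1e-2 at n = 1e6
    assert np.all(np.abs(table.estimate - 0.25) < 0.005)


def test_urban_ses_noisier_than_rural(lattice, graph):
    params = GenerativeParams(seed=42)
    truth = mlsae.draw_truth(lattice, graph, params)
    table = mlsae.simulate_direct(truth, lattice, params)
    urban = lattice.frame["residence"].to_numpy() == "urban"
    pos = table.se > 0
    assert table.se[urban & pos].mean() > table.se[~urban & pos].mean()


def test_reported_se_matches_empirical_sd_at_large_n(lattice, graph):
    """At n >= 500 the design-adjusted binomial SE formula must agree
    with the across-replicate sd of the estimates within 10%."""
    params = _zero_variance_params(
        deff=1.5, n_range_rural=(500, 500), n_range_urban=(500, 500)
    )
    truth = mlsae.draw_truth(lattice, graph, params)
    rng = np.random.default_rng(9)
    estimates, ses = [], []
    for _ in range(400):
        table = mlsae.simulate_direct(truth, lattice, params, rng=rng)
        estimates.append(table.estimate)
        ses.append(table.se)
    emp_sd = np.std(np.array(estimates), axis=0).mean()
    reported = np.mean(ses)
    assert abs(emp_sd - reported) / reported < 0.10


def test_seed_determinism(lattice, graph):
    params = GenerativeParams(seed=7)
    t1 = mlsae.draw_truth(lattice, graph, params)
    t2 = mlsae.draw_truth(lattice, graph, params)
    np.testing.assert_array_equal(t1.s, t2.s)
    d1 = mlsae.simulate_direct(t1, lattice, params)
    d2 = mlsae.simulate_direct(t2, lattice, params)
    pd.testing.assert_frame_equal(d1.frame, d2.frame)
    t3 = mlsae.draw_truth(lattice, graph, params.with_(seed=8))
    assert not np.array_equal(t1.s, t3.s)


def test_degenerate_domains_producible_with_tiny_urban_samples(lattice, graph):
    params = GenerativeParams(seed=1, n_range_urban=(5, 10), n_range_rural=(10, 20))
    truth = mlsae.draw_truth(lattice, graph, params)
    table = mlsae.simulate_direct(truth, lattice, params)
    degenerate = (table.estimate == 0) | (table.estimate == 1)
    assert degenerate.any()
    assert np.all(table.se[degenerate] == 0)


def test_population_weights_structure(lattice):
    w_equal = mlsae.population_weights(lattice, equal=True)
    np.testing.assert_array_equal(w_equal, 1.0)
    w = mlsae.population_weights(lattice, seed=3)
    assert np.all(w > 0)
    np.testing.assert_array_equal(w, mlsae.population_weights(lattice, seed=3))
    # a constant surface aggregates to itself under any weights
    const = np.full(lattice.n_domains, 0.37)
    assert np.isclose(np.average(const, weights=w), 0.37)
    # district shares sum to the drawn district total (construction)
    district_sums = pd.Series(w).groupby(lattice.codes("district")).sum()
    assert np.all(district_sums > 0)


def test_invalid_params_rejected():
    with pytest.raises(ValueError, match="design effect"):
        GenerativeParams(deff=0.5)
    with pytest.raises(ValueError, match="urban"):
        GenerativeParams(n_range_urban=(50, 500), n_range_rural=(60, 200))
    with pytest.raises(ValueError, match="negative spread"):
        GenerativeParams(component_values={"WN_DIST": (-0.1,)})


def test_missing_component_variance_rejected(lattice, graph):
    params = _zero_variance_params(component_values={"WN_DIST": (0.1,)})
    with pytest.raises(ValueError, match="variance specification"):
        mlsae.draw_truth(lattice, graph, params, components=("SP_DIST",))
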