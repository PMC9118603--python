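"""Gibbs sampler: conjugate updates, oracles, determinism, diagnostics."""

import numpy as np
import pytest

import mlsae
from conftest import dense_Z
from mlsae.components import assemble_model, build_component, fixed_design
from mlsae.sampler import (
    PosteriorDraws,
    SamplerConfig,
    run_chains,
    sample_beta,
    sample_effects,
    sample_variances,
)


def _intercept_model(y, sigma2):
    from mlsae.components import FixedDesign

    design = FixedDesign(X=np.ones((len(y), 1)), labels=("intercept",))
    return assemble_model(y, [], design, sigma2)


def test_beta_posterior_mean_is_sample_mean_for_intercept_model():
    rng = np.random.default_rng(0)
    y = rng.standard_normal(30) + 2.0
    model = _intercept_model(y, np.ones(30))
    draws = np.array([sample_beta(model, {}, rng)[0] for _ in range(20000)])
    # GLS identity: posterior N(ybar, 1/n); 3 MC standard errors
    assert abs(draws.mean() - y.mean()) < 3 * draws.std() / np.sqrt(len(draws))
    assert abs(draws.std() - 1 / np.sqrt(30)) < 0.01


def test_beta_montecarlo_matches_closed_form_gls_on_toy():
    rng = np.random.default_rng(1)
    D = 10
    X = np.column_stack([np.ones(D), rng.standard_normal(D)])
    y = rng.standard_normal(D)
    sigma2 = rng.uniform(0.5, 2.0, D)
    from mlsae.components import FixedDesign

    model = assemble_model(y, [], FixedDesign(X=X, labels=("a", "b")), sigma2)
    draws = np.array([sample_beta(model, {}, rng) for _ in range(20000)])
    P = X.T @ (X / sigma2[:, None])
    m = np.linalg.solve(P, X.T @ (y / sigma2))
    mc_se = draws.std(axis=0) / np.sqrt(len(draws))
    assert np.all(np.abs(draws.mean(axis=0) - m) < 3 * mc_se)


def test_doubling_sigma_preserves_mean_and_doubles_covariance():
    rng = np.random.default_rng(2)
    D = 50
    y = rng.standard_normal(D)
    m1 = _intercept_model(y, np.ones(D))
    m2 = _intercept_model(y, 2 * np.ones(D))
    d1 = np.array([sample_beta(m1, {}, np.random.default_rng(s))[0] for s in range(8000)])
    d2 = np.array([sample_beta(m2, {}, np.random.default_rng(s))[0] for s in range(8000)])
    assert abs(d1.mean() - d2.mean()) < 0.02
    assert abs(d2.var() / d1.var() - 2.0) < 0.1


def test_effects_shrink_as_variance_vanishes(small_lattice, small_graph):
    rng = np.random.default_rng(3)
    design = fixed_design(small_lattice)
    comp = build_component("WN_DIST", small_lattice)
    y = rng.standard_normal(small_lattice.n_domains)
    model = assemble_model(y, [comp], design, np.full(small_lattice.n_domains, 0.05))
    beta = np.zeros(design.p)
    norms = []
    for s2 in (1.0, 0.1, 0.01, 0.001, 1e-5):
        draws = [
            np.linalg.norm(
                sample_effects(model, comp, beta, {comp.name: np.zeros(comp.q)},
                               np.array([s2]), rng)
            )
            for _ in range(50)
        ]
        norms.append(np.mean(draws))
    assert all(a > b for a, b in zip(norms, norms[1:]))


def test_spatial_effects_centred_per_draw(small_lattice, small_graph):
    rng = np.random.default_rng(4)
    design = fixed_design(small_lattice)
    comp = build_component("SP_DIST", small_lattice, small_graph)
    y = rng.standard_normal(small_lattice.n_domains)
    model = assemble_model(y, [comp], design, np.full(small_lattice.n_domains, 0.05))
    for _ in range(20):
        v = sample_effects(
            model, comp, np.zeros(design.p), {comp.name: np.zeros(comp.q)},
            np.array([0.1]), rng,
        )
        assert abs(v.sum()) < 1e-10


def test_variance_update_reduces_to_prior_at_zero_effects(small_lattice):
    comp = build_component("WN_DIST", small_lattice, prior_shape=3.0, prior_rate=2.0)
    rng = np.random.default_rng(5)
    # u = 0: inverse-gamma(a0 + l/2, b0); mean = b0 / (a0 + l/2 - 1)
    draws = np.array([sample_variances(comp, np.zeros(comp.q), rng)[0] for _ in range(4000)])
    expected = 2.0 / (3.0 + comp.l / 2 - 1)
    assert abs(draws.mean() - expected) / expected < 0.1


def test_variance_update_rate_uses_half_sum_of_squares(small_lattice):
    comp = build_component("WN_DIST", small_lattice, prior_shape=2.0, prior_rate=1.0)
    rng = np.random.default_rng(6)
    v = np.full(comp.q, 0.2)
    S = float(v @ v)
    draws = np.array([sample_variances(comp, v, rng)[0] for _ in range(4000)])
    shape, rate = 2.0 + comp.l / 2, 1.0 + S / 2
    expected = rate / (shape - 1)  # analytic inverse-gamma mean
    assert abs(draws.mean() - expected) / expected < 0.05


def test_icar_variance_update_uses_car_quadratic_and_reduced_rank(small_lattice, small_graph):
    comp = build_component("SP_DIST", small_lattice, small_graph,
                           prior_shape=2.0, prior_rate=1.0)
    rng = np.random.default_rng(7)
    v = rng.standard_normal(comp.q)
    v -= v.mean()
    quad = float(v @ comp.Q_A @ v)
    draws = np.array([sample_variances(comp, v, rng)[0] for _ in range(4000)])
    shape, rate = 2.0 + (comp.l - 1) / 2, 1.0 + quad / 2
    expected = rate / (shape - 1)
    assert abs(draws.mean() - expected) / expected < 0.05


def test_gibbs_matches_fay_herriot_shrinkage_oracle():
    """Single white-noise component with fixed variances reduces to the
    basic area-level model; the posterior mean of eta must match the
    closed-form shrinkage estimator gamma*y + (1-gamma)*x'beta_gls."""
    rng = np.random.default_rng(8)
    lat = mlsae.example_lattice(5, 1, n_ages=2)  # 5*2*2*2 = 40; use 20 below
    lat20 = mlsae.build_lattice(
        {"district": lat.districts, "age_group": ("0-11",),
         "residence": ("rural", "urban"), "sex": ("female", "male")},
        lat.nesting,
    )
    D = lat20.n_domains
    assert D == 20
    design = fixed_design(lat20)
    comp = build_component("WN_DIST", lat20)
    sigma2_e = rng.uniform(0.01, 0.05, D)
    s2_v = 0.02
    beta_true = rng.standard_normal(design.p) * 0.1
    y = design.X @ beta_true + rng.standard_normal(D) * np.sqrt(s2_v + sigma2_e)
    model = assemble_model(y, [comp], design, sigma2_e)
    config = SamplerConfig(
        n_chains=2, n_iter=6000, n_burn=1000, seed=9,
        sample_variances=False, fixed_variances={"WN_DIST": 0.02},
    )
    draws = run_chains(model, config)
    eta_mean = draws.stacked(draws.eta).mean(axis=0)
    # closed-form oracle
    M = s2_v + sigma2_e
    P = design.X.T @ (design.X / M[:, None])
    beta_gls = np.linalg.solve(P, design.X.T @ (y / M))
    gamma = s2_v / (s2_v + sigma2_e)
    oracle = gamma * y + (1 - gamma) * (design.X @ beta_gls)
    mc_se = draws.stacked(draws.eta).std(axis=0) / np.sqrt(draws.stacked(draws.eta).shape[0] / 10)
    assert np.all(np.abs(eta_mean - oracle) < np.maximum(3 * mc_se, 0.01))


def test_gibbs_matches_dense_joint_gls_oracle():
    """Fixed variances on a 3-district toy: the Gibbs posterior mean of
    (beta, v) must solve the mixed-model equations."""
    rng = np.random.default_rng(10)
    lat = mlsae.example_lattice(3, 1, n_ages=2)
    D = lat.n_domains
    design = fixed_design(lat)
    names = ("AGE_DIST", "WN_DIST")
    comps = [build_component(n, lat) for n in names]
    sigma2_e = rng.uniform(0.01, 0.04, D)
    fixed = {"AGE_DIST": np.array([0.03, 0.05]), "WN_DIST": np.array([0.02])}
    y = rng.standard_normal(D) * 0.3
    model = assemble_model(y, comps, design, sigma2_e)
    config = SamplerConfig(
        n_chains=2, n_iter=8000, n_burn=1000, seed=11,
        sample_variances=False, fixed_variances=fixed,
    )
    draws = run_chains(model, config)
    # dense mixed-model equations oracle
    Zs = [dense_Z(c, D) for c in comps]
    C = np.hstack([design.X] + Zs)
    G_inv = [np.zeros((design.p, design.p))] + [
        c.prior_precision(fixed[c.name]) for c in comps
    ]
    from scipy.linalg import block_diag

    H = C.T @ (C / sigma2_e[:, None]) + block_diag(*G_inv)
    sol = np.linalg.solve(H, C.T @ (y / sigma2_e))
    gibbs_mean = np.concatenate(
        [draws.stacked(draws.beta).mean(axis=0)]
        + [draws.stacked(draws.effects[n]).mean(axis=0) for n in names]
    )
    flat = np.concatenate(
        [draws.stacked(draws.beta)]
        + [draws.stacked(draws.effects[n]) for n in names],
        axis=1,
    )
    mc_se = flat.std(axis=0) / np.sqrt(flat.shape[0] / 20)  # autocorr. slack
    assert np.all(np.abs(gibbs_mean - sol) < np.maximum(3 * mc_se, 0.01))


def test_identical_master_seed_gives_bit_identical_draws(small_lattice, small_graph):
    rng = np.random.default_rng(12)
    design = fixed_design(small_lattice)
    comps = [build_component(n, small_lattice, small_graph) for n in ("SP_DIST", "WN_DIST")]
    y = rng.standard_normal(small_lattice.n_domains) * 0.2
    model = assemble_model(y, comps, design, np.full(small_lattice.n_domains, 0.02))
    config = SamplerConfig(n_chains=2, n_iter=200, n_burn=100, seed=13)
    d1 = run_chains(model, config)
    d2 = run_chains(model, config)
    np.testing.assert_array_equal(d1.beta, d2.beta)
    np.testing.assert_array_equal(d1.eta, d2.eta)
    d3 = run_chains(model, SamplerConfig(n_chains=2, n_iter=200, n_burn=100, seed=14))
    assert not np.array_equal(d1.beta, d3.beta)


def test_eta_draws_reproduce_linear_predictor(small_lattice, small_graph):
    rng = np.random.default_rng(15)
    design = fixed_design(small_lattice)
    comps = [build_component(n, small_lattice, small_graph) for n in ("AGE_DIST", "WN_DIST")]
    y = rng.standard_normal(small_lattice.n_domains) * 0.2
    model = assemble_model(y, comps, design, np.full(small_lattice.n_domains, 0.02))
    draws = run_chains(model, SamplerConfig(n_chains=2, n_iter=60, n_burn=30, seed=16))
    for chain in range(2):
        for s in range(draws.n_draws):
            eta = model.eta(
                draws.beta[chain, s],
                {n: draws.effects[n][chain, s] for n in ("AGE_DIST", "WN_DIST")},
            )
            np.testing.assert_allclose(draws.eta[chain, s], eta, atol=1e-10)
    assert all(np.all(draws.variances[n] > 0) for n in draws.variances)


def test_chains_converge_on_toy_model(small_fit):
    conv = mlsae.convergence(small_fit["fit"].draws)
    beta_rows = conv[conv["parameter"].str.startswith("beta")]
    assert (beta_rows["rhat"] < 1.1).all()


def test_convergence_requires_two_chains():
    draws = PosteriorDraws(
        beta=np.zeros((1, 10, 1)), beta_labels=("intercept",),
        effects={}, variances={}, eta=np.zeros((1, 10, 2)),
    )
    with pytest.raises(ValueError, match="2 chains"):
        mlsae.convergence(draws)


def test_convergence_flags_disjoint_chains_and_passes_identical_ones():
    rng = np.random.default_rng(17)
    chain = rng.standard_normal((1, 400, 1))
    identical = PosteriorDraws(
        beta=np.concatenate([chain, chain]), beta_labels=("b",),
        effects={}, variances={}, eta=np.zeros((2, 400, 1)),
    )
    conv = mlsae.convergence(identical)
    assert conv["rhat"].iloc[0] < 1.01
    disjoint = PosteriorDraws(
        beta=np.concatenate([chain, chain + 50.0]), beta_labels=("b",),
        effects={}, variances={}, eta=np.zeros((2, 400, 1)),
    )
    conv2 = mlsae.convergence(disjoint)
    assert conv2["rhat"].iloc[0] > 1.1


def test_iid_draws_have_ess_near_sample_size():
    rng = np.random.default_rng(18)
    draws = PosteriorDraws(
        beta=rng.standard_normal((2, 1000, 1)), beta_labels=("b",),
        effects={}, variances={}, eta=np.zeros((2, 1000, 1)),
    )
    conv = mlsae.convergence(draws)
    assert abs(conv["ess_bulk"].iloc[0] - 2000) / 2000 < 0.2


def test_draws_roundtrip_through_npz(tmp_path, small_fit):
    draws = small_fit["fit"].draws
    draws.save(tmp_path / "draws")
    again = PosteriorDraws.load(tmp_path / "draws")
    np.testing.assert_array_equal(draws.beta, again.beta)
    np.testing.assert_array_equal(draws.eta, again.eta)
    assert again.beta_labels == draws.beta_labels
    for name in draws.effects:
        np.testing.assert_array_equal(draws.effects[name], again.effects[name])


def test_config_validation():
    with pytest.raises(ValueError):
        SamplerConfig(n_iter=10, n_burn=10)
    with pytest.raises(ValueError):
        SamplerConfig(thin=0)
    with pytest.raises(ValueError):
        SamplerConfig(sample_variances=False)
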