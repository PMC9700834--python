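"""Sampler correctness: determinism, conjugate updates, adaptation
contract, and agreement with independent posterior computations."""

import numpy as np
import pytest

from carmap.cohort import CountTable
from carmap.expected import ExpectedCounts, expected_counts
from carmap.geo import queen_adjacency
from carmap.mcmc import (PosteriorSamples, SamplerConfig, adapt_proposals,
                         conjugate_tau_update, run_mcmc)
from carmap.model import ModelSpec
from carmap.simulate import make_grid_geometry


def _intercept_only_setup(O=42, E=30.0):
    """One zone, one period, intercept-only model."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        A = queen_adjacency(make_grid_geometry(1, 1))
    spec = ModelSpec(adjacency=A, t_codes=np.array([1.0]),
                     include_u=False, include_v=False,
                     include_covariates=False, include_time=False)
    C = CountTable(["Z_0_0"], [1], [[O]], [[100]])
    Eo = ExpectedCounts(["Z_0_0"], [1], [[E]], {})
    return spec, C, Eo


def quadrature_posterior_alpha(O, E, V, grid=20001, span=12.0):
    """Independent oracle: 1-D quadrature of the Poisson x Normal posterior
    of the intercept."""
    center = np.log(O / E) if O > 0 else 0.0
    sd0 = 1.0 / np.sqrt(max(O, 1))
    a = np.linspace(center - span * sd0, center + span * sd0, grid)
    logp = O * (np.log(E) + a) - E * np.exp(a) - 0.5 * a ** 2 / V
    logp -= logp.max()
    w = np.exp(logp)
    w /= w.sum()
    mean = float(a @ w)
    sd = float(np.sqrt(((a - mean) ** 2) @ w))
    return mean, sd


def test_same_seed_bitwise_identical():
    spec, C, Eo = _intercept_only_setup()
    cfg = SamplerConfig(n_chains=2, n_burnin=200, n_iter=400, thin=2, seed=5)
    s1 = run_mcmc(spec, C, Eo, None, cfg)
    s2 = run_mcmc(spec, C, Eo, None, cfg)
    assert np.array_equal(s1.alpha, s2.alpha)
    assert np.array_equal(s1.tau_u, s2.tau_u)


def test_different_seeds_differ():
    spec, C, Eo = _intercept_only_setup()
    cfg1 = SamplerConfig(n_chains=1, n_burnin=100, n_iter=200, thin=1, seed=1)
    cfg2 = SamplerConfig(n_chains=1, n_burnin=100, n_iter=200, thin=1, seed=2)
    assert not np.array_equal(run_mcmc(spec, C, Eo, None, cfg1).alpha,
                              run_mcmc(spec, C, Eo, None, cfg2).alpha)


def test_intercept_posterior_matches_quadrature():
    """The sampler's stationary distribution agrees with 1-D numerical
    quadrature of the exact posterior (detailed-balance smoke test)."""
    spec, C, Eo = _intercept_only_setup(O=42, E=30.0)
    cfg = SamplerConfig(n_chains=2, n_burnin=2000, n_iter=20000, thin=2, seed=17)
    samples = run_mcmc(spec, C, Eo, None, cfg)
    draws = samples.pooled("alpha")
    qmean, qsd = quadrature_posterior_alpha(42, 30.0, spec.V_beta)
    from carmap.diagnostics import mc_error

    mcse = mc_error(draws)["mc_error"]
    assert abs(draws.mean() - qmean) < 3 * mcse
    # SD standard error for a (near-)normal posterior: sd/sqrt(2*ess)
    ess_proxy = draws.size * (mcse and (draws.std() / mcse) ** 2 / draws.size)
    sd_se = qsd / np.sqrt(2 * max(ess_proxy, 10))
    assert abs(draws.std(ddof=1) - qsd) < 3 * sd_se


def test_stored_draw_count_and_sum_zero_constraint(small_fit):
    sim, E, spec, cfg, samples = small_fit
    assert samples.n_draws == cfg.n_iter // cfg.thin
    assert samples.alpha.shape == (cfg.n_chains, cfg.n_iter // cfg.thin)
    assert np.abs(samples.u.sum(axis=2)).max() < 1e-8


def test_incremental_logposterior_matches_full_recompute(small_fit):
    _, _, _, _, samples = small_fit
    assert samples.meta["logpost_check_max_abs_diff"] < 1e-8


def test_invalid_inputs_rejected():
    spec, C, Eo = _intercept_only_setup()
    bad_E = ExpectedCounts(["Z_0_0"], [1], [[0.0]], {})
    cfg = SamplerConfig(n_chains=1, n_burnin=10, n_iter=10, thin=1)
    with pytest.raises(ValueError):
        run_mcmc(spec, C, bad_E, None, cfg)
    with pytest.raises(ValueError):
        SamplerConfig(n_iter=0)


# ------------------------------------------------------ conjugate updates
def test_tau_update_zero_field_is_prior_draw():
    spec, _, _ = _intercept_only_setup()
    a, b = 2.0, 3.0
    rng = np.random.default_rng(0)
    draws = [conjugate_tau_update(np.zeros(1), spec, a, b, rng,
                                  structured=True) for _ in range(4000)]
    # zero quadratic form: Gamma(a + rank/2, b); rank = 1 for the island
    shape, rate = a + 0.5, b
    se = np.sqrt(shape / rate ** 2 / len(draws))
    assert abs(np.mean(draws) - shape / rate) < 3.5 * se


def test_tau_update_two_node_path_moment():
    spec = ModelSpec(adjacency=queen_adjacency(make_grid_geometry(1, 2)),
                     t_codes=np.array([1.0]))
    u = np.array([1.0, -1.0])  # quadform 4
    a, b = 0.5, 0.0005
    rng = np.random.default_rng(1)
    draws = np.array([conjugate_tau_update(u, spec, a, b, rng)
                      for _ in range(20000)])
    shape, rate = a + 0.5, b + 2.0
    se = np.sqrt(shape / rate ** 2 / draws.size)
    assert abs(draws.mean() - shape / rate) < 3.5 * se


def test_tau_update_monotone_in_quadform():
    spec = ModelSpec(adjacency=queen_adjacency(make_grid_geometry(1, 2)),
                     t_codes=np.array([1.0]))
    rng1, rng2 = np.random.default_rng(3), np.random.default_rng(3)
    small = np.mean([conjugate_tau_update(np.array([0.1, -0.1]), spec, 0.5,
                                          0.0005, rng1) for _ in range(2000)])
    large = np.mean([conjugate_tau_update(np.array([2.0, -2.0]), spec, 0.5,
                                          0.0005, rng2) for _ in range(2000)])
    assert large < small


def test_tau_update_unstructured_uses_sum_of_squares():
    spec, _, _ = _intercept_only_setup()
    v = np.array([1.0, 2.0, 3.0])
    rng = np.random.default_rng(2)
    draws = np.array([conjugate_tau_update(v, spec, 1.0, 1.0, rng,
                                           structured=False)
                      for _ in range(20000)])
    shape, rate = 1.0 + 1.5, 1.0 + 7.0
    se = np.sqrt(shape / rate ** 2 / draws.size)
    assert abs(draws.mean() - shape / rate) < 3.5 * se


# ----------------------------------------------------------- adaptation
def test_adapt_direction():
    s = np.array([0.1, 0.1, 0.1])
    up = adapt_proposals(s, np.array([0.9, 0.9, 0.9]), step=0.5)
    down = adapt_proposals(s, np.array([0.05, 0.05, 0.05]), step=0.5)
    hold = adapt_proposals(s, np.full(3, 0.35), step=0.5)
    assert (up > s).all() and (down < s).all()
    assert hold == pytest.approx(s)


def test_scales_frozen_after_burnin(small_fit):
    # acceptance metadata records the final (frozen) scales; a second run
    # with zero extra burn-in from the same config reproduces them exactly
    sim, E, spec, cfg, samples = small_fit
    again = run_mcmc(spec, sim.counts, E, sim.covariates, cfg)
    for a, b in zip(samples.meta["acceptance_rates"],
                    again.meta["acceptance_rates"]):
        assert a["final_scale_fixed"] == b["final_scale_fixed"]


# -------------------------------------------------------- persistence
def test_save_load_round_trip(tmp_path, small_fit):
    _, _, _, _, samples = small_fit
    samples.save(tmp_path / "s")
    back = PosteriorSamples.load(tmp_path / "s")
    assert np.allclose(back.alpha, samples.alpha)
    assert np.allclose(back.u, samples.u)
    assert np.allclose(back.beta, samples.beta)
    assert back.covariate_names == samples.covariate_names


# ------------------------------------------ reduction to plain Poisson GLM
def test_reduces_to_poisson_regression_without_random_effects():
    """With u, v and covariates off, the posterior centres on the ML fit of
    a Poisson regression on log E + alpha + beta1 * t (flat-ish priors)."""
    import statsmodels.api as sm

    rng = np.random.default_rng(21)
    nZ, nK = 6, 3
    n = np.full((nZ, nK), 200)
    t = np.array([1.0, 2.0, 3.0])
    true_alpha, true_b1 = -0.2, 0.15
    E = n * 0.5
    mu = E * np.exp(true_alpha + true_b1 * t[None, :])
    O = rng.poisson(mu)
    C = CountTable([f"Z{i}" for i in range(nZ)], [1, 2, 3], O, n)
    Eo = ExpectedCounts(C.zone_ids, C.periods, E, {})
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        A = queen_adjacency(make_grid_geometry(2, 3))
    spec = ModelSpec(adjacency=A, t_codes=t, include_u=False, include_v=False,
                     include_covariates=False)
    cfg = SamplerConfig(n_chains=2, n_burnin=1500, n_iter=6000, thin=2, seed=4)
    samples = run_mcmc(spec, C, Eo, None, cfg)
    design = np.column_stack([np.ones(nZ * nK),
                              np.tile(t, nZ)])
    glm = sm.GLM(O.reshape(-1), design, family=sm.families.Poisson(),
                 offset=np.log(E).reshape(-1)).fit()
    assert abs(samples.pooled("alpha").mean() - glm.params[0]) < 3 * glm.bse[0]
    assert abs(samples.pooled("beta1").mean() - glm.params[1]) < 3 * glm.bse[1]
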