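"""Log-density kernels of the spatio-temporal Poisson CAR model."""

import numpy as np
import pytest
from scipy.stats import norm, poisson

from carmap.cohort import CountTable, ZoneCovariates
from carmap.expected import ExpectedCounts
from carmap.geo import queen_adjacency
from carmap.model import (ModelSpec, Parameters, icar_logdensity,
                          icar_quadform, linear_predictor, poisson_loglik,
                          prior_logdensity, rr_from_coef)
from carmap.simulate import make_grid_geometry


def _setup(rows=3, cols=3, periods=2, seed=0):
    rng = np.random.default_rng(seed)
    zones = make_grid_geometry(rows, cols)
    A = queen_adjacency(zones)
    nZ = rows * cols
    quart = {"education": rng.integers(1, 5, (nZ, periods)),
             "ses": rng.integers(1, 5, (nZ, periods))}
    X = ZoneCovariates([z.zone_id for z in zones], list(range(1, periods + 1)),
                       quart)
    spec = ModelSpec(adjacency=A, covariate_names=X.column_names,
                     t_codes=np.arange(1.0, periods + 1))
    E = ExpectedCounts(X.zone_ids, X.periods,
                       rng.uniform(5, 50, (nZ, periods)), {})
    n = np.full((nZ, periods), 100)
    O = rng.integers(0, 60, (nZ, periods))
    C = CountTable(X.zone_ids, X.periods, O, n)
    return spec, X, E, C, rng


# ------------------------------------------------------- linear predictor
def test_null_parameters_give_mu_equal_E():
    spec, X, E, C, _ = _setup()
    p = Parameters.zeros(9, 6)
    mu = np.exp(linear_predictor(p, E, X, spec))
    assert mu == pytest.approx(E.E)


def test_intercept_only_scales_E():
    spec, X, E, C, _ = _setup()
    p = Parameters.zeros(9, 6)
    p.alpha = 0.1
    mu = np.exp(linear_predictor(p, E, X, spec))
    assert mu == pytest.approx(E.E * np.exp(0.1))


def test_linear_predictor_against_term_by_term_oracle():
    spec, X, E, C, rng = _setup(seed=3)
    p = Parameters(alpha=rng.normal(), beta1=rng.normal(0, 0.1),
                   beta=rng.normal(0, 0.2, 6),
                   u=rng.normal(0, 0.3, 9), v=rng.normal(0, 0.2, 9),
                   tau_u=1.0, tau_v=1.0)
    eta = linear_predictor(p, E, X, spec)
    for i in range(9):
        for k in range(2):
            manual = (np.log(E.E[i, k]) + p.alpha + p.u[i] + p.v[i]
                      + p.beta1 * spec.t_codes[k]
                      + float(X.X[i, k] @ p.beta))
            assert abs(eta[i, k] - manual) < 1e-12


def test_dimension_mismatch_rejected():
    spec, X, E, C, _ = _setup()
    p = Parameters.zeros(5, 6)  # wrong zone count
    with pytest.raises(ValueError):
        linear_predictor(p, E, X, spec)


# --------------------------------------------------------- Poisson loglik
def test_poisson_loglik_closed_form_zero_count():
    C = CountTable(["a"], [1], [[0]], [[10]])
    assert poisson_loglik(C, np.array([[1.0]])) == pytest.approx(-1.0)


def test_poisson_loglik_matches_scipy_pmf():
    rng = np.random.default_rng(1)
    O = rng.integers(0, 30, (4, 3))
    mu = rng.uniform(0.5, 25, (4, 3))
    C = CountTable(list("abcd"), [1, 2, 3], O, np.full((4, 3), 50))
    expected = poisson.logpmf(O, mu).sum()
    assert poisson_loglik(C, mu) == pytest.approx(expected, rel=1e-12)


def test_poisson_loglik_maximized_at_mu_equals_O():
    O = np.array([[3, 7], [0, 12]])
    C = CountTable(["a", "b"], [1, 2], O, np.full((2, 2), 20))
    mu_hat = np.maximum(O, 1e-8).astype(float)
    best = poisson_loglik(C, mu_hat)
    rng = np.random.default_rng(2)
    for _ in range(25):
        other = mu_hat * np.exp(rng.normal(0, 0.3, O.shape))
        assert poisson_loglik(C, other) <= best + 1e-9


def test_poisson_loglik_skips_empty_cells():
    C = CountTable(["a", "b"], [1], [[5], [0]], [[10], [0]])
    mu = np.array([[5.0], [123.0]])  # second cell must be ignored
    assert poisson_loglik(C, mu) == pytest.approx(poisson.logpmf(5, 5.0))


# -------------------------------------------------------------- ICAR prior
def _spec_for_graph(rows, cols):
    return ModelSpec(adjacency=queen_adjacency(make_grid_geometry(rows, cols)),
                     t_codes=np.array([1.0]))


def test_icar_constant_field_has_zero_quadform():
    spec = _spec_for_graph(2, 3)
    u = np.zeros(6)
    assert icar_quadform(u, spec) == 0.0
    # the kernel is maximal there: any sum-zero perturbation lowers it
    rng = np.random.default_rng(0)
    for _ in range(10):
        z = rng.normal(0, 0.5, 6)
        z -= z.mean()
        assert icar_logdensity(z, 1.0, spec) <= icar_logdensity(u, 1.0, spec)


def test_icar_two_node_path_quadform():
    spec = _spec_for_graph(1, 2)
    u = np.array([1.0, -1.0])
    # single edge: (u1-u2)^2 = 4 -> -(tau/2)*4 = -2
    assert icar_quadform(u, spec) == pytest.approx(4.0)
    assert icar_logdensity(u, 1.0, spec) == pytest.approx(
        0.5 * 1 * np.log(1.0) - 2.0)


def test_icar_kernel_translation_invariant():
    spec = _spec_for_graph(3, 3)
    rng = np.random.default_rng(4)
    u = rng.normal(0, 1, 9)
    assert icar_quadform(u + 5.0, spec) == pytest.approx(icar_quadform(u, spec))


def test_icar_quadform_equals_laplacian_quadratic_form():
    spec = _spec_for_graph(3, 4)
    W = spec.adjacency.weights.astype(float)
    Q = np.diag(W.sum(axis=1)) - W
    rng = np.random.default_rng(7)
    for _ in range(5):
        u = rng.normal(0, 1, 12)
        assert icar_quadform(u, spec) == pytest.approx(u @ Q @ u)


def test_icar_rejects_asymmetric_weights():
    spec = _spec_for_graph(1, 2)
    spec.adjacency.weights = np.array([[0, 1], [0, 0]])
    with pytest.raises(ValueError, match="symmetric"):
        icar_logdensity(np.array([0.5, -0.5]), 1.0, spec)


def test_icar_nonpositive_precision_is_minus_inf():
    spec = _spec_for_graph(1, 2)
    assert icar_logdensity(np.array([0.5, -0.5]), 0.0, spec) == -np.inf


def test_icar_island_rank_counts_island_fully():
    import warnings

    from carmap.geo import ZoneGeometry
    from shapely.geometry import Polygon

    zones = make_grid_geometry(1, 3)
    zones.append(ZoneGeometry("far", Polygon([(9, 9), (10, 9), (10, 10), (9, 10)])))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        spec = ModelSpec(adjacency=queen_adjacency(zones), t_codes=np.array([1.0]))
    _, islands, rank, _ = spec.graph_structure()
    assert list(islands) == [3]
    assert rank == (3 - 1) + 1


# -------------------------------------------------------------- full prior
def test_prior_logdensity_term_by_term_oracle():
    spec, X, E, C, rng = _setup(seed=9)
    p = Parameters(alpha=0.2, beta1=-0.05, beta=rng.normal(0, 0.1, 6),
                   u=np.zeros(9), v=rng.normal(0, 0.3, 9),
                   tau_u=2.0, tau_v=0.5)
    from scipy.stats import gamma as gamma_dist

    manual = sum(norm.logpdf(val, 0, np.sqrt(spec.V_beta))
                 for val in [p.alpha, p.beta1, *p.beta])
    manual += icar_logdensity(p.u, p.tau_u, spec)
    manual += norm.logpdf(p.v, 0, 1 / np.sqrt(p.tau_v)).sum()
    manual += gamma_dist.logpdf(p.tau_u, a=spec.tau_shape,
                                scale=1 / spec.tau_rate)
    manual += gamma_dist.logpdf(p.tau_v, a=spec.tau_shape,
                                scale=1 / spec.tau_rate)
    assert prior_logdensity(p, spec) == pytest.approx(manual, rel=1e-12)


def test_prior_mode_of_beta_terms_at_zero():
    spec, X, E, C, _ = _setup()
    p0 = Parameters.zeros(9, 6)
    base = prior_logdensity(p0, spec)
    p1 = Parameters.zeros(9, 6)
    p1.beta = p1.beta + 5.0
    assert prior_logdensity(p1, spec) < base


def test_prior_nonpositive_precision_minus_inf():
    spec, X, E, C, _ = _setup()
    p = Parameters.zeros(9, 6)
    p.tau_u = -1.0
    assert prior_logdensity(p, spec) == -np.inf


# ------------------------------------------------------------ RR reporting
@pytest.mark.parametrize("coef,rr", [(0.149, 1.16), (-0.094, 0.91), (0.0, 1.0)])
def test_rr_from_coef_reporting_convention(coef, rr):
    assert rr_from_coef(coef) == pytest.approx(rr)


def test_rr_from_coef_vector_and_validation():
    out = rr_from_coef(np.array([0.0, np.log(2)]))
    assert out == pytest.approx([1.0, 2.0])
    with pytest.raises(ValueError):
        rr_from_coef(np.inf)
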