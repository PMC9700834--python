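"""Spatio-temporal Poisson log-linear model with BYM-type random effects.

The model for the anemic count O_ik in zone i, period k is

    O_ik ~ Poisson(mu_ik)
    log mu_ik = log E_ik + alpha + u_i + v_i + beta1 * t_k + x_ik' beta

where E_ik is the internally standardized expected count (an offset),
u is a spatially structured effect with an intrinsic CAR (ICAR) prior on
the queen-contiguity graph, v is an exchangeable Normal(0, 1/tau_v)
effect, t_k is a linear period code (1, 2, 3 by default) and x_ik are the
zone-level quartile indicator covariates.  The ICAR prior is improper;
identifiability comes from the sum-to-zero constraint on u together with
the explicit intercept alpha.

Priors: alpha, beta1 and each beta_j are Normal(0, V_beta); the
precisions tau_u, tau_v carry Gamma(shape a, rate b) hyperpriors.  The
defaults (V_beta = 1e6, a = 0.5, b = 0.0005) are the conventional weakly
informative disease-mapping choices and are config-overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from scipy.stats import gamma as gamma_dist

from .cohort import CountTable, ZoneCovariates
from .expected import ExpectedCounts
from .geo import AdjacencyMatrix


@dataclass
class ModelSpec:
    """Model structure: adjacency, design layout, time codes and priors.

    The include_* flags implement the DIC model ladder (null model without
    covariates up to the full convolution model).
    """

    adjacency: AdjacencyMatrix
    covariate_names: list[str] = field(default_factory=list)
    t_codes: np.ndarray = field(default_factory=lambda: np.array([1.0, 2.0, 3.0]))
    V_beta: float = 1e6
    tau_shape: float = 0.5
    tau_rate: float = 0.0005
    include_u: bool = True
    include_v: bool = True
    include_covariates: bool = True
    include_time: bool = True

    def __post_init__(self) -> None:
        self.t_codes = np.asarray(self.t_codes, dtype=float)
        if self.V_beta <= 0 or self.tau_shape <= 0 or self.tau_rate <= 0:
            raise ValueError("prior hyperparameters must be positive")
        if (np.diff(self.t_codes) <= 0).any():
            raise ValueError("time codes must be strictly increasing")

    # --- derived graph quantities, computed once -------------------------
    @property
    def n_zones(self) -> int:
        return self.adjacency.n

    def graph_structure(self):
        """(row sums m_i, island index array, ICAR rank r, Laplacian D - W).

        Islands (no neighbours) get an exchangeable Normal(0, 1/tau_u)
        prior in place of the undefined ICAR conditional, so each island
        contributes full rank 1 while a connected component of size s
        contributes s - 1.
        """
        W = self.adjacency.weights.astype(float)
        m = W.sum(axis=1)
        islands = np.flatnonzero(m == 0)
        comps = self.adjacency.components()
        rank = sum(max(len(c) - 1, 1) for c in comps)
        L = np.diag(m) - W
        return m, islands, rank, L


@dataclass
class Parameters:
    """One state of the model's unknowns."""

    alpha: float
    beta1: float
    beta: np.ndarray
    u: np.ndarray
    v: np.ndarray
    tau_u: float
    tau_v: float

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)

    @classmethod
    def zeros(cls, n_zones: int, n_beta: int) -> "Parameters":
        return cls(0.0, 0.0, np.zeros(n_beta), np.zeros(n_zones),
                   np.zeros(n_zones), 1.0, 1.0)


def linear_predictor(p: Parameters, E: ExpectedCounts, X: ZoneCovariates | None,
                     spec: ModelSpec | None = None) -> np.ndarray:
    """log mu_ik = log E_ik + alpha + u_i + v_i + beta1 t_k + x_ik' beta.

    Returns the full (n_zones, n_periods) array of log means.  Components
    switched off in ``spec`` are omitted.
    """
    Ea = np.asarray(E.E, dtype=float)
    if (Ea <= 0).any():
        raise ValueError("expected counts must be positive")
    n_zones, n_periods = Ea.shape
    if p.u.shape != (n_zones,) or p.v.shape != (n_zones,):
        raise ValueError("random-effect length does not match zone count")
    t = spec.t_codes if spec is not None else np.arange(1, n_periods + 1, dtype=float)
    if t.shape != (n_periods,):
        raise ValueError("time codes do not match period count")
    eta = np.log(Ea) + p.alpha
    if spec is None or spec.include_u:
        eta = eta + p.u[:, None]
    if spec is None or spec.include_v:
        eta = eta + p.v[:, None]
    if spec is None or spec.include_time:
        eta = eta + p.beta1 * t[None, :]
    if (spec is None or spec.include_covariates) and X is not None and p.beta.size:
        if X.X.shape[2] != p.beta.size:
            raise ValueError("beta length does not match covariate columns")
        eta = eta + X.X @ p.beta
    return eta


def poisson_loglik(C: CountTable, mu: np.ndarray) -> float:
    """Poisson log-likelihood sum_ik [O log mu - mu - log O!].

    Cells with n = 0 (no children examined) carry no information and are
    skipped.
    """
    O = np.asarray(C.O, dtype=float)
    if (O < 0).any():
        raise ValueError("negative observed counts")
    mask = C.n > 0
    mu = np.asarray(mu, dtype=float)
    if (mu[mask] <= 0).any():
        raise ValueError("non-positive Poisson mean at an observed cell")
    o = O[mask]
    m = mu[mask]
    return float(np.sum(o * np.log(m) - m - gammaln(o + 1.0)))


def icar_quadform(u: np.ndarray, spec: ModelSpec) -> float:
    """sum_{i<j} w_ij (u_i - u_j)^2 plus sum of u_i^2 over islands.

    Equals u' (D - W) u + island terms; the island squares come from their
    exchangeable Normal(0, 1/tau_u) stand-in prior.
    """
    _, islands, _, L = spec.graph_structure()
    q = float(u @ (L @ u))
    if islands.size:
        q += float(np.sum(u[islands] ** 2))
    return q


def icar_logdensity(u: np.ndarray, tau_u: float, spec: ModelSpec,
                    sum_tol: float = 1e-6) -> float:
    """Unnormalized intrinsic-CAR log density of the structured effect.

    (r/2) log tau_u - (tau_u/2) * quadratic form, where the rank r counts
    size-1 per connected component below its size (islands contribute 1 via
    their normal stand-in).  The kernel depends on u only through pairwise
    differences, hence is invariant to adding a constant (the reason for the
    sum-to-zero constraint).
    """
    W = spec.adjacency.weights
    if not np.array_equal(W, W.T):
        raise ValueError("adjacency matrix is not symmetric")
    if tau_u <= 0:
        return -np.inf
    u = np.asarray(u, dtype=float)
    if abs(u.sum()) > sum_tol * max(1.0, np.abs(u).max() * u.size):
        raise ValueError(f"u must sum to zero (got {u.sum():g})")
    _, _, rank, _ = spec.graph_structure()
    return 0.5 * rank * np.log(tau_u) - 0.5 * tau_u * icar_quadform(u, spec)


def prior_logdensity(p: Parameters, spec: ModelSpec) -> float:
    """Joint log prior: normal fixed effects, ICAR u, iid normal v, gamma
    precisions.  Returns -inf for non-positive precisions."""
    if p.tau_u <= 0 or p.tau_v <= 0:
        return -np.inf
    lp = 0.0
    V = spec.V_beta
    fixed = [p.alpha]
    if spec.include_time:
        fixed.append(p.beta1)
    if spec.include_covariates:
        fixed.extend(np.atleast_1d(p.beta))
    for val in fixed:
        lp += -0.5 * np.log(2 * np.pi * V) - 0.5 * val * val / V
    if spec.include_u:
        lp += icar_logdensity(p.u, p.tau_u, spec)
        lp += gamma_dist.logpdf(p.tau_u, a=spec.tau_shape,
                                scale=1.0 / spec.tau_rate)
    if spec.include_v:
        n = p.v.size
        lp += 0.5 * n * np.log(p.tau_v) - 0.5 * n * np.log(2 * np.pi) \
            - 0.5 * p.tau_v * float(np.sum(p.v ** 2))
        lp += gamma_dist.logpdf(p.tau_v, a=spec.tau_shape,
                                scale=1.0 / spec.tau_rate)
    return float(lp)


def log_posterior(p: Parameters, spec: ModelSpec, C: CountTable,
                  E: ExpectedCounts, X: ZoneCovariates | None) -> float:
    """Unnormalized log posterior = Poisson log-likelihood + log prior."""
    mu = np.exp(linear_predictor(p, E, X, spec))
    return poisson_loglik(C, mu) + prior_logdensity(p, spec)


def rr_from_coef(coef, decimals: int = 2):
    """Relative risk exp(coef), rounded to the reporting precision.

    Accepts a scalar or an array (e.g. a posterior mean with credible
    bounds); the relative-risk scale is how areal log-linear coefficients
    are reported.
    """
    arr = np.asarray(coef, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("coefficient must be finite")
    out = np.round(np.exp(arr), decimals)
    return float(out) if np.isscalar(coef) or arr.ndim == 0 else out
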