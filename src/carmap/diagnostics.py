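"""Convergence diagnostics and DIC model comparison.

Gelman-Rubin is the classic (non-rank-normalized) potential scale
reduction factor; MC error uses the batch-means estimator with a pass
flag at the conventional "< 5% of the posterior SD" rule; DIC follows the
classic plug-in definition DIC = Dbar + pD with pD = Dbar - D(theta-bar)
evaluated at the posterior means of the natural-scale parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CountTable, ZoneCovariates
from .expected import ExpectedCounts
from .mcmc import PosteriorSamples
from .model import ModelSpec, Parameters, linear_predictor, poisson_loglik


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor R-hat from >= 2 equal-length chains.

    R-hat = sqrt( ((n-1)/n * W + B/n) / W ) with W the mean within-chain
    variance and B = n * var(chain means).  Returns NaN (flagged undefined)
    when the within-chain variance is zero.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2 or chains.shape[1] < 2:
        raise ValueError("need >= 2 chains of length >= 2")
    m, n = chains.shape
    W = chains.var(axis=1, ddof=1).mean()
    B = n * chains.mean(axis=1).var(ddof=1)
    if W == 0:
        return float("nan")
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def mc_error(draws: np.ndarray, n_batches: int = 20) -> dict:
    """Batch-means Monte Carlo standard error and its ratio to the
    posterior SD.  The 'passed' flag applies the ratio < 0.05 rule."""
    draws = np.asarray(draws, dtype=float).reshape(-1)
    if n_batches < 10:
        raise ValueError("need at least 10 batches")
    if draws.size < n_batches:
        raise ValueError(f"too few draws ({draws.size}) for {n_batches} batches")
    size = draws.size // n_batches
    batches = draws[: size * n_batches].reshape(n_batches, size).mean(axis=1)
    mcse = float(batches.std(ddof=1) / np.sqrt(n_batches))
    sd = float(draws.std(ddof=1))
    ratio = mcse / sd if sd > 0 else 0.0
    return {"mc_error": mcse, "sd": sd, "ratio": ratio, "passed": ratio < 0.05}


def autocorrelation(draws: np.ndarray, max_lag: int = 20) -> np.ndarray:
    """Sample autocorrelation at lags 0..max_lag (lag 0 is 1)."""
    x = np.asarray(draws, dtype=float).reshape(-1)
    if x.size <= max_lag:
        raise ValueError("series shorter than max lag")
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0:
        return np.r_[1.0, np.zeros(max_lag)]
    acf = np.empty(max_lag + 1)
    acf[0] = 1.0
    for lag in range(1, max_lag + 1):
        acf[lag] = float(x[:-lag] @ x[lag:]) / denom
    return acf


@dataclass
class DicResult:
    Dbar: float
    D_at_mean: float
    pD: float
    DIC: float

    def as_dict(self) -> dict:
        return {"Dbar": self.Dbar, "D_at_mean": self.D_at_mean,
                "pD": self.pD, "DIC": self.DIC}


def deviance(p: Parameters, spec: ModelSpec, C: CountTable,
             E: ExpectedCounts, X: ZoneCovariates | None) -> float:
    """D(theta) = -2 * Poisson log-likelihood at one parameter state."""
    mu = np.exp(linear_predictor(p, E, X, spec))
    return -2.0 * poisson_loglik(C, mu)


def dic(samples: PosteriorSamples, C: CountTable, E: ExpectedCounts,
        X: ZoneCovariates | None, spec: ModelSpec) -> DicResult:
    """Deviance information criterion from stored draws.

    Dbar is the posterior mean deviance; D(theta-bar) plugs in the posterior
    means of alpha, beta1, beta, u, v (u recentred with its mean folded into
    alpha); pD = Dbar - D(theta-bar); DIC = Dbar + pD.
    """
    if samples.n_draws < 1:
        raise ValueError("need at least one stored draw")
    log_rr = samples.log_rr_draws()                 # (draws, zones, periods)
    logE = np.log(np.asarray(E.E, dtype=float))
    mask = C.n > 0
    O = np.where(mask, C.O.astype(float), 0.0)
    from scipy.special import gammaln

    const = float(np.sum(gammaln(O[mask] + 1.0)))
    eta = log_rr + logE[None, :, :]
    mu = np.exp(eta)
    ll = (O[None] * eta - np.where(mask[None], mu, 0.0)).sum(axis=(1, 2)) - const
    if not np.isfinite(ll).all():
        bad = int(np.flatnonzero(~np.isfinite(ll))[0])
        raise ValueError(f"non-finite deviance at draw {bad}")
    Dbar = float(np.mean(-2.0 * ll))
    pbar = samples.posterior_mean_parameters()
    D_hat = deviance(pbar, spec, C, E, X)
    return DicResult(Dbar, D_hat, Dbar - D_hat, Dbar + (Dbar - D_hat))


def overdispersion_check(C: CountTable) -> dict:
    """Compare mean and variance of the observed counts (Poisson-ness)."""
    O = C.O[C.n > 0].astype(float)
    if O.size == 0:
        raise ValueError("empty count table")
    mean = float(O.mean())
    var = float(O.var(ddof=1)) if O.size > 1 else 0.0
    return {"mean": mean, "variance": var,
            "ratio": var / mean if mean > 0 else 0.0}


@dataclass
class DiagnosticsReport:
    """Per-parameter convergence summaries plus model-level DIC."""

    parameters: pd.DataFrame
    dic: DicResult | None = None
    notes: list[str] = field(default_factory=list)

    def all_converged(self, rhat_limit: float = 1.1) -> bool:
        r = self.parameters["rhat"].dropna()
        return bool((r < rhat_limit).all()
                    and self.parameters["mc_ratio_passed"].all())


def diagnostics_report(samples: PosteriorSamples,
                       C: CountTable | None = None,
                       E: ExpectedCounts | None = None,
                       X: ZoneCovariates | None = None,
                       spec: ModelSpec | None = None,
                       max_lag: int = 20,
                       include_random_effects: bool = False) -> DiagnosticsReport:
    """Assemble R-hat, MC error and lag-1 autocorrelation for every scalar
    parameter (random effects optional), plus DIC when the data are given."""
    rows = []
    names: list[tuple[str, str, int | None]] = [
        ("alpha", "alpha", None), ("beta1", "beta1", None),
        ("tau_u", "tau_u", None), ("tau_v", "tau_v", None)]
    names += [(samples.covariate_names[j], "beta", j)
              for j in range(len(samples.covariate_names))]
    if include_random_effects:
        names += [(f"u[{z}]", "u", i) for i, z in enumerate(samples.zone_ids)]
        names += [(f"v[{z}]", "v", i) for i, z in enumerate(samples.zone_ids)]
    for label, attr, idx in names:
        ch = samples.scalar_chains(attr, idx)
        pooled = ch.reshape(-1)
        rhat = gelman_rubin(ch) if ch.shape[0] >= 2 else np.nan
        mce = mc_error(pooled) if pooled.size >= 20 else {
            "mc_error": np.nan, "sd": float(pooled.std(ddof=1)),
            "ratio": np.nan, "passed": False}
        lag1 = (autocorrelation(pooled, max_lag=1)[1]
                if pooled.size > 1 else np.nan)
        rows.append({"parameter": label, "mean": float(pooled.mean()),
                     "sd": mce["sd"], "rhat": rhat, "mc_error": mce["mc_error"],
                     "mc_ratio": mce["ratio"], "mc_ratio_passed": mce["passed"],
                     "acf_lag1": lag1})
    report = DiagnosticsReport(parameters=pd.DataFrame(rows))
    if C is not None and E is not None and spec is not None:
        report.dic = dic(samples, C, E, X, spec)
    return report
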