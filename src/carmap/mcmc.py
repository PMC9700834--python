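"""Metropolis-within-Gibbs sampler for the spatio-temporal CAR model.

Update sweep: adaptive single-site random-walk Metropolis for every
structured effect u_i (against Poisson likelihood x ICAR full
conditional), recentring u to sum zero afterwards; the same for every
unstructured effect v_i; random-walk Metropolis for the fixed effects
alpha, beta1 and each beta_j; and exact conjugate Gibbs draws for the
precisions tau_u and tau_v.

The u updates are grouped by a greedy colouring of the contiguity graph:
zones of one colour share no edge, so their ICAR full conditionals do not
involve each other and the whole colour class can be proposed and
accepted in a single vectorized step -- a composition of valid
single-site kernels.  All v sites are conditionally independent and
update in one vectorized step.

Proposal scales adapt toward a 0.35 acceptance rate during burn-in only
and are frozen afterwards, preserving the stationary distribution of the
retained chain.  Runs are deterministic given the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .cohort import CountTable, ZoneCovariates
from .expected import ExpectedCounts
from .model import ModelSpec, Parameters, log_posterior, poisson_loglik, prior_logdensity

TARGET_ACCEPT = 0.35


@dataclass
class SamplerConfig:
    """MCMC run configuration.

    The desk-scale defaults (2 chains x 5,000 burn-in + 20,000 retained
    sweeps, thin 10) keep a full fit to seconds; a fidelity preset with
    100,000 burn-in, 1,000,000 iterations and thin 10 matches the original
    survey-scale analysis and is available through the pipeline config.
    """

    n_chains: int = 2
    n_burnin: int = 5000
    n_iter: int = 20000
    thin: int = 10
    seed: int = 0
    init_spread: float = 0.5
    initial_scale: float = 0.1
    adapt_window: int = 50
    check_every: int = 1000

    def __post_init__(self) -> None:
        if min(self.n_chains, self.n_iter, self.thin) < 1 or self.n_burnin < 0:
            raise ValueError("chain/iteration counts must be positive, thin >= 1")


@dataclass
class PosteriorSamples:
    """Thinned posterior draws plus everything needed to reconstruct
    per-draw fitted surfaces (time codes, covariate design, zone order)."""

    zone_ids: list[str]
    periods: list
    t_codes: np.ndarray
    X: np.ndarray                    # (n_zones, n_periods, p)
    covariate_names: list[str]
    alpha: np.ndarray                # (chains, draws)
    beta1: np.ndarray                # (chains, draws)
    beta: np.ndarray                 # (chains, draws, p)
    u: np.ndarray                    # (chains, draws, n_zones)
    v: np.ndarray                    # (chains, draws, n_zones)
    tau_u: np.ndarray                # (chains, draws)
    tau_v: np.ndarray                # (chains, draws)
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_draws(self) -> int:
        return self.alpha.shape[1]

    def scalar_chains(self, name: str, index: int | None = None) -> np.ndarray:
        """Per-chain draw matrix for one scalar parameter (for diagnostics)."""
        if name == "beta":
            return self.beta[:, :, index]
        arr = getattr(self, name)
        if arr.ndim == 3:
            return arr[:, :, index]
        return arr

    def parameter_names(self) -> list[str]:
        names = ["alpha", "beta1", *self.covariate_names, "tau_u", "tau_v"]
        names += [f"u[{z}]" for z in self.zone_ids]
        names += [f"v[{z}]" for z in self.zone_ids]
        return names

    def pooled(self, name: str, index: int | None = None) -> np.ndarray:
        """All chains concatenated for one scalar parameter."""
        return self.scalar_chains(name, index).reshape(-1)

    def log_rr_draws(self) -> np.ndarray:
        """(total_draws, n_zones, n_periods) array of per-draw log relative
        risks: alpha + u_i + v_i + beta1 t_k + x_ik' beta."""
        a = self.alpha.reshape(-1)
        b1 = self.beta1.reshape(-1)
        b = self.beta.reshape(a.size, self.beta.shape[-1])
        u = self.u.reshape(-1, self.u.shape[-1])
        v = self.v.reshape(-1, self.v.shape[-1])
        base = (u + v)[:, :, None] + a[:, None, None] \
            + b1[:, None, None] * self.t_codes[None, None, :]
        if b.shape[1]:
            base = base + np.einsum("ikp,dp->dik", self.X, b)
        return base

    def posterior_mean_parameters(self) -> Parameters:
        """Posterior means of all parameters pooled over chains (u recentred,
        its mean folded into alpha), for the DIC plug-in deviance."""
        u = self.u.reshape(-1, self.u.shape[-1]).mean(axis=0)
        v = self.v.reshape(-1, self.v.shape[-1]).mean(axis=0)
        alpha = float(self.alpha.mean()) + float(u.mean())
        u = u - u.mean()
        return Parameters(
            alpha=alpha,
            beta1=float(self.beta1.mean()),
            beta=self.beta.reshape(self.alpha.size,
                                   self.beta.shape[-1]).mean(axis=0),
            u=u, v=v,
            tau_u=float(self.tau_u.mean()), tau_v=float(self.tau_v.mean()),
        )

    # ------------------------------------------------------------------
    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table (chain, draw, parameter, value)."""
        rows = []
        for c in range(self.n_chains):
            for d in range(self.n_draws):
                rows.append((c, d, "alpha", self.alpha[c, d]))
                rows.append((c, d, "beta1", self.beta1[c, d]))
                for j, name in enumerate(self.covariate_names):
                    rows.append((c, d, name, self.beta[c, d, j]))
                rows.append((c, d, "tau_u", self.tau_u[c, d]))
                rows.append((c, d, "tau_v", self.tau_v[c, d]))
                for i, z in enumerate(self.zone_ids):
                    rows.append((c, d, f"u[{z}]", self.u[c, d, i]))
                    rows.append((c, d, f"v[{z}]", self.v[c, d, i]))
        return pd.DataFrame(rows, columns=["chain", "draw", "parameter", "value"])

    def save(self, directory) -> None:
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_long_frame().to_csv(directory / "samples.csv", index=False)
        manifest = {
            "zone_ids": self.zone_ids,
            "periods": [str(p) for p in self.periods],
            "t_codes": self.t_codes.tolist(),
            "covariate_names": self.covariate_names,
            "X": self.X.tolist(),
            "meta": _jsonable(self.meta),
        }
        with open(directory / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)

    @classmethod
    def load(cls, directory) -> "PosteriorSamples":
        from pathlib import Path

        directory = Path(directory)
        with open(directory / "manifest.json") as fh:
            man = json.load(fh)
        df = pd.read_csv(directory / "samples.csv")
        zone_ids = man["zone_ids"]
        cov = man["covariate_names"]
        chains = sorted(df["chain"].unique())
        draws = sorted(df["draw"].unique())
        nC, nD, nZ, nP = len(chains), len(draws), len(zone_ids), len(cov)
        wide = df.pivot_table(index=["chain", "draw"], columns="parameter",
                              values="value", sort=False)
        out = cls(
            zone_ids=zone_ids, periods=man["periods"],
            t_codes=np.asarray(man["t_codes"], dtype=float),
            X=np.asarray(man["X"], dtype=float), covariate_names=cov,
            alpha=wide["alpha"].to_numpy().reshape(nC, nD),
            beta1=wide["beta1"].to_numpy().reshape(nC, nD),
            beta=(np.stack([wide[c].to_numpy() for c in cov], axis=-1)
                  .reshape(nC, nD, nP) if cov else np.zeros((nC, nD, 0))),
            u=np.stack([wide[f"u[{z}]"].to_numpy() for z in zone_ids],
                       axis=-1).reshape(nC, nD, nZ),
            v=np.stack([wide[f"v[{z}]"].to_numpy() for z in zone_ids],
                       axis=-1).reshape(nC, nD, nZ),
            tau_u=wide["tau_u"].to_numpy().reshape(nC, nD),
            tau_v=wide["tau_v"].to_numpy().reshape(nC, nD),
            meta=man.get("meta", {}),
        )
        return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def conjugate_tau_update(x: np.ndarray, spec: ModelSpec, a: float, b: float,
                         rng: np.random.Generator,
                         structured: bool = True) -> float:
    """Exact Gibbs draw of a precision from its Gamma full conditional.

    Structured (ICAR) effect: shape a + r/2, rate b + quadform/2 with r the
    ICAR rank and the quadratic form the pairwise-difference sum (plus
    island squares).  Unstructured effect: shape a + n/2, rate b + sum x^2/2.
    """
    from .model import icar_quadform

    x = np.asarray(x, dtype=float)
    if structured:
        _, _, rank, _ = spec.graph_structure()
        shape = a + 0.5 * rank
        rate = b + 0.5 * icar_quadform(x, spec)
    else:
        shape = a + 0.5 * x.size
        rate = b + 0.5 * float(np.sum(x ** 2))
    return float(rng.gamma(shape, 1.0 / rate))


def adapt_proposals(scales: np.ndarray, accept_rate: np.ndarray,
                    step: float, target: float = TARGET_ACCEPT,
                    band: float = 0.0) -> np.ndarray:
    """Robbins-Monro-style proposal-scale adaptation toward the target
    acceptance rate: scale <- scale * exp(step * (rate - target)).  Rates
    inside +/- band of the target leave the scale unchanged.  Used during
    burn-in only."""
    scales = np.asarray(scales, dtype=float)
    rate = np.asarray(accept_rate, dtype=float)
    delta = rate - target
    if band > 0:
        delta = np.where(np.abs(delta) <= band, 0.0, delta)
    return scales * np.exp(step * delta)


def _color_classes(W: np.ndarray) -> list[np.ndarray]:
    g = nx.from_numpy_array(W)
    coloring = nx.greedy_color(g, strategy="largest_first")
    ncol = max(coloring.values()) + 1 if coloring else 1
    return [np.array([i for i, c in coloring.items() if c == col], dtype=int)
            for col in range(ncol)]


class _ChainState:
    """Mutable state of one chain with cached eta/mu and incremental
    log-posterior bookkeeping."""

    def __init__(self, params: Parameters, spec: ModelSpec, C: CountTable,
                 E: ExpectedCounts, X: ZoneCovariates | None):
        from .model import linear_predictor

        self.p = params
        self.spec = spec
        Earr = np.asarray(E.E, dtype=float)
        self.mask = (C.n > 0)
        if (Earr[self.mask] <= 0).any():
            raise ValueError("expected counts must be positive in every "
                             "populated cell")
        self.logE = np.log(np.where(self.mask, Earr, 1.0))
        self.O = C.O.astype(float)
        self.Om = np.where(self.mask, self.O, 0.0)
        self.eta = linear_predictor(params, E, X, spec)
        self.mu = np.where(self.mask, np.exp(self.eta), 0.0)
        ll = poisson_loglik(C, np.where(self.mask, self.mu, 1.0))
        lp = prior_logdensity(params, spec)
        if not math.isfinite(ll):
            raise ValueError("non-finite Poisson log-likelihood at initial state")
        if not math.isfinite(lp):
            raise ValueError("non-finite log prior at initial state")
        self.logpost = ll + lp


def run_mcmc(spec: ModelSpec, C: CountTable, E: ExpectedCounts,
             X: ZoneCovariates | None, cfg: SamplerConfig) -> PosteriorSamples:
    """Fit the model; returns thinned draws from every chain.

    Deterministic given ``cfg.seed``.  Raises if the posterior is non-finite
    at an initial state.
    """
    nZ, nK = C.O.shape
    t = spec.t_codes
    if t.shape != (nK,):
        raise ValueError("time codes do not match period count")
    Xarr = (X.X if (X is not None and spec.include_covariates)
            else np.zeros((nZ, nK, 0)))
    cov_names = (list(X.column_names) if (X is not None and spec.include_covariates)
                 else [])
    nB = Xarr.shape[2]
    n_store = cfg.n_iter // cfg.thin

    m, islands, rank, L = spec.graph_structure()
    W = spec.adjacency.weights.astype(float)
    island_mask = np.zeros(nZ, dtype=bool)
    island_mask[islands] = True
    colors = _color_classes(W) if spec.include_u else []

    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
    store = {k: np.zeros((cfg.n_chains, n_store)) for k in
             ("alpha", "beta1", "tau_u", "tau_v")}
    store["beta"] = np.zeros((cfg.n_chains, n_store, nB))
    store["u"] = np.zeros((cfg.n_chains, n_store, nZ))
    store["v"] = np.zeros((cfg.n_chains, n_store, nZ))
    accept_rates: list[dict] = []
    check_diffs: list[float] = []

    for c in range(cfg.n_chains):
        rng = np.random.default_rng(seeds[c])
        params = _initial_params(c, nZ, nB, cfg, rng)
        st = _ChainState(params, spec, C, E, X)
        _run_chain(st, spec, C, E, X, Xarr, cfg, rng, colors, m, W,
                   island_mask, rank, store, c, accept_rates, check_diffs)

    meta = {
        "config": vars(cfg).copy(),
        "acceptance_rates": accept_rates,
        "logpost_check_max_abs_diff": max(check_diffs) if check_diffs else 0.0,
        "include_u": spec.include_u, "include_v": spec.include_v,
        "include_covariates": spec.include_covariates,
    }
    return PosteriorSamples(
        zone_ids=list(C.zone_ids), periods=list(C.periods), t_codes=t.copy(),
        X=Xarr.copy(), covariate_names=cov_names,
        alpha=store["alpha"], beta1=store["beta1"], beta=store["beta"],
        u=store["u"], v=store["v"], tau_u=store["tau_u"],
        tau_v=store["tau_v"], meta=meta)


def _initial_params(chain: int, nZ: int, nB: int, cfg: SamplerConfig,
                    rng: np.random.Generator) -> Parameters:
    """Chain 1 starts at zeros (precisions 1); later chains start
    over-dispersed relative to the posterior scale."""
    if chain == 0:
        return Parameters.zeros(nZ, nB)
    s = cfg.init_spread
    u = rng.normal(0.0, 0.5 * s, nZ)
    u -= u.mean()
    return Parameters(
        alpha=float(rng.uniform(-s, s)), beta1=float(rng.uniform(-s, s)),
        beta=rng.uniform(-s, s, nB), u=u, v=rng.normal(0.0, 0.5 * s, nZ),
        tau_u=float(np.exp(rng.uniform(-np.log(10), np.log(10)))),
        tau_v=float(np.exp(rng.uniform(-np.log(10), np.log(10)))),
    )


def _run_chain(st, spec, C, E, X, Xarr, cfg, rng, colors, m, W, island_mask,
               rank, store, chain, accept_rates, check_diffs):
    nZ, nK = st.O.shape
    nB = Xarr.shape[2]
    t = spec.t_codes
    a, b = spec.tau_shape, spec.tau_rate
    V = spec.V_beta
    Osum_z = st.Om.sum(axis=1)               # per-zone (masked) counts
    Osum_k = st.Om.sum(axis=0)
    O_tot = st.Om.sum()
    OX = np.array([(st.Om * Xarr[:, :, j]).sum() for j in range(nB)])
    Xmask = [Xarr[:, :, j] > 0 for j in range(nB)]

    quad_u = _quadform(st.p.u, W, island_mask)
    sum_v2 = float(np.sum(st.p.v ** 2))

    scale_u = np.full(nZ, cfg.initial_scale)
    scale_v = np.full(nZ, cfg.initial_scale)
    scale_f = np.full(2 + nB, cfg.initial_scale)  # alpha, beta1, betas
    acc_u = np.zeros(nZ)
    acc_v = np.zeros(nZ)
    acc_f = np.zeros(2 + nB)
    window_n = 0
    window_idx = 0
    thin_c = 0
    stored = 0

    total_sweeps = cfg.n_burnin + cfg.n_iter
    post_acc_f = np.zeros(2 + nB)
    post_n = 0

    for sweep in range(total_sweeps):
        burnin = sweep < cfg.n_burnin
        p = st.p

        # --- structured effects u, vectorized by colour class ----------
        if spec.include_u:
            for idx in colors:
                d = scale_u[idx] * rng.standard_normal(idx.size)
                ed = np.exp(d)
                mu_rows = st.mu[idx]
                dll = d * Osum_z[idx] - mu_rows.sum(axis=1) * (ed - 1.0)
                s_i = W[idx] @ p.u
                ui = p.u[idx]
                uin = ui + d
                dq = np.where(island_mask[idx],
                              uin ** 2 - ui ** 2,
                              m[idx] * (uin ** 2 - ui ** 2) - 2.0 * d * s_i)
                dlp = dll - 0.5 * p.tau_u * dq
                acc = np.log(rng.random(idx.size)) < dlp
                if acc.any():
                    ai = idx[acc]
                    p.u[ai] += d[acc]
                    st.eta[ai] += d[acc, None]
                    st.mu[ai] *= ed[acc, None]
                    st.logpost += float(dlp[acc].sum())
                    quad_u += float(dq[acc].sum())
                if burnin:
                    acc_u[idx] += acc
            # recentre u, folding the mean into alpha (eta unchanged)
            ubar = p.u.mean()
            if ubar != 0.0:
                old_alpha = p.alpha
                p.u -= ubar
                p.alpha += ubar
                st.logpost += -0.5 * (p.alpha ** 2 - old_alpha ** 2) / V
                if island_mask.any():
                    new_quad = _quadform(p.u, W, island_mask)
                    st.logpost += -0.5 * p.tau_u * (new_quad - quad_u)
                    quad_u = new_quad

        # --- unstructured effects v, all sites at once ------------------
        if spec.include_v:
            d = scale_v * rng.standard_normal(nZ)
            ed = np.exp(d)
            dll = d * Osum_z - st.mu.sum(axis=1) * (ed - 1.0)
            dq = (p.v + d) ** 2 - p.v ** 2
            dlp = dll - 0.5 * p.tau_v * dq
            acc = np.log(rng.random(nZ)) < dlp
            if acc.any():
                p.v[acc] += d[acc]
                st.eta[acc] += d[acc, None]
                st.mu[acc] *= ed[acc, None]
                st.logpost += float(dlp[acc].sum())
                sum_v2 += float(dq[acc].sum())
            if burnin:
                acc_v += acc

        # --- fixed effects ----------------------------------------------
        # alpha
        d = scale_f[0] * rng.standard_normal()
        ed = math.exp(d)
        dlp = d * O_tot - st.mu.sum() * (ed - 1.0) \
            - 0.5 * ((p.alpha + d) ** 2 - p.alpha ** 2) / V
        if math.log(rng.random()) < dlp:
            p.alpha += d
            st.eta += d
            st.mu *= ed
            st.logpost += dlp
            acc_f[0] += 1
            if not burnin:
                post_acc_f[0] += 1
        # beta1 (time slope)
        if spec.include_time:
            d = scale_f[1] * rng.standard_normal()
            col = np.exp(d * t)
            dll = d * float(Osum_k @ t) - float(st.mu.sum(axis=0) @ (col - 1.0))
            dlp = dll - 0.5 * ((p.beta1 + d) ** 2 - p.beta1 ** 2) / V
            if math.log(rng.random()) < dlp:
                p.beta1 += d
                st.eta += d * t[None, :]
                st.mu *= col[None, :]
                st.logpost += dlp
                acc_f[1] += 1
                if not burnin:
                    post_acc_f[1] += 1
        # quartile-indicator coefficients
        for j in range(nB):
            d = scale_f[2 + j] * rng.standard_normal()
            ed = math.exp(d)
            msum = float(st.mu[Xmask[j]].sum())
            dlp = d * OX[j] - msum * (ed - 1.0) \
                - 0.5 * ((p.beta[j] + d) ** 2 - p.beta[j] ** 2) / V
            if math.log(rng.random()) < dlp:
                p.beta[j] += d
                st.eta[Xmask[j]] += d
                st.mu[Xmask[j]] *= ed
                st.logpost += dlp
                acc_f[2 + j] += 1
                if not burnin:
                    post_acc_f[2 + j] += 1

        # --- conjugate precision draws -----------------------------------
        if spec.include_u:
            new_tau = float(rng.gamma(a + 0.5 * rank, 1.0 / (b + 0.5 * quad_u)))
            st.logpost += (0.5 * rank + a - 1.0) * (math.log(new_tau) - math.log(p.tau_u)) \
                - (0.5 * quad_u + b) * (new_tau - p.tau_u)
            p.tau_u = new_tau
        if spec.include_v:
            new_tau = float(rng.gamma(a + 0.5 * nZ, 1.0 / (b + 0.5 * sum_v2)))
            st.logpost += (0.5 * nZ + a - 1.0) * (math.log(new_tau) - math.log(p.tau_v)) \
                - (0.5 * sum_v2 + b) * (new_tau - p.tau_v)
            p.tau_v = new_tau

        # --- adaptation (burn-in only) ------------------------------------
        window_n += 1
        if burnin and window_n == cfg.adapt_window:
            window_idx += 1
            step = min(0.5, 2.0 / math.sqrt(window_idx))
            if spec.include_u:
                scale_u = adapt_proposals(scale_u, acc_u / window_n, step)
            if spec.include_v:
                scale_v = adapt_proposals(scale_v, acc_v / window_n, step)
            scale_f = adapt_proposals(scale_f, acc_f / window_n, step)
            acc_u[:] = 0
            acc_v[:] = 0
            acc_f[:] = 0
            window_n = 0
        elif not burnin:
            post_n += 1
            if window_n == cfg.adapt_window:
                window_n = 0  # scales frozen; counter reset only

        # --- periodic full-recompute consistency check --------------------
        if (sweep + 1) % cfg.check_every == 0:
            full = log_posterior(p, spec, C, E, X)
            check_diffs.append(abs(full - st.logpost))
            st.logpost = full
            st.eta = st.logE + _eta_offset(p, spec, Xarr, t, nZ, nK)
            st.mu = np.where(st.mask, np.exp(st.eta), 0.0)
            quad_u = _quadform(p.u, W, island_mask)
            sum_v2 = float(np.sum(p.v ** 2))

        # --- storage -------------------------------------------------------
        if not burnin:
            thin_c += 1
            if thin_c == cfg.thin:
                thin_c = 0
                store["alpha"][chain, stored] = p.alpha
                store["beta1"][chain, stored] = p.beta1
                store["beta"][chain, stored] = p.beta
                store["u"][chain, stored] = p.u
                store["v"][chain, stored] = p.v
                store["tau_u"][chain, stored] = p.tau_u
                store["tau_v"][chain, stored] = p.tau_v
                stored += 1

    accept_rates.append({
        "fixed": (post_acc_f / max(post_n, 1)).tolist(),
        "final_scale_u_mean": float(scale_u.mean()),
        "final_scale_v_mean": float(scale_v.mean()),
        "final_scale_fixed": scale_f.tolist(),
    })


def _eta_offset(p: Parameters, spec: ModelSpec, Xarr, t, nZ, nK) -> np.ndarray:
    eta = np.full((nZ, nK), p.alpha)
    if spec.include_u:
        eta += p.u[:, None]
    if spec.include_v:
        eta += p.v[:, None]
    if spec.include_time:
        eta += p.beta1 * t[None, :]
    if spec.include_covariates and Xarr.shape[2]:
        eta += Xarr @ p.beta
    return eta


def _quadform(u: np.ndarray, W: np.ndarray, island_mask: np.ndarray) -> float:
    m = W.sum(axis=1)
    q = float(u @ ((np.diag(m) - W) @ u))
    if island_mask.any():
        q += float(np.sum(u[island_mask] ** 2))
    return q
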