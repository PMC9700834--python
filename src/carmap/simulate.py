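"""Synthetic data from the model's own generative process.

The generator stands in for restricted survey microdata: a connected grid
of unit-square zones (default 8x9 = 72, near the study's 74), three
survey periods, ~85 children per zone-period (mirroring 18,939 children /
74 zones / 3 periods), zone-level quartile covariates, an ICAR-correlated
structured effect, an exchangeable unstructured effect, a linear period
trend and Poisson counts around internally standardized expected counts.
Default effect sizes are the magnitudes the fitted survey analysis
reports (coefficients ~ -0.01 .. 0.21 on the log scale); the baseline
anemia rate is 0.55.

Individual records are emitted so the whole tabulation pipeline can run;
record-level covariates are drawn independently given the zone-level
proportions (no joint dependence is emulated).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .cohort import CountTable, ZoneCovariates, _quartile_cut
from .geo import AdjacencyMatrix, ZoneGeometry, queen_adjacency
from .table1 import table1_fixture  # noqa: F401  (re-exported fixture entry point)

# Log-scale covariate effects: quartiles 2-4 of the three zone-level
# variables, at the magnitudes the survey-scale analysis reports.
DEFAULT_BETA = {
    "education_q2": -0.012, "education_q3": 0.149, "education_q4": 0.114,
    "ses_q2": 0.064, "ses_q3": 0.158, "ses_q4": 0.144,
    "maternal_anemia_q2": 0.168, "maternal_anemia_q3": 0.213,
    "maternal_anemia_q4": 0.065,
}

# Pooled severity split among anemic children (severe : moderate : mild) and
# pooled category splits used to dress individual records.
SEVERITY_SPLIT = np.array([736, 5400, 4257]) / 10393
EDU_SPLIT = np.array([4505, 900, 375]) / 5780            # primary/secondary/higher
SES_HIGH_SPLIT = np.array([2887, 3332]) / 6219           # richer/richest
SES_LOW_SPLIT = np.array([6137, 3490, 3093]) / 12720     # poorest/poorer/middle
MANEM_SPLIT = np.array([253, 1519, 3751]) / 5523         # severe/moderate/mild
AGE_SPLIT = np.array([637, 3653, 5793, 4113, 3039, 1263, 441]) / 18939
RURAL_P = 16048 / 18939
MALE_P = 9660 / 18939
LOWBW_P = 13508 / 18939
ORDER_SPLIT = np.array([9505, 6114, 3320]) / 18939


@dataclass
class SimulationParams:
    """True generative settings; all recorded in the output manifest."""

    rows: int = 8
    cols: int = 9
    period_labels: tuple = (2005, 2011, 2016)
    t_codes: tuple = (1.0, 2.0, 3.0)
    children_per_cell: int = 85
    alpha: float = -0.1
    beta1: float = 0.02
    beta: dict = field(default_factory=lambda: dict(DEFAULT_BETA))
    sigma_u: float = 0.2
    sigma_v: float = 0.1
    baseline_rate: float = 0.55
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.baseline_rate < 1:
            raise ValueError("baseline rate must be in (0, 1)")
        if self.rows * self.cols < 4:
            raise ValueError("grid must have at least 2x2 zones")


@dataclass
class SimulatedData:
    """Everything the pipeline consumes, plus the generative truth."""

    zones: list[ZoneGeometry]
    adjacency: AdjacencyMatrix
    records: pd.DataFrame
    counts: CountTable
    covariates: ZoneCovariates
    truth: dict

    def write(self, directory) -> dict:
        """Write the pipeline input dialects (GeoJSON, records/counts/
        covariates CSV, truth manifest JSON); returns the path map."""
        from .geo import write_geojson

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "geojson": directory / "zones.geojson",
            "records": directory / "records.csv",
            "counts": directory / "counts.csv",
            "covariates": directory / "covariates.csv",
            "truth": directory / "truth.json",
        }
        write_geojson(self.zones, paths["geojson"])
        self.records.to_csv(paths["records"], index=False)
        self.counts.to_frame().to_csv(paths["counts"], index=False)
        self.covariates.to_frame().to_csv(paths["covariates"], index=False)
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=1, default=_default)
        return {k: str(v) for k, v in paths.items()}


def _default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(type(o))


def make_grid_geometry(rows: int, cols: int) -> list[ZoneGeometry]:
    """Unit-square grid zones labelled Z_r_c; queen structure is analytic:
    an R x C grid has R(C-1) + C(R-1) + 2(R-1)(C-1) undirected edges."""
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    zones = []
    for r in range(rows):
        for c in range(cols):
            poly = Polygon([(c, r), (c + 1, r), (c + 1, r + 1), (c, r + 1)])
            zones.append(ZoneGeometry(zone_id=f"Z_{r}_{c}", geometry=poly))
    return zones


def sample_icar_field(A: AdjacencyMatrix, sigma_u: float,
                      rng: np.random.Generator,
                      per_component: bool = False) -> np.ndarray:
    """Exact draw from the intrinsic CAR distribution, restricted to the
    sum-to-zero subspace, via eigendecomposition of the graph Laplacian
    D - W (zero eigenvalues removed), scaled by sigma_u.

    A disconnected graph raises unless ``per_component`` is set, in which
    case each component is drawn with its own sum-to-zero constraint and
    islands get an exchangeable Normal(0, sigma_u^2) draw.
    """
    if sigma_u < 0:
        raise ValueError("sigma_u must be >= 0")
    n = A.n
    if sigma_u == 0:
        return np.zeros(n)
    comps = A.components()
    if len(comps) > 1 and not per_component:
        raise ValueError(f"graph has {len(comps)} components; "
                         "pass per_component=True to draw each separately")
    W = A.weights.astype(float)
    u = np.zeros(n)
    for comp in comps:
        idx = np.array(sorted(comp), dtype=int)
        if idx.size == 1:
            u[idx] = rng.normal(0.0, sigma_u)
            continue
        Wc = W[np.ix_(idx, idx)]
        L = np.diag(Wc.sum(axis=1)) - Wc
        evals, evecs = np.linalg.eigh(L)
        pos = evals > 1e-10 * evals.max()
        z = rng.standard_normal(int(pos.sum()))
        u[idx] = sigma_u * (evecs[:, pos] @ (z / np.sqrt(evals[pos])))
        u[idx] -= u[idx].mean()
    return u


def simulate_dataset(p: SimulationParams) -> SimulatedData:
    """Generate a full synthetic dataset from known parameters.

    Zone-level covariate proportions are drawn, quartiles derived with the
    same direction conventions the tabulation uses, u drawn from the ICAR
    law and v iid normal; mu_ik = E_ik exp(alpha + u_i + v_i + beta1 t_k +
    x'beta) with E_ik from the baseline rate; O_ik ~ Poisson(mu_ik) (capped
    at n_ik); then n_ik individual records per cell are emitted with O_ik
    anemic children and covariates consistent with the zone proportions.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(p.seed)
    zones = make_grid_geometry(p.rows, p.cols)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        A = queen_adjacency(zones)
    nZ = len(zones)
    periods = list(p.period_labels)
    nK = len(periods)
    t = np.asarray(p.t_codes, dtype=float)

    # zone x period covariate proportions and their quartile labels
    prop = {
        "education": rng.beta(3.0, 7.0, size=(nZ, nK)),
        "ses": rng.beta(3.0, 6.0, size=(nZ, nK)),
        "maternal_anemia": rng.beta(3.0, 7.5, size=(nZ, nK)),
    }
    higher_is_q1 = {"education": True, "ses": True, "maternal_anemia": False}
    quart = {}
    for var, pr in prop.items():
        q = np.ones((nZ, nK), dtype=int)
        for k in range(nK):
            q[:, k] = _quartile_cut(pr[:, k], higher_is_q1[var])
        quart[var] = q
    X = ZoneCovariates([z.zone_id for z in zones], periods, quart)
    beta_vec = np.array([p.beta[name] for name in X.column_names])

    u = sample_icar_field(A, p.sigma_u, rng, per_component=True)
    v = rng.normal(0.0, p.sigma_v, nZ)

    n = np.full((nZ, nK), p.children_per_cell, dtype=int)
    E = n * p.baseline_rate

    # The time and covariate contributions are centred in the generator so
    # that baseline_rate is the pooled anemia rate rather than the rate of
    # the (rare) all-reference cell; centring only shifts the intercept, so
    # the implied intercept of the uncentred model parameterization,
    # alpha - beta1*mean(t) - mean(x)'beta, is recorded in the manifest
    # while beta1 and beta are unchanged as estimands.
    t_bar = t.mean()
    x_bar = X.X.mean(axis=(0, 1))
    alpha_uncentred = p.alpha - p.beta1 * t_bar - float(x_bar @ beta_vec)
    # feasibility is a property of the user-set parameters alone: the worst
    # deterministic cell (most adverse quartile combination, last period)
    # must keep the expected rate below 1
    worst = p.alpha + abs(p.beta1) * np.abs(t - t_bar).max() + sum(
        max(max(p.beta.get(f"{var}_q{q}", 0.0) for q in (2, 3, 4)), 0.0)
        for var in quart)
    if p.baseline_rate * np.exp(worst) > 1.0:
        raise ValueError("parameters imply an expected anemia rate above 1 "
                         "in the most adverse covariate cell; reduce effects "
                         "or the baseline rate")
    eta = np.log(E) + p.alpha + u[:, None] + v[:, None] \
        + p.beta1 * (t[None, :] - t_bar) + (X.X - x_bar) @ beta_vec
    mu = np.exp(eta)
    O = rng.poisson(mu)
    capped = O > n
    if capped.any():
        warnings.warn(f"{int(capped.sum())} simulated count(s) capped at the "
                      "denominator", stacklevel=2)
        O = np.minimum(O, n)
    counts = CountTable([z.zone_id for z in zones], periods, O, n)
    records = _emit_records(counts, prop, rng)
    truth = {
        "alpha": p.alpha, "alpha_uncentred": alpha_uncentred,
        "beta1": p.beta1,
        "beta": {name: p.beta[name] for name in X.column_names},
        "u": u, "v": v, "sigma_u": p.sigma_u, "sigma_v": p.sigma_v,
        "baseline_rate": p.baseline_rate, "seed": p.seed,
        "t_codes": list(p.t_codes), "rows": p.rows, "cols": p.cols,
        "children_per_cell": p.children_per_cell,
        "quartiles": {k: vq for k, vq in quart.items()},
        "proportions": prop,
    }
    return SimulatedData(zones, A, records, counts, X, truth)


def _emit_records(counts: CountTable, prop: dict,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Individual records per zone-period with exactly O anemic children of
    n, covariates drawn from the zone proportions and pooled splits."""
    rows = []
    for i, z in enumerate(counts.zone_ids):
        for k, per in enumerate(counts.periods):
            n_ik, o_ik = int(counts.n[i, k]), int(counts.O[i, k])
            status = np.array(["non-anemic"] * n_ik, dtype=object)
            sev = rng.choice(["severe", "moderate", "mild"], size=o_ik,
                             p=SEVERITY_SPLIT)
            status[:o_ik] = sev
            rng.shuffle(status)
            edu_any = rng.random(n_ik) < prop["education"][i, k]
            edu = np.where(
                edu_any,
                rng.choice(["primary", "secondary", "higher"], size=n_ik,
                           p=EDU_SPLIT),
                "none")
            ses_hi = rng.random(n_ik) < prop["ses"][i, k]
            wealth = np.where(
                ses_hi,
                rng.choice(["richer", "richest"], size=n_ik, p=SES_HIGH_SPLIT),
                rng.choice(["poorest", "poorer", "middle"], size=n_ik,
                           p=SES_LOW_SPLIT))
            manem = np.where(
                rng.random(n_ik) < prop["maternal_anemia"][i, k],
                rng.choice(["severe", "moderate", "mild"], size=n_ik,
                           p=MANEM_SPLIT),
                "non-anemic")
            df = pd.DataFrame({
                "survey_year": per, "zone_id": z, "anemia_level": status,
                "maternal_education": edu, "wealth_quintile": wealth,
                "maternal_anemia": manem,
                "maternal_age_group": rng.choice(
                    ["15-19", "20-24", "25-29", "30-34", "35-39", "40-44",
                     "45-49"], size=n_ik, p=AGE_SPLIT / AGE_SPLIT.sum()),
                "residence": np.where(rng.random(n_ik) < RURAL_P,
                                      "rural", "urban"),
                "sex": np.where(rng.random(n_ik) < MALE_P, "male", "female"),
                "birth_weight_class": np.where(rng.random(n_ik) < LOWBW_P,
                                               "<=2.5kg", ">2.5kg"),
                "birth_order_class": rng.choice(
                    ["1-3", "4-6", ">6"], size=n_ik,
                    p=ORDER_SPLIT / ORDER_SPLIT.sum()),
            })
            rows.append(df)
    return pd.concat(rows, ignore_index=True)
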