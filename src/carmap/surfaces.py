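"""Posterior risk surfaces: smoothed relative risks, exceedance
probabilities, map classes and the fixed-effect RR table.

The smoothed relative risk of zone i in period k is the posterior of
exp(alpha + u_i + v_i + beta1 t_k + x_ik' beta); it borrows strength
across contiguity neighbours through the ICAR prior, stabilising the
noisy crude O/E ratios of sparsely sampled zones.  The exceedance
probability P(RR > 1 | data) is estimated as the fraction of stored MCMC
draws above the threshold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import CountTable
from .expected import ExpectedCounts, crude_rr
from .mcmc import PosteriorSamples

# Map class conventions: the relative-risk choropleth uses three bands and
# the exceedance-probability map four.  The published band edges for RR are
# self-inconsistent ("< 0.85" next to "0.8-1.1"); resolved here as
# < 0.85 / 0.85-1.1 / > 1.1.
RR_CLASS_BOUNDS = (0.85, 1.1)
PROB_CLASS_BOUNDS = (0.25, 0.5, 0.8)
PROB_CLASS_LABELS = ("0-0.25", "0.25-0.5", "0.5-0.8", ">0.8")


def smoothed_rr(samples: PosteriorSamples,
                point: str = "median") -> dict[str, np.ndarray]:
    """Per zone-period smoothed RR point estimate with 95% credible interval.

    The point estimate is the posterior median by default (robust to the
    lognormal skew of RR draws); ``point='mean'`` reports the posterior mean
    instead.  Returns arrays of shape (n_zones, n_periods) under keys
    'rr', 'lo', 'hi' (2.5/97.5 percentiles), plus both 'median' and 'mean'.
    """
    rr_draws = np.exp(samples.log_rr_draws())
    if rr_draws.shape[0] == 0:
        raise ValueError("no stored draws")
    med = np.median(rr_draws, axis=0)
    mean = rr_draws.mean(axis=0)
    lo, hi = np.percentile(rr_draws, [2.5, 97.5], axis=0)
    return {"rr": med if point == "median" else mean,
            "median": med, "mean": mean, "lo": lo, "hi": hi}


def exceedance_prob(samples: PosteriorSamples, threshold: float = 1.0) -> np.ndarray:
    """P(RR_ik > threshold | data): fraction of draws above the threshold."""
    rr_draws = np.exp(samples.log_rr_draws())
    if rr_draws.shape[0] == 0:
        raise ValueError("no stored draws")
    return (rr_draws > threshold).mean(axis=0)


def classify_rr(value: float) -> str:
    """Three-band RR map class: low (< 0.85), middle (0.85-1.1), high (> 1.1)."""
    if np.isnan(value):
        return "missing"
    if value < 0:
        raise ValueError("relative risk cannot be negative")
    lo, hi = RR_CLASS_BOUNDS
    if value < lo:
        return "low"
    if value <= hi:
        return "middle"
    return "high"


def classify_prob(p: float) -> str:
    """Four-band exceedance-probability class: [0,0.25], (0.25,0.5],
    (0.5,0.8], (0.8,1]."""
    if np.isnan(p):
        return "missing"
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    for bound, label in zip(PROB_CLASS_BOUNDS, PROB_CLASS_LABELS):
        if p <= bound:
            return label
    return PROB_CLASS_LABELS[-1]


def fixed_effect_table(samples: PosteriorSamples) -> pd.DataFrame:
    """Posterior summary of the fixed effects, on the log and RR scales.

    Per coefficient: posterior mean, SD, 95% CrI of the log-scale
    coefficient; the RR columns exponentiate each draw and report the
    posterior median with 2.5/97.5 percentiles; the significance star marks
    an RR credible interval that excludes 1.
    """
    rows = []
    entries = [("alpha", samples.pooled("alpha")),
               ("beta1", samples.pooled("beta1"))]
    entries += [(name, samples.pooled("beta", j))
                for j, name in enumerate(samples.covariate_names)]
    for name, draws in entries:
        lo, hi = np.percentile(draws, [2.5, 97.5])
        rr = np.exp(draws)
        rr_lo, rr_med, rr_hi = np.percentile(rr, [2.5, 50, 97.5])
        rows.append({
            "parameter": name,
            "mean": float(draws.mean()), "sd": float(draws.std(ddof=1)),
            "cri_lo": float(lo), "cri_hi": float(hi),
            "rr": round(float(rr_med), 2),
            "rr_lo": round(float(rr_lo), 2), "rr_hi": round(float(rr_hi), 2),
            "significant": bool(rr_lo > 1.0 or rr_hi < 1.0),
        })
    return pd.DataFrame(rows)


def risk_surface(samples: PosteriorSamples, C: CountTable, E: ExpectedCounts,
                 threshold: float = 1.0, point: str = "median") -> pd.DataFrame:
    """Full risk-surface table per zone x period.

    Columns: crude_rr, rr (point), rr_lo, rr_hi, rr_mean, exc_prob, rr_class,
    prob_class.  Cells without data keep a crude RR of NaN but still get a
    model-smoothed estimate (that is the point of smoothing).
    """
    sm = smoothed_rr(samples, point=point)
    exc = exceedance_prob(samples, threshold=threshold)
    crude = crude_rr(C, E)
    rows = []
    for i, z in enumerate(samples.zone_ids):
        for k, p in enumerate(samples.periods):
            rr = float(sm["rr"][i, k])
            rows.append({
                "zone_id": z, "period": p,
                "crude_rr": float(crude[i, k]),
                "rr": rr, "rr_lo": float(sm["lo"][i, k]),
                "rr_hi": float(sm["hi"][i, k]),
                "rr_mean": float(sm["mean"][i, k]),
                "exc_prob": float(exc[i, k]),
                "rr_class": classify_rr(rr),
                "prob_class": classify_prob(float(exc[i, k])),
            })
    return pd.DataFrame(rows)


def surface_geojson(surface: pd.DataFrame, zones, path) -> None:
    """Join the risk surface onto the zone geometry and write GeoJSON for
    choropleth rendering; one property set per period per zone."""
    from .geo import write_geojson

    props: dict[str, dict] = {}
    for _, row in surface.iterrows():
        d = props.setdefault(str(row["zone_id"]), {})
        p = row["period"]
        for col in ("crude_rr", "rr", "rr_lo", "rr_hi", "exc_prob",
                    "rr_class", "prob_class"):
            val = row[col]
            if isinstance(val, float) and np.isnan(val):
                val = None
            d[f"{col}_{p}"] = val
    write_geojson(zones, path, extra_properties=props)
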