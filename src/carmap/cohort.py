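"""Individual child records -> zone x period counts, descriptive summaries,
and zone-level quartile covariates.

Records are a pandas DataFrame, one row per child, with categorical columns
drawn from fixed domains (see :data:`RECORD_DOMAINS`).  The count response of
the areal model is the number of anemic children per zone and survey period;
a child is anemic when haemoglobin-based status is severe, moderate or mild.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ANEMIA_LEVELS = ("severe", "moderate", "mild", "non-anemic")
ANEMIC_LEVELS = frozenset(("severe", "moderate", "mild"))

RECORD_DOMAINS: dict[str, tuple[str, ...]] = {
    "anemia_level": ANEMIA_LEVELS,
    "maternal_education": ("none", "primary", "secondary", "higher"),
    "wealth_quintile": ("poorest", "poorer", "middle", "richer", "richest"),
    "maternal_anemia": ANEMIA_LEVELS,
    "maternal_age_group": ("15-19", "20-24", "25-29", "30-34", "35-39",
                           "40-44", "45-49"),
    "residence": ("urban", "rural"),
    "region": ("tigray", "afar", "amhara", "oromia", "somalia", "benishangul",
               "snnprs", "gambella", "harari", "addis ababa", "dire dawa"),
    "sex": ("male", "female"),
    "birth_weight_class": ("<=2.5kg", ">2.5kg"),
    "birth_order_class": ("1-3", "4-6", ">6"),
}

REQUIRED_COLUMNS = ("survey_year", "zone_id", "anemia_level")

# Covariate definitions for the three zone-level quartile variables:
# (column, predicate giving the zone proportion, True when quartile 1
#  should hold the HIGH-proportion zones).
QUARTILE_VARIABLES = {
    "education": ("maternal_education", lambda s: s != "none", True),
    "ses": ("wealth_quintile", lambda s: s.isin(["richer", "richest"]), True),
    "maternal_anemia": ("maternal_anemia", lambda s: s != "non-anemic", False),
}


class RecordValidationError(ValueError):
    pass


@dataclass
class CountTable:
    """Observed anemic counts O and denominators n by zone and period."""

    zone_ids: list[str]
    periods: list
    O: np.ndarray  # (n_zones, n_periods) int
    n: np.ndarray  # (n_zones, n_periods) int

    def __post_init__(self) -> None:
        self.O = np.asarray(self.O, dtype=int)
        self.n = np.asarray(self.n, dtype=int)
        if self.O.shape != (len(self.zone_ids), len(self.periods)):
            raise ValueError("count array shape does not match zone/period labels")
        if self.O.shape != self.n.shape:
            raise ValueError("O and n shapes differ")
        if (self.O < 0).any() or (self.n < 0).any():
            raise ValueError("negative counts")
        if (self.O > self.n).any():
            raise ValueError("O exceeds n in some cell")

    def to_frame(self) -> pd.DataFrame:
        rows = [(z, p, int(self.O[i, k]), int(self.n[i, k]))
                for i, z in enumerate(self.zone_ids)
                for k, p in enumerate(self.periods)]
        return pd.DataFrame(rows, columns=["zone_id", "period", "O", "n"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   zone_ids: list[str] | None = None,
                   periods: list | None = None) -> "CountTable":
        if zone_ids is None:
            zone_ids = list(pd.unique(df["zone_id"].astype(str)))
        if periods is None:
            periods = sorted(pd.unique(df["period"]))
        O = np.zeros((len(zone_ids), len(periods)), dtype=int)
        n = np.zeros_like(O)
        zi = {z: i for i, z in enumerate(zone_ids)}
        pi = {p: k for k, p in enumerate(periods)}
        for _, row in df.iterrows():
            O[zi[str(row["zone_id"])], pi[row["period"]]] = row["O"]
            n[zi[str(row["zone_id"])], pi[row["period"]]] = row["n"]
        return cls(zone_ids, periods, O, n)


@dataclass
class ZoneCovariates:
    """Zone x period quartile labels and their indicator design matrix.

    ``quartiles`` maps variable name -> (n_zones, n_periods) int array of
    labels 1-4 (quartile 1 is the model's reference category).  ``X`` is the
    stacked indicator design, shape (n_zones, n_periods, p), one 0/1 column
    per quartile 2-4 of each variable, named in ``column_names``.
    """

    zone_ids: list[str]
    periods: list
    quartiles: dict[str, np.ndarray]
    X: np.ndarray = field(init=False)
    column_names: list[str] = field(init=False)

    def __post_init__(self) -> None:
        cols, names = [], []
        for var, q in self.quartiles.items():
            q = np.asarray(q)
            if not np.isin(q, [1, 2, 3, 4]).all():
                raise ValueError(f"quartile labels for {var} outside 1-4")
            for lvl in (2, 3, 4):
                cols.append((q == lvl).astype(float))
                names.append(f"{var}_q{lvl}")
        self.X = (np.stack(cols, axis=-1) if cols
                  else np.zeros((len(self.zone_ids), len(self.periods), 0)))
        self.column_names = names

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, z in enumerate(self.zone_ids):
            for k, p in enumerate(self.periods):
                row = {"zone_id": z, "period": p}
                for var, q in self.quartiles.items():
                    row[f"{var}_q"] = int(q[i, k])
                rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, zone_ids: list[str],
                   periods: list) -> "ZoneCovariates":
        qvars = [c[:-2] for c in df.columns if c.endswith("_q")]
        zi = {z: i for i, z in enumerate(zone_ids)}
        pi = {p: k for k, p in enumerate(periods)}
        quart = {v: np.ones((len(zone_ids), len(periods)), dtype=int) for v in qvars}
        for _, row in df.iterrows():
            i, k = zi[str(row["zone_id"])], pi[row["period"]]
            for v in qvars:
                quart[v][i, k] = int(row[f"{v}_q"])
        return cls(zone_ids, periods, quart)


def recode_anemia(level: str) -> str:
    """Collapse the 4-level anemia status to binary: severe/moderate/mild ->
    'anemic'; 'non-anemic' stays.  Unknown levels raise."""
    if level in ANEMIC_LEVELS:
        return "anemic"
    if level == "non-anemic":
        return "non-anemic"
    raise RecordValidationError(f"unknown anemia level {level!r}")


def validate_records(records: pd.DataFrame) -> None:
    for col in REQUIRED_COLUMNS:
        if col not in records.columns:
            raise RecordValidationError(f"records missing column {col!r}")
    for col, domain in RECORD_DOMAINS.items():
        if col not in records.columns:
            continue
        vals = records[col].dropna()
        bad = set(vals.unique()) - set(domain)
        if bad:
            raise RecordValidationError(f"column {col!r} has values outside "
                                        f"its domain: {sorted(bad)}")


def tabulate_counts(records: pd.DataFrame, zone_ids: list[str],
                    periods: list) -> CountTable:
    """Count anemic children (O) and all children (n) per zone x period.

    Zone-periods with no contributing records get 0/0 and a warning.  A
    record whose zone or year is outside the given orders raises, naming the
    record index.
    """
    validate_records(records)
    zi = {z: i for i, z in enumerate(zone_ids)}
    pi = {p: k for k, p in enumerate(periods)}
    O = np.zeros((len(zone_ids), len(periods)), dtype=int)
    n = np.zeros_like(O)
    zcodes = records["zone_id"].astype(str).map(zi)
    pcodes = records["survey_year"].map(pi)
    if zcodes.isna().any():
        bad = records.index[zcodes.isna()][0]
        raise RecordValidationError(
            f"record {bad}: unknown zone {records.loc[bad, 'zone_id']!r}")
    if pcodes.isna().any():
        bad = records.index[pcodes.isna()][0]
        raise RecordValidationError(
            f"record {bad}: unknown survey year {records.loc[bad, 'survey_year']!r}")
    anemic = records["anemia_level"].isin(ANEMIC_LEVELS).to_numpy()
    np.add.at(n, (zcodes.to_numpy(dtype=int), pcodes.to_numpy(dtype=int)), 1)
    np.add.at(O, (zcodes.to_numpy(dtype=int)[anemic],
                  pcodes.to_numpy(dtype=int)[anemic]), 1)
    empty = int((n == 0).sum())
    if empty:
        warnings.warn(f"{empty} zone-period cell(s) have no records", stacklevel=2)
    return CountTable(list(zone_ids), list(periods), O, n)


def descriptive_table(records: pd.DataFrame,
                      variables: list[str] | None = None) -> pd.DataFrame:
    """Count and percent per category, by survey year and overall.

    Percentages are computed against non-missing totals within each period
    and rounded to 2 decimals.  Returns a long DataFrame with columns
    variable, category, period, count, percent ('overall' is a period).
    """
    if records.empty:
        raise RecordValidationError("descriptive_table requires non-empty records")
    if variables is None:
        variables = [c for c in RECORD_DOMAINS if c in records.columns]
    periods = sorted(records["survey_year"].unique())
    rows = []
    for var in variables:
        domain = RECORD_DOMAINS[var]
        for per in [*periods, "overall"]:
            sub = records if per == "overall" else records[records["survey_year"] == per]
            vals = sub[var].dropna()
            total = len(vals)
            counts = vals.value_counts()
            for cat in domain:
                c = int(counts.get(cat, 0))
                pct = round(100.0 * c / total, 2) if total else 0.0
                rows.append((var, cat, per, c, pct))
    return pd.DataFrame(rows, columns=["variable", "category", "period",
                                       "count", "percent"])


def _zone_proportions(records: pd.DataFrame, zone_ids: list[str],
                      column: str, predicate) -> np.ndarray:
    """Per-zone proportion of records satisfying the predicate, with missing
    values excluded from numerator and denominator.  NaN where a zone has no
    non-missing records."""
    props = np.full(len(zone_ids), np.nan)
    sub = records.dropna(subset=[column])
    flag = predicate(sub[column])
    grouped_n = sub.groupby(sub["zone_id"].astype(str)).size()
    grouped_o = flag.groupby(sub["zone_id"].astype(str)).sum()
    for i, z in enumerate(zone_ids):
        if z in grouped_n.index and grouped_n[z] > 0:
            props[i] = grouped_o.get(z, 0) / grouped_n[z]
    return props


def _quartile_cut(props: np.ndarray, higher_is_q1: bool) -> np.ndarray:
    """Assign quartile labels 1-4 by the 25/50/75 empirical percentiles.

    Ties at a cut share the lower quartile.  All-equal proportions map to
    quartile 1 with a warning.  Direction: higher_is_q1 reverses the order
    so the reference quartile holds the high-proportion zones.
    """
    finite = props[np.isfinite(props)]
    if finite.size < 4:
        raise ValueError("need at least 4 zones with non-missing proportions")
    scores = -props if higher_is_q1 else props.copy()
    fin = scores[np.isfinite(scores)]
    if np.allclose(fin, fin[0]):
        warnings.warn("all zone proportions equal; every zone in quartile 1",
                      stacklevel=3)
        q = np.ones(props.shape, dtype=int)
        return q
    cuts = np.percentile(fin, [25, 50, 75])
    q = np.ones(props.shape, dtype=int)
    for c in cuts:
        q += (scores > c).astype(int)
    q[~np.isfinite(scores)] = 1  # zones with no data default to the reference
    return q


def quartile_covariates(records: pd.DataFrame, zone_ids: list[str],
                        periods: list,
                        variables: dict | None = None,
                        per_period: bool = True) -> ZoneCovariates:
    """Zone-level quartile covariates from record-level proportions.

    For each variable the zone proportion is computed (education: any
    education; SES: wealth richer/richest; maternal anemia: any maternal
    anemia), zones are cut at the 25/50/75 percentiles, and the direction
    flag puts high education, high SES and LOW maternal anemia in quartile 1
    (the reference).  ``per_period=True`` recomputes quartiles within each
    survey period; otherwise they are pooled and repeated across periods.
    """
    validate_records(records)
    if variables is None:
        variables = QUARTILE_VARIABLES
    quart: dict[str, np.ndarray] = {}
    for var, (column, predicate, higher_is_q1) in variables.items():
        q = np.ones((len(zone_ids), len(periods)), dtype=int)
        if per_period:
            for k, per in enumerate(periods):
                sub = records[records["survey_year"] == per]
                props = _zone_proportions(sub, zone_ids, column, predicate)
                q[:, k] = _quartile_cut(props, higher_is_q1)
        else:
            props = _zone_proportions(records, zone_ids, column, predicate)
            q[:] = _quartile_cut(props, higher_is_q1)[:, None]
        quart[var] = q
    return ZoneCovariates(list(zone_ids), list(periods), quart)
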