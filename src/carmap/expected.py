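"""Expected counts by internal standardization and the crude relative risk.

The expected count E_ik plays the role of an offset in the Poisson
log-linear model: it is the count a zone-period would have seen if the
overall (pooled) rate applied to its denominator.  With internal
standardization, sum(E) = sum(O) by construction, so the crude relative
risk O/E (the standardized morbidity ratio, SMR) averages to 1 with
weights E.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CountTable


@dataclass
class ExpectedCounts:
    """Expected counts per zone x period plus the reference rate(s) used."""

    zone_ids: list[str]
    periods: list
    E: np.ndarray
    reference_rates: dict

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float)


def expected_counts(C: CountTable, per_period: bool = False,
                    strata: pd.DataFrame | None = None) -> ExpectedCounts:
    """Internally standardized expected counts.

    Default: E_ik = n_ik * (sum O / sum n) pooled over all zones and periods,
    so the temporal trend remains visible in the relative risk.  With
    ``per_period=True`` the rate is computed within each period instead.
    ``strata`` optionally supplies a long table (zone_id, period, stratum,
    O, n) for direct standardization by a stratifying factor such as age
    group: E_ik = sum_s n_iks * r_s with r_s the pooled stratum rate.
    """
    if C.O.sum() == 0:
        raise ValueError("all observed counts are zero: no reference rate")
    if strata is not None:
        return _stratified(C, strata)
    if per_period:
        rates = {}
        E = np.zeros(C.n.shape, dtype=float)
        for k, p in enumerate(C.periods):
            tot_n = C.n[:, k].sum()
            if tot_n == 0:
                raise ValueError(f"period {p!r} has zero denominator")
            r = C.O[:, k].sum() / tot_n
            rates[p] = r
            E[:, k] = C.n[:, k] * r
        return ExpectedCounts(C.zone_ids, C.periods, E, rates)
    r = C.O.sum() / C.n.sum()
    return ExpectedCounts(C.zone_ids, C.periods, C.n * r, {"pooled": r})


def _stratified(C: CountTable, strata: pd.DataFrame) -> ExpectedCounts:
    req = {"zone_id", "period", "stratum", "O", "n"}
    if not req.issubset(strata.columns):
        raise ValueError(f"strata table needs columns {sorted(req)}")
    pooled = strata.groupby("stratum")[["O", "n"]].sum()
    rates = (pooled["O"] / pooled["n"]).to_dict()
    zi = {z: i for i, z in enumerate(C.zone_ids)}
    pi = {p: k for k, p in enumerate(C.periods)}
    E = np.zeros(C.n.shape, dtype=float)
    for _, row in strata.iterrows():
        E[zi[str(row["zone_id"])], pi[row["period"]]] += row["n"] * rates[row["stratum"]]
    return ExpectedCounts(C.zone_ids, C.periods, E, rates)


def crude_rr(C: CountTable, E: ExpectedCounts) -> np.ndarray:
    """Crude relative risk (SMR) RR_ik = O_ik / E_ik.

    Cells with n = 0 are reported as NaN (no information), not 0.  A cell
    with E = 0 but O > 0 is an error.
    """
    Ea = np.asarray(E.E, dtype=float)
    rr = np.full(Ea.shape, np.nan)
    observed = C.n > 0
    bad = observed & (Ea <= 0) & (C.O > 0)
    if bad.any():
        i, k = np.argwhere(bad)[0]
        raise ValueError(f"zero expected count with positive observed count "
                         f"at zone {C.zone_ids[i]!r}, period {C.periods[k]!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        rr[observed] = C.O[observed] / Ea[observed]
    return rr


def expected_frame(C: CountTable, E: ExpectedCounts) -> pd.DataFrame:
    """Long-format export: zone_id, period, O, n, E, crude_rr."""
    rr = crude_rr(C, E)
    rows = [(z, p, int(C.O[i, k]), int(C.n[i, k]), float(E.E[i, k]),
             float(rr[i, k]) if np.isfinite(rr[i, k]) else np.nan)
            for i, z in enumerate(C.zone_ids)
            for k, p in enumerate(C.periods)]
    return pd.DataFrame(rows, columns=["zone_id", "period", "O", "n", "E",
                                       "crude_rr"])
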