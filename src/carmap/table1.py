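"""Synthetic fixture reproducing the published survey's one-way descriptive
margins (three survey waves, 18,939 children, 74 zones).

The fixture is *synthetic*: each variable's per-period category counts match
the published descriptive table exactly, but the joint structure is
product-of-margins (variables are shuffled independently), so it carries no
real joint information.  It exists to exercise the tabulation code against
known totals.

Two internal inconsistencies of the source table are resolved here:
the 2011 maternal-anemia column sums to one more than the period total
(non-anemic reduced 6191 -> 6190), and the 2016 column is 104 short of the
period total (those 104 records carry a missing maternal-anemia value, and
percentages are computed against non-missing totals).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

PERIODS = (2005, 2011, 2016)
PERIOD_TOTALS = {2005: 3296, 2011: 8100, 2016: 7543}
N_ZONES = 74

# variable -> category -> (count_2005, count_2011, count_2016)
TABLE1_MARGINS: dict[str, dict[str, tuple[int, int, int]]] = {
    "anemia_level": {
        "severe": (150, 291, 295),
        "moderate": (943, 2006, 2451),
        "mild": (723, 1739, 1795),
        "non-anemic": (1480, 4064, 3002),
    },
    "maternal_age_group": {
        "15-19": (129, 285, 223),
        "20-24": (617, 1543, 1493),
        "25-29": (965, 2546, 2282),
        "30-34": (683, 1719, 1201),
        "35-39": (547, 1291, 1711),
        "40-44": (250, 528, 485),
        "45-49": (105, 188, 148),
    },
    "residence": {
        "urban": (360, 1232, 1299),
        "rural": (2936, 6868, 6244),
    },
    "region": {
        "tigray": (385, 946, 797),
        "afar": (162, 768, 725),
        "amhara": (442, 912, 741),
        "oromia": (702, 1290, 1151),
        "somalia": (163, 601, 999),
        "benishangul": (255, 711, 649),
        "snnprs": (633, 1191, 968),
        "gambella": (162, 558, 497),
        "harari": (156, 401, 367),
        "addis ababa": (100, 248, 302),
        "dire dawa": (136, 474, 347),
    },
    "maternal_education": {
        "none": (2541, 5721, 4897),
        "primary": (556, 2022, 1927),
        "secondary": (182, 239, 479),
        "higher": (17, 118, 240),
    },
    "wealth_quintile": {
        "poorest": (856, 2514, 2767),
        "poorer": (628, 1521, 1341),
        "middle": (645, 1334, 1114),
        "richer": (590, 1356, 941),
        "richest": (577, 1375, 1380),
    },
    "sex": {
        "male": (1657, 4134, 3869),
        "female": (1639, 3966, 3674),
    },
    "birth_weight_class": {
        "<=2.5kg": (2400, 5607, 5501),
        ">2.5kg": (896, 2493, 2042),
    },
    "birth_order_class": {
        "1-3": (1551, 4084, 3870),
        "4-6": (1069, 2608, 2437),
        ">6": (676, 1408, 1236),
    },
    # Source column sums are inconsistent with the period totals; the 2011
    # count 6191 is printed but reduced by 1 here, and 2016 is 104 records
    # short (treated as missing values).
    "maternal_anemia": {
        "severe": (48, 84, 121),
        "moderate": (304, 485, 730),
        "mild": (652, 1341, 1758),
        "non-anemic": (2292, 6190, 4830),
    },
}


def fixture_zone_ids(n: int = N_ZONES) -> list[str]:
    return [f"Z{i:02d}" for i in range(1, n + 1)]


def table1_fixture(seed: int = 20050) -> pd.DataFrame:
    """Individual synthetic records whose per-period one-way margins equal
    the published Table-1 counts.

    Each variable's category vector is filled to the exact counts and then
    shuffled independently (product-of-margins joint distribution).  Zones
    are assigned round-robin over 74 synthetic labels.  Deterministic given
    the seed.
    """
    rng = np.random.default_rng(seed)
    zones = fixture_zone_ids()
    frames = []
    for k, period in enumerate(PERIODS):
        n = PERIOD_TOTALS[period]
        data: dict[str, np.ndarray] = {
            "survey_year": np.full(n, period),
            "zone_id": np.array([zones[i % len(zones)] for i in range(n)]),
        }
        for var, cats in TABLE1_MARGINS.items():
            col = np.empty(n, dtype=object)
            pos = 0
            for cat, counts in cats.items():
                c = counts[k]
                col[pos: pos + c] = cat
                pos += c
            if pos > n:
                raise AssertionError(f"{var} margins exceed period total")
            col[pos:] = None  # shortfall = missing values
            rng.shuffle(col)
            data[var] = col
        frames.append(pd.DataFrame(data))
    return pd.concat(frames, ignore_index=True)
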