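"""Descriptive margins of the packaged child-anemia fixture.

The package ships a record-level fixture of 18,939 children over three
survey rounds (2005, 2011, 2016) across 74 zones, built to match a fixed
set of published marginal counts.  This script tabulates it the same way a
survey report would: counts and percentages per category and period.
"""

from carmap.cohort import descriptive_table, tabulate_counts
from carmap.table1 import table1_fixture

records = table1_fixture()
print(f"children: {len(records)}")

anemic = records["anemia_level"].isin(["severe", "moderate", "mild"])
print(f"anemic:   {anemic.sum()} ({100 * anemic.mean():.2f}%)")

table = descriptive_table(records)
overall = table[table["period"] == "overall"]
for var in ("residence", "wealth_quintile", "maternal_education"):
    print(f"\n{var}")
    sub = overall[overall["variable"] == var]
    for _, row in sub.iterrows():
        print(f"  {row['category']:<12} {row['count']:>6}  {row['percent']:6.2f}%")

zones = sorted(records["zone_id"].unique())
counts = tabulate_counts(records, zones, [2005, 2011, 2016])
print(f"\nzone x period count table: {counts.O.shape[0]} zones x "
      f"{counts.O.shape[1]} periods, total anemic {counts.O.sum()}")
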