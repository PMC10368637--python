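"""Compliance/consumption descriptives and outlier winsorization.

Prints the condition x week-type descriptive table (the standard layout
for this design: response percentage, drinking-occasion percentage and
drinks per occasion) and demonstrates the explicit winsorization rule:
an outlier set is named, and every member is replaced by the largest
remaining per-occasion total.
"""

import emahurdle as eh
from emahurdle.preprocess import descriptives, winsorize_drinks

ds = eh.generate_dataset(
    eh.StudyDesign(n_groups=10, participants_per_group=10),
    eh.GenerativeParams(seed=7),
)

d = descriptives(ds)
print(d["by_cell"].round(2).to_string(index=False))
print(f"\nmedian response rate: {d['response_pct_median']:.2f}%")
print(f"participants with no drinking occasions: {d['n_zero_drinkers']}")

top = ds.records["total_drinks"].max()
ds2, n_changed, affected = winsorize_drinks(
    ds, cap="next_largest", outliers={int(top)}
)
print(f"\nwinsorized {n_changed} totals of {top} (from {len(affected)} "
      f"participant(s)) down to {ds2.records['total_drinks'].max()}")
# The drank flag never changes: winsorization caps amounts, it does not
# delete drinking occasions.
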