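"""Single-fiber morphometry and the longitudinal-growth statistics.

Simulates a single-fiber cohort in which mechanical overload lengthens
fibers by 7.5% at unchanged sarcomere length, derives the serial sarcomere
number (fiber length / mean sarcomere length), applies the >3-SD outlier
rule, and tests the group difference.
"""

import numpy as np

from myoseries import (
    SingleFiberTableParams,
    compare_groups,
    exclude_outliers,
    normalize_to_control,
    simulate_single_fiber_table,
    single_fiber_records,
)

params = SingleFiberTableParams()  # overload: +7.5% length, sarcomere length unchanged
table = single_fiber_records(simulate_single_fiber_table(params, seed=12))

for group, sub in table.groupby("group"):
    kept, log = exclude_outliers(sub["n_sarcomeres"].to_numpy())
    print(
        f"{group:5s}: n={len(sub)}, mean fiber length "
        f"{sub['fiber_length_um'].mean():7.1f} um, mean serial sarcomere "
        f"number {kept.mean():7.1f} ({len(log)} outliers excluded)"
    )

sham = table[table.group == "sham"]
mov = table[table.group == "mov"]
rel = normalize_to_control(mov["n_sarcomeres"].to_numpy(), sham["n_sarcomeres"].to_numpy())
print(f"\nserial sarcomere number, overload relative to sham mean: {rel.mean():.3f}")

result = compare_groups("t", table.rename(columns={"n_sarcomeres": "value"}))
print(
    f"t test: t = {result.statistic:.2f}, df = {result.df[0]:.0f}, "
    f"p = {result.p_value:.2e} ({result.direction})"
)
print(
    "\nThe relative value tracks the planted 1.075 length factor because the "
    "sarcomere length is unchanged: longitudinal growth is purely serial "
    "sarcomere addition."
)
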