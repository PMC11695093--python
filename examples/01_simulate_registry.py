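"""Simulate a synthetic twin/singleton birth registry and inspect it.

Draws a small registry (10,000 childbirths, ~2% twins) with a smooth
postpartum-depression hazard peaking near day 60 and an early-peaked twin
effect, writes births.csv / events.csv, and prints the ground-truth curves
the generator encodes.
"""

import numpy as np

import twinppd as tp

scenario = tp.paper_shaped_scenario(n_births=10_000, seed=7)
registry = tp.simulate_scenario(scenario)
tp.write_registry(registry, "scratch/registry")

print(f"births table: {len(registry.births)} rows "
      f"({registry.births['birth_id'].nunique()} childbirths x 2 parents)")
print(f"events table: {len(registry.events)} rows "
      "(pre-birth + postpartum diagnoses/prescriptions)")
twins = registry.births.drop_duplicates("birth_id")["plurality"].eq("twin").sum()
print(f"twin childbirths: {twins} ({100 * twins / 10_000:.1f}%)")

truth = tp.true_curves(scenario, np.array([60.0, 180.0, 365.0]))
print("\nground truth encoded by the scenario:")
for i, day in enumerate(truth.grid):
    print(f"  day {day:5.0f}: singleton risk {truth.baseline_cum_incidence[i]:5.1f} "
          f"/ twin risk {truth.twin_cum_incidence[i]:5.1f} per 1000, "
          f"momentary HR {truth.hr[i]:.2f}")
print("\nThe twin:singleton hazard ratio peaks at 1.30 around day 60 and "
      "decays towards 1, while ~2% of births are twins — the structure the "
      "downstream model is asked to recover.")
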