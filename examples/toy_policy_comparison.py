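"""Compare sharing, sparing and three-compartment sparing on the toy landscape.

The toy landscape has four 100 ha cells with yields 1, 2, 4 and 8 output
units/ha and two species. Each policy is run with the cost-minimization
rule (enrol the cheapest land first) and scored against the no-policy
baseline.
"""

from spareshare import PolicySpec, run_scenario, toy_landscape

t4 = toy_landscape()
print(f"Toy landscape: {t4.n_cells} cells, {t4.total_farmland:.0f} ha farmland, "
      f"baseline output {t4.baseline_output:.0f} units/yr\n")

policies = [
    PolicySpec("sharing", "cost_min", "grassland", 71.428571),  # same conserved area
    PolicySpec("sparing", "cost_min", "grassland", 0.05),
    PolicySpec("sparing3c", "cost_min", "grassland", 0.05),
]

header = f"{'strategy':<10} {'conserved ha':>12} {'gain in occ.':>12} {'dFood/yr':>10} {'leakage NPV':>12}"
print(header)
print("-" * len(header))
for policy in policies:
    out = run_scenario(t4, policy)
    print(
        f"{policy.strategy:<10} {out.spared_area_ha:>12.2f} {out.gain_in_occupancy:>12.4f} "
        f"{out.delta_food[0]:>10.2f} {out.leakage_npv:>12.2f}"
    )

print(
    "\nAt the same 71.4 ha conserved, sharing loses 71.4 output units each year\n"
    "(leakage: that food must be imported), pure sparing is output-neutral, and\n"
    "three-compartment sparing slightly raises output (+2.5/yr) because one-third\n"
    "of the spared land stays in low-yield agriculture. Its occupancy gain is\n"
    "lower than pure sparing's because only two-thirds becomes natural habitat."
)
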