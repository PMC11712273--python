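"""Sweep sparing uplifts under the three allocation rules on a seeded landscape.

Generates the default 40x40-cell, 100-species landscape and sweeps the
yield uplift g from 1% to 5% under each allocation rule, reproducing the
rule-dominance structure: biodiversity maximization >= cost minimization >=
equal allocation in occupancy gain at every uplift.
"""

from spareshare import GeneratorConfig, generate_landscape, sweep_policy

landscape = generate_landscape(GeneratorConfig(seed=42))
print(
    f"Landscape: {landscape.n_cells} cells, {landscape.n_species} species, "
    f"{landscape.total_farmland:,.0f} ha farmland\n"
)

tables = {
    rule: sweep_policy(landscape, "sparing", rule, "grassland")
    for rule in ("equal", "cost_min", "biodiv_max")
}

print(f"{'uplift g':>8} | {'gain (equal)':>14} {'gain (cost_min)':>16} {'gain (biodiv_max)':>18}")
for i, g in enumerate(tables["equal"]["parameter"]):
    print(
        f"{g:>8.2f} | {tables['equal']['gain_in_occupancy'][i]:>14.1f} "
        f"{tables['cost_min']['gain_in_occupancy'][i]:>16.1f} "
        f"{tables['biodiv_max']['gain_in_occupancy'][i]:>18.1f}"
    )

print(
    "\nGain in occupancy is the change in probability of occurrence summed over\n"
    "all cells and species, averaged 2020-2060. Targeting where species respond\n"
    "most (biodiv_max) beats targeting the cheapest land (cost_min), which beats\n"
    "spreading effort uniformly (equal) -- at every uplift level."
)
print(
    f"\nSpared area at g=0.05: equal {tables['equal']['spared_area_ha'].iloc[-1]:,.0f} ha, "
    f"cost_min {tables['cost_min']['spared_area_ha'].iloc[-1]:,.0f} ha "
    "(low-yield-first sparing frees the most land per unit of forgone output)."
)
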