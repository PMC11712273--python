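"""Where does each allocation rule put conservation? Export selection maps.

Runs sharing at a 10%-of-farmland area target under cost minimization and
biodiversity maximization, reports how much of the conserved area falls in
the low-yield upland stratum, and writes ESRI ASCII selection grids
(1 = cell selected for conservation, 0 = remains in production).
"""

import tempfile
from pathlib import Path

from spareshare import (
    GeneratorConfig,
    allocate_shared_area,
    generate_landscape,
    write_map,
)

landscape = generate_landscape(GeneratorConfig(seed=42))
upland = (landscape.cells["stratum"] == "upland").to_numpy()
farmland = landscape.farmland_area
target = 0.10 * farmland.sum()

print(
    f"Upland stratum: {upland.sum()} of {landscape.n_cells} cells, "
    f"{farmland[upland].sum() / farmland.sum():.1%} of farmland\n"
)

out_dir = Path(tempfile.mkdtemp(prefix="spareshare_maps_"))
for rule in ("cost_min", "biodiv_max"):
    alloc = allocate_shared_area(landscape, rule, target, "grassland")
    conv = alloc.habitat_ha + alloc.lowyield_ha
    share = conv[upland].sum() / conv.sum()
    path = write_map(alloc.selection_map(), landscape, out_dir / f"selection_{rule}.asc")
    print(f"{rule:>11}: {share:.1%} of conserved area in uplands -> {path}")

print(
    "\nCost minimization concentrates almost all conservation in the cheap,\n"
    "low-yield uplands; biodiversity maximization ranks cells by per-hectare\n"
    "occupancy gain instead, producing a diffuse pattern close to the uplands'\n"
    "share of farmland."
)
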