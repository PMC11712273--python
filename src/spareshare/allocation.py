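"""Allocation rules: which hectares leave conventional farming, and where.

Three rules place conserved land:

* ``equal`` — the target is divided equally across cells (water-filling when
  some cells lack the farmland to take their share);
* ``cost_min`` — cells enrol from lowest to highest yield, the proxy for
  subsidy cost;
* ``biodiv_max`` — cells enrol in descending order of occupancy gain, per
  hectare under an area target and per unit of forgone output under the
  output-neutrality constraint of sparing.

Two stopping conditions correspond to the two policy families: an area
target (sharing) and output neutrality at a given yield uplift (sparing).
Land is divisible — any portion of a cell's farmland up to all of it can be
converted — which makes each greedy rule exactly optimal for its linear
objective (a continuous knapsack).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .landscape import HABITATS, Landscape

RULES = ("equal", "cost_min", "biodiv_max")
OBJECTIVES = ("area_constrained", "output_constrained")

_REL_TOL = 1e-9


@dataclass(frozen=True)
class RankEntry:
    cell_id: int
    score: float
    available_area: float


@dataclass
class AllocationResult:
    """Per-cell converted areas (hectares) by compartment.

    ``habitat_ha`` is land converted to the conservation habitat named by
    ``habitat``; ``lowyield_ha`` is land converted to low-yield agriculture
    (nonzero only after a three-compartment split).
    """

    habitat: str
    habitat_ha: np.ndarray
    lowyield_ha: np.ndarray

    def __post_init__(self) -> None:
        self.habitat_ha = np.asarray(self.habitat_ha, dtype=float)
        self.lowyield_ha = np.asarray(self.lowyield_ha, dtype=float)
        if self.habitat not in HABITATS:
            raise ValueError(f"unknown habitat {self.habitat!r}; expected one of {HABITATS}")
        if (self.habitat_ha < -1e-12).any() or (self.lowyield_ha < -1e-12).any():
            raise ValueError("converted areas must be nonnegative")
        np.clip(self.habitat_ha, 0.0, None, out=self.habitat_ha)
        np.clip(self.lowyield_ha, 0.0, None, out=self.lowyield_ha)

    @classmethod
    def empty(cls, n_cells: int, habitat: str = "grassland") -> "AllocationResult":
        return cls(habitat, np.zeros(n_cells), np.zeros(n_cells))

    @property
    def habitat_area(self) -> float:
        return float(self.habitat_ha.sum())

    @property
    def lowyield_area(self) -> float:
        return float(self.lowyield_ha.sum())

    @property
    def spared_area(self) -> float:
        return self.habitat_area + self.lowyield_area

    def validate_against(self, landscape: Landscape) -> None:
        if len(self.habitat_ha) != landscape.n_cells:
            raise ValueError("allocation references a different number of cells than the landscape")
        over = self.habitat_ha + self.lowyield_ha - landscape.farmland_area
        if (over > 1e-6 * np.maximum(landscape.farmland_area, 1.0)).any():
            bad = int(np.argmax(over))
            raise ValueError(
                f"converted area exceeds farmland in cell_id {landscape.cells['cell_id'].iloc[bad]}"
            )

    def selection_map(self) -> np.ndarray:
        """1.0 where any farmland is converted, else 0.0 (Fig-4-style map)."""
        return ((self.habitat_ha + self.lowyield_ha) > 0).astype(float)


def _per_ha_gain(landscape: Landscape, habitat: str) -> np.ndarray:
    """Occupancy gain per hectare converted: sum_s delta / farmland_area."""
    total_delta = landscape.delta(habitat).sum(axis=0)
    area = landscape.farmland_area
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(area > 0, total_delta / area, 0.0)
    return g


def rank_cells(
    landscape: Landscape,
    rule: str,
    habitat: str = "grassland",
    objective: str = "area_constrained",
) -> list[RankEntry]:
    """Order cells by the rule's enrolment priority; ties by ascending cell_id."""
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}; expected one of {RULES}")
    if objective not in OBJECTIVES:
        raise ValueError(f"unknown objective {objective!r}; expected one of {OBJECTIVES}")
    cell_ids = landscape.cells["cell_id"].to_numpy()
    area = landscape.farmland_area
    if rule == "equal":
        order = np.arange(landscape.n_cells)
        scores = np.zeros(landscape.n_cells)
    elif rule == "cost_min":
        scores = landscape.yield_rate
        order = np.lexsort((cell_ids, scores))
    else:  # biodiv_max
        gain = _per_ha_gain(landscape, habitat)
        if objective == "area_constrained":
            scores = gain
        else:
            y = landscape.yield_rate
            with np.errstate(divide="ignore", invalid="ignore"):
                scores = np.where(y > 0, gain / y, np.where(gain > 0, np.inf, 0.0))
        order = np.lexsort((cell_ids, -scores))
    return [
        RankEntry(int(cell_ids[i]), float(scores[i]), float(area[i])) for i in order
    ]


def _greedy_fill_area(order: np.ndarray, capacity: np.ndarray, target: float) -> np.ndarray:
    """Convert whole cells in ranked order; fractional final cell hits the target."""
    alloc = np.zeros_like(capacity)
    residual = target
    for i in order:
        if residual <= 0:
            break
        take = min(capacity[i], residual)
        alloc[i] = take
        residual -= take
    return alloc


def allocate_shared_area(
    landscape: Landscape,
    rule: str,
    target_area: float,
    habitat: str = "grassland",
) -> AllocationResult:
    """Area-target (sharing) allocation: place ``target_area`` hectares of the
    conservation habitat according to ``rule``."""
    if target_area < 0:
        raise ValueError("target_area must be nonnegative")
    total = landscape.total_farmland
    if target_area > total * (1 + _REL_TOL):
        raise ValueError(
            f"target_area {target_area} exceeds total farmland {total}"
        )
    area = landscape.farmland_area
    n = landscape.n_cells
    if rule == "equal":
        alloc = _water_fill(area, target_area)
    else:
        entries = rank_cells(landscape, rule, habitat, objective="area_constrained")
        id_to_idx = {cid: i for i, cid in enumerate(landscape.cells["cell_id"])}
        order = np.array([id_to_idx[e.cell_id] for e in entries])
        alloc = _greedy_fill_area(order, area, target_area)
    result = AllocationResult(habitat, alloc, np.zeros(n))
    result.validate_against(landscape)
    return result


def _water_fill(capacity: np.ndarray, target: float) -> np.ndarray:
    """Equal division with caps: shortfall from capped cells is re-divided
    equally among unfilled cells until the full target is placed."""
    alloc = np.zeros_like(capacity)
    active = capacity > 0
    residual = target
    for _ in range(len(capacity) + 1):
        if residual <= 1e-12 * max(target, 1.0) or not active.any():
            break
        share = residual / active.sum()
        room = capacity - alloc
        add = np.where(active, np.minimum(share, room), 0.0)
        alloc += add
        residual -= add.sum()
        active &= (capacity - alloc) > 1e-12 * np.maximum(capacity, 1.0)
    return alloc


def allocate_spared(
    landscape: Landscape,
    rule: str,
    uplift: float,
    habitat: str = "grassland",
    max_uplift: float | None = 0.05,
) -> AllocationResult:
    """Output-neutral (sparing) allocation at proportional yield uplift ``g``.

    Solves for converted areas c_i >= 0 with (1+g) * sum y_i (A_i - c_i)
    equal to the baseline sum y_i A_i, i.e. the output removed must equal
    g/(1+g) of baseline output. The equal rule has the closed form
    f = g/(1+g) of every cell's farmland; ranked rules walk the
    output-constrained ranking converting whole cells with a fractional
    final cell so the identity holds exactly.
    """
    if uplift < 0:
        raise ValueError("uplift must be nonnegative")
    if max_uplift is not None and uplift > max_uplift + 1e-12:
        raise ValueError(f"uplift {uplift} exceeds configured maximum {max_uplift}")
    n = landscape.n_cells
    area = landscape.farmland_area
    y = landscape.yield_rate
    if rule == "equal":
        f = uplift / (1.0 + uplift)
        alloc = f * area
    elif rule in ("cost_min", "biodiv_max"):
        budget = uplift / (1.0 + uplift) * landscape.baseline_output
        entries = rank_cells(landscape, rule, habitat, objective="output_constrained")
        id_to_idx = {cid: i for i, cid in enumerate(landscape.cells["cell_id"])}
        alloc = np.zeros(n)
        residual = budget
        for e in entries:
            if residual <= 0:
                break
            i = id_to_idx[e.cell_id]
            if y[i] <= 0:
                # yield-free land costs no output: convert it whole
                alloc[i] = area[i]
                continue
            cell_output = y[i] * area[i]
            if cell_output <= residual:
                alloc[i] = area[i]
                residual -= cell_output
            else:
                alloc[i] = residual / y[i]
                residual = 0.0
    else:
        raise ValueError(f"unknown rule {rule!r}; expected one of {RULES}")
    result = AllocationResult(habitat, alloc, np.zeros(n))
    result.validate_against(landscape)
    return result


def split_three_compartment(landscape: Landscape, spared: AllocationResult) -> AllocationResult:
    """Reassign one-third of the spared hectares to low-yield agriculture.

    The lowest-yield spared hectares are chosen first (fractional split of
    the marginal cell); total spared area is unchanged, so the land-conserved
    curve of three-compartment sparing is identical to pure sparing.
    """
    if spared.lowyield_area > 0:
        raise ValueError("input allocation already contains low-yield area")
    habitat_ha = spared.habitat_ha.copy()
    lowyield_ha = np.zeros_like(habitat_ha)
    target = spared.habitat_area / 3.0
    if target > 0:
        y = landscape.yield_rate
        cell_ids = landscape.cells["cell_id"].to_numpy()
        order = np.lexsort((cell_ids, y))
        residual = target
        for i in order:
            if residual <= 0:
                break
            move = min(habitat_ha[i], residual)
            if move > 0:
                habitat_ha[i] -= move
                lowyield_ha[i] += move
                residual -= move
    result = AllocationResult(spared.habitat, habitat_ha, lowyield_ha)
    result.validate_against(landscape)
    return result
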