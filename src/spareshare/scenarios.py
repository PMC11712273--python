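"""Policy scenarios: single runs, parameter sweeps and the full factorial.

A policy is a (strategy, rule, habitat, parameter) quadruple. The three
strategies are:

* ``sharing`` — an area target is converted to the conservation habitat
  with no yield change (parameter: hectares);
* ``sparing`` — a proportional yield uplift funds conversion up to output
  neutrality (parameter: uplift fraction g);
* ``sparing3c`` — as sparing, then one-third of the spared hectares are
  reassigned to low-yield agriculture for farmland-specialist species.

Every outcome is measured against the common no-policy baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import allocation as alloc_mod
from . import economics as econ
from .allocation import AllocationResult
from .landscape import HABITATS, Landscape
from .occupancy import gain_in_occupancy, richness_change_map

STRATEGIES = ("sharing", "sparing", "sparing3c")

SWEEP_COLUMNS = [
    "strategy",
    "rule",
    "habitat",
    "parameter",
    "spared_area_ha",
    "habitat_area_ha",
    "lowyield_area_ha",
    "gain_in_occupancy",
    "delta_food_npv",
    "leakage_npv",
    "opportunity_cost_npv",
]

DEFAULT_UPLIFT_GRID = (0.01, 0.02, 0.03, 0.04, 0.05)
# sharing targets for synthetic landscapes: fractions of total farmland
DEFAULT_SHARING_FRACTIONS = tuple(np.linspace(0.0, 0.15, 10))

#: The study-scale configuration: 57 230 cells of 2 km, a 600 kha sharing
#: sweep endpoint, 1-5% sparing uplifts and 100 at-risk species. Recorded for
#: users supplying real national data; desk-scale defaults are much smaller.
GB_PRESET = {
    "n_cells": 57230,
    "cell_size_m": 2000,
    "sharing_target_max_ha": 600_000.0,
    "uplift_grid": DEFAULT_UPLIFT_GRID,
    "n_species": 100,
}


@dataclass(frozen=True)
class PolicySpec:
    strategy: str
    rule: str
    habitat: str
    parameter: float

    def validate(self, landscape: Landscape) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; expected one of {STRATEGIES}")
        if self.rule not in alloc_mod.RULES:
            raise ValueError(f"unknown rule {self.rule!r}; expected one of {alloc_mod.RULES}")
        if self.habitat not in HABITATS:
            raise ValueError(f"unknown habitat {self.habitat!r}; expected one of {HABITATS}")
        if self.parameter < 0:
            raise ValueError("policy parameter must be nonnegative")
        if self.strategy == "sharing" and self.parameter > landscape.total_farmland * (1 + 1e-9):
            raise ValueError(
                f"sharing target {self.parameter} ha exceeds total farmland "
                f"{landscape.total_farmland} ha"
            )


@dataclass
class ScenarioOutcome:
    """All headline quantities of one policy run against the baseline."""

    policy: PolicySpec
    allocation: AllocationResult
    gain_in_occupancy: float
    spared_area_ha: float
    habitat_area_ha: float
    lowyield_area_ha: float
    delta_food: np.ndarray
    delta_food_npv: float
    leakage_series: np.ndarray
    leakage_npv: float
    opportunity_cost_npv: float
    richness_map: np.ndarray
    selection_map: np.ndarray

    def summary_row(self) -> dict:
        return {
            "strategy": self.policy.strategy,
            "rule": self.policy.rule,
            "habitat": self.policy.habitat,
            "parameter": self.policy.parameter,
            "spared_area_ha": self.spared_area_ha,
            "habitat_area_ha": self.habitat_area_ha,
            "lowyield_area_ha": self.lowyield_area_ha,
            "gain_in_occupancy": self.gain_in_occupancy,
            "delta_food_npv": self.delta_food_npv,
            "leakage_npv": self.leakage_npv,
            "opportunity_cost_npv": self.opportunity_cost_npv,
        }


def _allocate(landscape: Landscape, policy: PolicySpec, max_uplift: float | None) -> tuple[AllocationResult, float]:
    if policy.strategy == "sharing":
        return (
            alloc_mod.allocate_shared_area(landscape, policy.rule, policy.parameter, policy.habitat),
            0.0,
        )
    spared = alloc_mod.allocate_spared(
        landscape, policy.rule, policy.parameter, policy.habitat, max_uplift=max_uplift
    )
    if policy.strategy == "sparing3c":
        spared = alloc_mod.split_three_compartment(landscape, spared)
    return spared, policy.parameter


def run_scenario(
    landscape: Landscape,
    policy: PolicySpec,
    discount_rate: float = econ.DEFAULT_DISCOUNT_RATE,
    unit_price: float = econ.DEFAULT_UNIT_PRICE,
    max_uplift: float | None = 0.05,
) -> ScenarioOutcome:
    """Run one policy end to end against the common no-policy baseline."""
    policy.validate(landscape)
    allocation, uplift = _allocate(landscape, policy, max_uplift)
    gain_map = richness_change_map(landscape, allocation, policy.habitat)
    delta = econ.delta_food_series(landscape, allocation, uplift)
    leak_npv, leak_series = econ.leakage_indicator(delta, discount_rate)
    return ScenarioOutcome(
        policy=policy,
        allocation=allocation,
        gain_in_occupancy=float(gain_map.sum()),
        spared_area_ha=allocation.spared_area,
        habitat_area_ha=allocation.habitat_area,
        lowyield_area_ha=allocation.lowyield_area,
        delta_food=delta,
        delta_food_npv=econ.npv(delta, discount_rate),
        leakage_series=leak_series,
        leakage_npv=leak_npv,
        opportunity_cost_npv=econ.opportunity_cost_npv(delta, discount_rate, unit_price),
        richness_map=gain_map,
        selection_map=allocation.selection_map(),
    )


def default_sharing_grid(landscape: Landscape) -> np.ndarray:
    return np.array(DEFAULT_SHARING_FRACTIONS) * landscape.total_farmland


def default_grid(landscape: Landscape, strategy: str) -> np.ndarray:
    if strategy == "sharing":
        return default_sharing_grid(landscape)
    return np.array(DEFAULT_UPLIFT_GRID)


def sweep_policy(
    landscape: Landscape,
    strategy: str,
    rule: str,
    habitat: str,
    grid=None,
    discount_rate: float = econ.DEFAULT_DISCOUNT_RATE,
    unit_price: float = econ.DEFAULT_UNIT_PRICE,
) -> pd.DataFrame:
    """One scenario run per grid value; rows in grid order."""
    if grid is None:
        grid = default_grid(landscape, strategy)
    rows = []
    for value in grid:
        outcome = run_scenario(
            landscape,
            PolicySpec(strategy, rule, habitat, float(value)),
            discount_rate=discount_rate,
            unit_price=unit_price,
        )
        rows.append(outcome.summary_row())
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def factorial_run(
    landscape: Landscape,
    sharing_grid=None,
    uplift_grid=None,
    discount_rate: float = econ.DEFAULT_DISCOUNT_RATE,
    unit_price: float = econ.DEFAULT_UNIT_PRICE,
) -> pd.DataFrame:
    """All 3 strategies x 3 rules x 2 habitats, rows ordered lexicographically
    by (strategy, rule, habitat, parameter)."""
    if sharing_grid is None:
        sharing_grid = default_sharing_grid(landscape)
    if uplift_grid is None:
        uplift_grid = np.array(DEFAULT_UPLIFT_GRID)
    tables = []
    for strategy in sorted(STRATEGIES):
        grid = sharing_grid if strategy == "sharing" else uplift_grid
        for rule in sorted(alloc_mod.RULES):
            for habitat in sorted(HABITATS):
                tables.append(
                    sweep_policy(
                        landscape, strategy, rule, habitat, grid,
                        discount_rate=discount_rate, unit_price=unit_price,
                    )
                )
    return pd.concat(tables, ignore_index=True)
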