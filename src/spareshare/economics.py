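"""Food-output accounting, leakage and discounted opportunity cost.

Annual food output sums, over cells, the yield of the farmland remaining in
conventional agriculture plus a fraction ``lowyield_factor`` of conventional
yield on land converted to low-yield agriculture; habitat land produces
nothing. Yields evolve with the climate anomaly through the cell
sensitivities kappa, and a policy yield uplift ``g`` applies as a step from
the base year to conventional and low-yield farmland alike.

Leakage is the one-sided shortfall of domestic output against the no-policy
baseline — food that must be imported, displacing habitat loss abroad. The
opportunity cost of a policy is the negative of the discounted sum of its
output deltas, monetised at a configurable unit price.
"""

from __future__ import annotations

import numpy as np

from .allocation import AllocationResult
from .landscape import Landscape

DEFAULT_DISCOUNT_RATE = 0.035  # HM Treasury social discount rate
DEFAULT_UNIT_PRICE = 1.0


def annual_food_output(
    landscape: Landscape,
    allocation: AllocationResult | None,
    uplift: float,
    year: int,
) -> float:
    """Total food output (output units) in one calendar year."""
    a = landscape.climate.anomaly_at(year)
    y_t = landscape.yield_rate * np.clip(1.0 + landscape.kappa * a, 0.0, None)
    area = landscape.farmland_area
    if allocation is None:
        conventional = area
        lowyield = np.zeros_like(area)
    else:
        allocation.validate_against(landscape)
        conventional = area - allocation.habitat_ha - allocation.lowyield_ha
        lowyield = allocation.lowyield_ha
    out = (conventional + lowyield * landscape.lowyield_factor) * y_t * (1.0 + uplift)
    return float(out.sum())


def food_series(
    landscape: Landscape,
    allocation: AllocationResult | None,
    uplift: float,
) -> np.ndarray:
    """Per-year food output over the climate horizon."""
    return np.array(
        [annual_food_output(landscape, allocation, uplift, int(t)) for t in landscape.climate.years]
    )


def delta_food_series(
    landscape: Landscape,
    allocation: AllocationResult | None,
    uplift: float,
) -> np.ndarray:
    """Per-year scenario output minus the no-policy baseline output.

    Strictly negative for sharing with a positive target, identically zero
    for pure sparing, and nonnegative for three-compartment sparing when the
    low-yield land retains any productivity.
    """
    return food_series(landscape, allocation, uplift) - food_series(landscape, None, 0.0)


def npv(flows, rate: float, base_year: int | None = None) -> float:
    """Present value of per-year flows, base-year flow undiscounted.

    ``flows[k]`` is the end-of-year flow ``k`` years after the base year;
    ``base_year`` is accepted for interface symmetry and does not affect the
    discounting exponent.
    """
    flows = np.asarray(flows, dtype=float)
    if flows.size == 0:
        raise ValueError("flow series must be non-empty")
    if rate <= -1:
        raise ValueError("rate must exceed -1")
    k = np.arange(flows.size)
    return float((flows / (1.0 + rate) ** k).sum())


def leakage_indicator(
    delta_series: np.ndarray,
    rate: float = DEFAULT_DISCOUNT_RATE,
) -> tuple[float, np.ndarray]:
    """One-sided import requirement: per-year max(0, -delta), and its NPV."""
    series = np.maximum(0.0, -np.asarray(delta_series, dtype=float))
    return npv(series, rate), series


def opportunity_cost_npv(
    delta_series: np.ndarray,
    rate: float = DEFAULT_DISCOUNT_RATE,
    unit_price: float = DEFAULT_UNIT_PRICE,
) -> float:
    """Discounted forgone output, monetised; negative when output rises."""
    return -npv(delta_series, rate) * unit_price
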