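"""Species occupancy under a land-use state, and the Gain-in-Occupancy metric.

Occupancy responds linearly to the fraction of a cell's farmland converted,
with clipping to [0, 1]:

    p = clip( p0 + delta_h * f_habitat + gamma * f_lowyield + beta * a(t), 0, 1 )

where ``delta_h`` is the response to full conversion to the conservation
habitat, ``gamma`` the response to full conversion to low-yield agriculture,
and ``a(t)`` the climate anomaly in year ``t``. The headline biodiversity
metric is the change in occupancy relative to the no-policy baseline, summed
over all cells and species and averaged over the calendar years of the
horizon (inclusive).
"""

from __future__ import annotations

import numpy as np

from .allocation import AllocationResult
from .landscape import HABITATS, Landscape


def cell_occupancy(
    p0,
    delta,
    gamma,
    beta,
    f_habitat=0.0,
    f_lowyield=0.0,
    anomaly: float = 0.0,
):
    """Occupancy probability under partial conversion; vectorised over inputs.

    ``f_habitat`` and ``f_lowyield`` are fractions of the cell's farmland
    converted to the conservation habitat and to low-yield agriculture; each
    must lie in [0, 1] and their sum must not exceed 1.
    """
    f_habitat = np.asarray(f_habitat, dtype=float)
    f_lowyield = np.asarray(f_lowyield, dtype=float)
    eps = 1e-9
    if ((f_habitat < -eps) | (f_habitat > 1 + eps)).any() or (
        (f_lowyield < -eps) | (f_lowyield > 1 + eps)
    ).any():
        raise ValueError("conversion fractions must lie in [0, 1]")
    if ((f_habitat + f_lowyield) > 1 + eps).any():
        raise ValueError("f_habitat + f_lowyield must not exceed 1 in any cell")
    p = (
        np.asarray(p0, dtype=float)
        + np.asarray(delta, dtype=float) * f_habitat
        + np.asarray(gamma, dtype=float) * f_lowyield
        + np.asarray(beta, dtype=float) * anomaly
    )
    return np.clip(p, 0.0, 1.0)


def _fractions(landscape: Landscape, allocation: AllocationResult) -> tuple[np.ndarray, np.ndarray]:
    area = landscape.farmland_area
    with np.errstate(invalid="ignore", divide="ignore"):
        f_h = np.where(area > 0, allocation.habitat_ha / area, 0.0)
        f_l = np.where(area > 0, allocation.lowyield_ha / area, 0.0)
    return f_h, f_l


def occupancy_matrix(
    landscape: Landscape,
    allocation: AllocationResult | None,
    habitat: str | None = None,
    anomaly: float = 0.0,
) -> np.ndarray:
    """Per-(species, cell) occupancy under ``allocation`` at one anomaly.

    ``allocation=None`` gives the no-policy baseline state.
    """
    if allocation is None:
        return cell_occupancy(
            landscape.p0, 0.0, 0.0, landscape.beta, 0.0, 0.0, anomaly
        )
    habitat = habitat or allocation.habitat
    if habitat not in HABITATS:
        raise ValueError(f"unknown habitat {habitat!r}; expected one of {HABITATS}")
    allocation.validate_against(landscape)
    f_h, f_l = _fractions(landscape, allocation)
    return cell_occupancy(
        landscape.p0, landscape.delta(habitat), landscape.gamma, landscape.beta,
        f_h[np.newaxis, :], f_l[np.newaxis, :], anomaly,
    )


def richness_change_map(
    landscape: Landscape,
    allocation: AllocationResult,
    habitat: str | None = None,
) -> np.ndarray:
    """Per-cell change in expected species richness vs the no-policy baseline,
    averaged over the calendar years of the climate horizon.

    Summing the map over cells gives :func:`gain_in_occupancy` exactly.
    """
    total = np.zeros(landscape.n_cells)
    anomalies = landscape.climate.anomaly
    for a in anomalies:
        occ = occupancy_matrix(landscape, allocation, habitat, anomaly=a)
        base = occupancy_matrix(landscape, None, anomaly=a)
        total += (occ - base).sum(axis=0)
    return total / len(anomalies)


def gain_in_occupancy(
    landscape: Landscape,
    allocation: AllocationResult,
    habitat: str | None = None,
) -> float:
    """Change in occupancy summed across all cells and species, averaged over
    the years of the horizon — the headline biodiversity metric.

    When every species has zero climate sensitivity the climate terms cancel
    in the difference and this equals the single-year sum.
    """
    return float(richness_change_map(landscape, allocation, habitat).sum())
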