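"""Landscape substrate: grid cells, species responses and a climate trajectory.

A :class:`Landscape` is the decision substrate for every policy simulation:
a rectangular grid of cells, each carrying an area of conventional farmland
(hectares) and a base-year yield (output units per hectare per year); a
table of per-species, per-cell occupancy responses to habitat creation and
to low-yield agriculture; and a scalar climate-anomaly trajectory that
perturbs both yields and occupancies over the analysis horizon.

Two constructors are provided.  :func:`toy_landscape` returns a fixed,
hand-checkable 2x2 fixture whose every derived number can be verified on
paper.  :func:`generate_landscape` draws seeded random landscapes with the
statistical structure the national-scale analysis assumes: spatially
autocorrelated yields with a contiguous low-yield upland stratum, ~100
at-risk species spanning woodland-specialist, grassland-specialist,
farmland-specialist and generalist response archetypes, and a monotone
warming trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

HABITATS = ("grassland", "woodland")
STRATA = ("upland", "lowland")

CELL_COLUMNS = ["cell_id", "col", "row", "farmland_area", "yield_rate", "stratum", "kappa"]
SPECIES_COLUMNS = ["species_id", "cell_id", "p0", "delta_grassland", "delta_woodland", "gamma", "beta"]
CLIMATE_COLUMNS = ["year", "anomaly"]

ARCHETYPES = ("woodland_specialist", "grassland_specialist", "farmland_specialist", "generalist")


@dataclass(frozen=True)
class ClimateTrajectory:
    """Scalar climate anomaly per calendar year, zero at the base year."""

    base_year: int
    end_year: int
    anomaly: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.anomaly, dtype=float)
        object.__setattr__(self, "anomaly", a)
        n = self.end_year - self.base_year + 1
        if a.shape != (n,):
            raise ValueError(
                f"anomaly must have one value per year ({n}), got shape {a.shape}"
            )
        if a[0] != 0.0:
            raise ValueError("anomaly at the base year must be 0")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.base_year, self.end_year + 1)

    def anomaly_at(self, year: int) -> float:
        if not self.base_year <= year <= self.end_year:
            raise ValueError(
                f"year {year} outside horizon [{self.base_year}, {self.end_year}]"
            )
        return float(self.anomaly[year - self.base_year])


@dataclass
class Landscape:
    """Grid cells, species response matrices and climate for one study area.

    Response matrices are shaped ``(n_species, n_cells)`` with cells ordered
    by ascending ``cell_id``, matching the row order of ``cells``.
    """

    cells: pd.DataFrame
    p0: np.ndarray
    delta_grassland: np.ndarray
    delta_woodland: np.ndarray
    gamma: np.ndarray
    beta: np.ndarray
    climate: ClimateTrajectory
    lowyield_factor: float = 0.1
    species_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.cells = self.cells.reset_index(drop=True)
        if list(self.cells.columns) != CELL_COLUMNS:
            raise ValueError(f"cells columns must be {CELL_COLUMNS}")
        if not self.cells["cell_id"].is_monotonic_increasing:
            self.cells = self.cells.sort_values("cell_id").reset_index(drop=True)
        if self.cells["cell_id"].duplicated().any():
            raise ValueError("cell_id values must be unique")
        for name in ("p0", "delta_grassland", "delta_woodland", "gamma", "beta"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.species_ids is None:
            self.species_ids = np.arange(self.p0.shape[0])
        self.species_ids = np.asarray(self.species_ids)
        self.validate()

    def validate(self) -> None:
        n_cells = len(self.cells)
        shape = (len(self.species_ids), n_cells)
        for name in ("p0", "delta_grassland", "delta_woodland", "gamma", "beta"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}, got {arr.shape}")
        if (self.cells["farmland_area"] < 0).any():
            raise ValueError("farmland_area must be >= 0")
        if (self.cells["yield_rate"] < 0).any():
            raise ValueError("yield_rate must be >= 0")
        if self.total_farmland <= 0:
            raise ValueError("total farmland area must be > 0")
        if ((self.p0 < 0) | (self.p0 > 1)).any():
            bad_s, bad_i = np.argwhere((self.p0 < 0) | (self.p0 > 1))[0]
            raise ValueError(
                "baseline occupancy outside [0, 1] for species_id "
                f"{self.species_ids[bad_s]}, cell_id {self.cells['cell_id'].iloc[bad_i]}"
            )
        if not (0 < self.lowyield_factor <= 1):
            raise ValueError("lowyield_factor must be in (0, 1]")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def farmland_area(self) -> np.ndarray:
        return self.cells["farmland_area"].to_numpy(dtype=float)

    @property
    def yield_rate(self) -> np.ndarray:
        return self.cells["yield_rate"].to_numpy(dtype=float)

    @property
    def kappa(self) -> np.ndarray:
        return self.cells["kappa"].to_numpy(dtype=float)

    @property
    def total_farmland(self) -> float:
        return float(self.cells["farmland_area"].sum())

    @property
    def baseline_output(self) -> float:
        """Base-year annual food output with no policy, anomaly 0."""
        return float((self.farmland_area * self.yield_rate).sum())

    def delta(self, habitat: str) -> np.ndarray:
        """Occupancy response matrix for full conversion to ``habitat``."""
        if habitat == "grassland":
            return self.delta_grassland
        if habitat == "woodland":
            return self.delta_woodland
        raise ValueError(f"unknown habitat {habitat!r}; expected one of {HABITATS}")

    def copy(self) -> "Landscape":
        return replace(
            self,
            cells=self.cells.copy(),
            p0=self.p0.copy(),
            delta_grassland=self.delta_grassland.copy(),
            delta_woodland=self.delta_woodland.copy(),
            gamma=self.gamma.copy(),
            beta=self.beta.copy(),
        )


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic landscape generator.

    Yields are drawn log-normally per stratum on 2 km-style cells and
    smoothed with a moving-average kernel to induce spatial autocorrelation;
    the first ``round(upland_fraction * n_cols)`` columns form a contiguous
    low-yield upland block. Species are split between four response
    archetypes in the configured proportions. The climate anomaly grows
    linearly from zero at the base year.
    """

    n_cols: int = 40
    n_rows: int = 40
    n_species: int = 100
    upland_fraction: float = 0.3
    yield_log_mean_upland: float = 0.5
    yield_log_mean_lowland: float = 2.0
    yield_log_sd: float = 0.4
    smoothing_radius: int = 2
    archetype_proportions: tuple[float, float, float, float] = (0.3, 0.3, 0.2, 0.2)
    climate_slope: float = 0.02
    base_year: int = 2020
    end_year: int = 2060
    cell_area_ha: float = 400.0
    farmland_fraction_range: tuple[float, float] = (0.2, 0.9)
    kappa_mean: float = -0.05
    kappa_sd: float = 0.0
    lowyield_factor: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_cols <= 0 or self.n_rows <= 0 or self.n_species <= 0:
            raise ValueError("n_cols, n_rows and n_species must be positive")
        if not 0 <= self.upland_fraction <= 1:
            raise ValueError("upland_fraction must be in [0, 1]")
        if abs(sum(self.archetype_proportions) - 1.0) > 1e-9:
            raise ValueError("archetype_proportions must sum to 1")
        if self.smoothing_radius < 0:
            raise ValueError("smoothing_radius must be >= 0")
        if self.end_year < self.base_year:
            raise ValueError("end_year must be >= base_year")


def toy_landscape() -> Landscape:
    """Deterministic 2x2 fixture "T4" used throughout tests and examples.

    Four cells of 100 ha farmland with yields 1, 2, 4, 8; cell c1 upland,
    the rest lowland; two species with contrasting grassland responses and
    one farmland-affiliated species (gamma > 0); climate switched off.
    Every policy outcome on this landscape is checkable by hand.
    """
    cells = pd.DataFrame(
        {
            "cell_id": [0, 1, 2, 3],
            "col": [0, 1, 0, 1],
            "row": [0, 0, 1, 1],
            "farmland_area": [100.0, 100.0, 100.0, 100.0],
            "yield_rate": [1.0, 2.0, 4.0, 8.0],
            "stratum": ["upland", "lowland", "lowland", "lowland"],
            "kappa": [0.0, 0.0, 0.0, 0.0],
        }
    )
    p0 = np.array([[0.2, 0.2, 0.2, 0.2], [0.1, 0.1, 0.1, 0.1]])
    delta_grassland = np.array([[0.1, 0.1, 0.1, 0.1], [0.2, 0.9, 0.4, 0.5]])
    delta_woodland = np.array([[0.4, 0.4, 0.4, 0.4], [0.05, 0.05, 0.05, 0.05]])
    gamma = np.array([[0.0, 0.0, 0.0, 0.0], [0.2, 0.2, 0.2, 0.2]])
    beta = np.zeros((2, 4))
    climate = ClimateTrajectory(2020, 2060, np.zeros(41))
    return Landscape(
        cells=cells,
        p0=p0,
        delta_grassland=delta_grassland,
        delta_woodland=delta_woodland,
        gamma=gamma,
        beta=beta,
        climate=climate,
        lowyield_factor=0.1,
        species_ids=np.array([1, 2]),
    )


def _archetype_counts(n_species: int, proportions: tuple[float, ...]) -> list[int]:
    # largest-remainder apportionment so counts sum exactly to n_species
    raw = [p * n_species for p in proportions]
    counts = [int(np.floor(r)) for r in raw]
    remainder = n_species - sum(counts)
    order = np.argsort([-(r - np.floor(r)) for r in raw], kind="stable")
    for k in order[:remainder]:
        counts[k] += 1
    return counts


def _smoothed_yields(config: GeneratorConfig, upland_col: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Log-normal yields, kernel-smoothed, stratum means enforced by rescaling."""
    noise = rng.normal(0.0, config.yield_log_sd, size=(config.n_rows, config.n_cols))
    if config.smoothing_radius > 0:
        size = 2 * config.smoothing_radius + 1
        noise = ndimage.uniform_filter(noise, size=size, mode="nearest")
    mu = np.where(upland_col[np.newaxis, :], config.yield_log_mean_upland, config.yield_log_mean_lowland)
    y = np.exp(mu + noise)
    # Rescale each stratum's realized arithmetic mean onto its log-normal
    # target mean exp(mu + sd^2/2): guarantees upland mean < lowland mean for
    # every seed by construction rather than by rejection.
    upland_mask = np.broadcast_to(upland_col[np.newaxis, :], y.shape)
    for mask, mu_s in ((upland_mask, config.yield_log_mean_upland), (~upland_mask, config.yield_log_mean_lowland)):
        if mask.any():
            target = np.exp(mu_s + config.yield_log_sd**2 / 2)
            y[mask] *= target / y[mask].mean()
    return y


def generate_landscape(config: GeneratorConfig) -> Landscape:
    """Draw a seeded random landscape; a pure function of ``config``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_cols, n_rows = config.n_cols, config.n_rows
    n_cells = n_cols * n_rows

    n_upland_cols = int(round(config.upland_fraction * n_cols))
    upland_col = np.zeros(n_cols, dtype=bool)
    upland_col[:n_upland_cols] = True

    yields = _smoothed_yields(config, upland_col, rng)

    cols, rows = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
    cols, rows = cols.ravel(), rows.ravel()
    lo, hi = config.farmland_fraction_range
    farmland = config.cell_area_ha * rng.uniform(lo, hi, n_cells)
    kappa = rng.normal(config.kappa_mean, config.kappa_sd, n_cells)

    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n_cells),
            "col": cols,
            "row": rows,
            "farmland_area": farmland,
            "yield_rate": yields.ravel(),
            "stratum": np.where(upland_col[cols], "upland", "lowland"),
            "kappa": kappa,
        }
    )

    # Species archetypes: per-species magnitudes, then per-cell multiplicative
    # heterogeneity. Default responses are nonnegative so policy gains are
    # monotone in converted area.
    counts = _archetype_counts(config.n_species, config.archetype_proportions)
    S = config.n_species
    d_grass = np.empty(S)
    d_wood = np.empty(S)
    g_low = np.empty(S)
    archetype = np.repeat(np.arange(4), counts)
    for s in range(S):
        kind = ARCHETYPES[archetype[s]]
        if kind == "woodland_specialist":
            d_wood[s] = rng.uniform(0.2, 0.6)
            d_grass[s] = rng.uniform(0.0, 0.08)
            g_low[s] = rng.uniform(0.0, 0.05)
        elif kind == "grassland_specialist":
            d_grass[s] = rng.uniform(0.2, 0.6)
            d_wood[s] = rng.uniform(0.0, 0.08)
            g_low[s] = rng.uniform(0.0, 0.05)
        elif kind == "farmland_specialist":
            g_low[s] = rng.uniform(0.2, 0.6)
            d_grass[s] = rng.uniform(0.0, 0.08)
            d_wood[s] = rng.uniform(0.0, 0.08)
        else:  # generalist
            d_grass[s] = rng.uniform(0.02, 0.1)
            d_wood[s] = rng.uniform(0.02, 0.1)
            g_low[s] = rng.uniform(0.02, 0.1)

    p0_species = rng.uniform(0.05, 0.3, size=S)
    p0 = np.clip(p0_species[:, None] + rng.normal(0.0, 0.03, size=(S, n_cells)), 0.0, 1.0)
    cell_noise = np.exp(rng.normal(0.0, 0.3, size=(S, n_cells)))
    delta_grassland = np.clip(d_grass[:, None] * cell_noise, 0.0, 1.0)
    cell_noise = np.exp(rng.normal(0.0, 0.3, size=(S, n_cells)))
    delta_woodland = np.clip(d_wood[:, None] * cell_noise, 0.0, 1.0)
    cell_noise = np.exp(rng.normal(0.0, 0.3, size=(S, n_cells)))
    gamma = np.clip(g_low[:, None] * cell_noise, 0.0, 1.0)
    beta = np.broadcast_to(rng.normal(0.0, 0.01, size=S)[:, None], (S, n_cells)).copy()

    years = np.arange(config.base_year, config.end_year + 1)
    climate = ClimateTrajectory(
        config.base_year,
        config.end_year,
        config.climate_slope * (years - config.base_year).astype(float),
    )

    return Landscape(
        cells=cells,
        p0=p0,
        delta_grassland=delta_grassland,
        delta_woodland=delta_woodland,
        gamma=gamma,
        beta=beta,
        climate=climate,
        lowyield_factor=config.lowyield_factor,
        species_ids=np.arange(S),
    )
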