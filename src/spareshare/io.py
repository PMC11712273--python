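"""Plain-text serialization: landscape tables, allocations, maps, sweeps.

A landscape round-trips through four files in a directory: ``cells.csv``,
``species.csv``, ``climate.csv`` and ``landscape.json`` (low-yield factor
and horizon years). Numeric fields are written as shortest-round-trip
decimal text, so ``read_landscape(write_landscape(L))`` is value-identical
to ``L``. Per-cell maps export as ``cell_id,col,row,value`` CSV or as ESRI
ASCII grids (row 0 of the landscape written first, i.e. northernmost; cell
size defaults to 2000 m).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .allocation import AllocationResult
from .landscape import (
    CELL_COLUMNS,
    CLIMATE_COLUMNS,
    SPECIES_COLUMNS,
    ClimateTrajectory,
    Landscape,
)

_FLOAT_FMT = "%.17g"

CELLS_FILE = "cells.csv"
SPECIES_FILE = "species.csv"
CLIMATE_FILE = "climate.csv"
HEADER_FILE = "landscape.json"


def write_landscape(landscape: Landscape, path) -> Path:
    """Write the four landscape files into directory ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    landscape.cells.to_csv(path / CELLS_FILE, index=False, float_format=_FLOAT_FMT)

    S, N = landscape.n_species, landscape.n_cells
    cell_ids = landscape.cells["cell_id"].to_numpy()
    species = pd.DataFrame(
        {
            "species_id": np.repeat(landscape.species_ids, N),
            "cell_id": np.tile(cell_ids, S),
            "p0": landscape.p0.ravel(),
            "delta_grassland": landscape.delta_grassland.ravel(),
            "delta_woodland": landscape.delta_woodland.ravel(),
            "gamma": landscape.gamma.ravel(),
            "beta": landscape.beta.ravel(),
        }
    )
    species.to_csv(path / SPECIES_FILE, index=False, float_format=_FLOAT_FMT)

    climate = pd.DataFrame(
        {"year": landscape.climate.years, "anomaly": landscape.climate.anomaly}
    )
    climate.to_csv(path / CLIMATE_FILE, index=False, float_format=_FLOAT_FMT)

    header = {
        "lowyield_factor": landscape.lowyield_factor,
        "base_year": landscape.climate.base_year,
        "end_year": landscape.climate.end_year,
    }
    (path / HEADER_FILE).write_text(json.dumps(header, indent=2) + "\n")
    return path


def _check_columns(df: pd.DataFrame, expected: list[str], filename: str) -> None:
    missing = [c for c in expected if c not in df.columns]
    extra = [c for c in df.columns if c not in expected]
    if missing:
        raise ValueError(f"{filename}: missing column(s) {missing}")
    if extra:
        raise ValueError(f"{filename}: unexpected column(s) {extra}")


def read_landscape(path) -> Landscape:
    """Read a landscape directory, validating schema and invariants."""
    path = Path(path)
    for name in (CELLS_FILE, SPECIES_FILE, CLIMATE_FILE, HEADER_FILE):
        if not (path / name).exists():
            raise FileNotFoundError(f"landscape file {name} not found in {path}")
    cells = pd.read_csv(path / CELLS_FILE, float_precision="round_trip")
    _check_columns(cells, CELL_COLUMNS, CELLS_FILE)
    cells = cells[CELL_COLUMNS].sort_values("cell_id").reset_index(drop=True)

    species = pd.read_csv(path / SPECIES_FILE, float_precision="round_trip")
    _check_columns(species, SPECIES_COLUMNS, SPECIES_FILE)
    bad = species[(species["p0"] < 0) | (species["p0"] > 1)]
    if len(bad):
        row = bad.iloc[0]
        raise ValueError(
            f"{SPECIES_FILE}: baseline occupancy p0={row['p0']} outside [0, 1] "
            f"for species_id {int(row['species_id'])}, cell_id {int(row['cell_id'])}"
        )
    unknown = set(species["cell_id"]) - set(cells["cell_id"])
    if unknown:
        raise ValueError(f"{SPECIES_FILE}: references unknown cell_id(s) {sorted(unknown)[:5]}")

    species_ids = np.sort(species["species_id"].unique())
    cell_ids = cells["cell_id"].to_numpy()
    S, N = len(species_ids), len(cell_ids)
    if len(species) != S * N:
        raise ValueError(
            f"{SPECIES_FILE}: expected one row per (species, cell) pair "
            f"({S} x {N} = {S * N}), got {len(species)}"
        )
    sid_idx = {s: i for i, s in enumerate(species_ids)}
    cid_idx = {c: i for i, c in enumerate(cell_ids)}
    rows = species["species_id"].map(sid_idx).to_numpy()
    cols = species["cell_id"].map(cid_idx).to_numpy()
    mats = {}
    for col in ("p0", "delta_grassland", "delta_woodland", "gamma", "beta"):
        m = np.full((S, N), np.nan)
        m[rows, cols] = species[col].to_numpy(dtype=float)
        if np.isnan(m).any():
            raise ValueError(f"{SPECIES_FILE}: species table does not cover every cell")
        mats[col] = m

    climate_df = pd.read_csv(path / CLIMATE_FILE, float_precision="round_trip")
    _check_columns(climate_df, CLIMATE_COLUMNS, CLIMATE_FILE)
    header = json.loads((path / HEADER_FILE).read_text())
    climate_df = climate_df.sort_values("year")
    climate = ClimateTrajectory(
        int(header["base_year"]),
        int(header["end_year"]),
        climate_df["anomaly"].to_numpy(dtype=float),
    )
    return Landscape(
        cells=cells,
        p0=mats["p0"],
        delta_grassland=mats["delta_grassland"],
        delta_woodland=mats["delta_woodland"],
        gamma=mats["gamma"],
        beta=mats["beta"],
        climate=climate,
        lowyield_factor=float(header["lowyield_factor"]),
        species_ids=species_ids,
    )


def write_allocation(allocation: AllocationResult, landscape: Landscape, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "cell_id": landscape.cells["cell_id"],
            "habitat_ha": allocation.habitat_ha,
            "lowyield_ha": allocation.lowyield_ha,
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def _grid_from_values(values: np.ndarray, landscape: Landscape) -> np.ndarray:
    cols = landscape.cells["col"].to_numpy()
    rows = landscape.cells["row"].to_numpy()
    n_cols, n_rows = cols.max() + 1, rows.max() + 1
    if landscape.n_cells != n_cols * n_rows or len(set(zip(cols, rows))) != landscape.n_cells:
        raise ValueError("landscape grid is not rectangular-complete; cannot rasterize")
    grid = np.full((n_rows, n_cols), np.nan)
    grid[rows, cols] = values
    return grid


def write_map(values, landscape: Landscape, path, format: str = "esri_ascii", cellsize: float = 2000.0) -> Path:
    """Export per-cell values as an ESRI ASCII grid or a long-format CSV.

    ESRI ASCII rows are written north-to-south with landscape row 0 as the
    northernmost row.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (landscape.n_cells,):
        raise ValueError("values must cover all cells")
    path = Path(path)
    if format == "csv":
        pd.DataFrame(
            {
                "cell_id": landscape.cells["cell_id"],
                "col": landscape.cells["col"],
                "row": landscape.cells["row"],
                "value": values,
            }
        ).to_csv(path, index=False, float_format=_FLOAT_FMT)
        return path
    if format != "esri_ascii":
        raise ValueError(f"unknown map format {format!r}; expected 'esri_ascii' or 'csv'")
    grid = _grid_from_values(values, landscape)
    n_rows, n_cols = grid.shape
    lines = [
        f"ncols {n_cols}",
        f"nrows {n_rows}",
        "xllcorner 0",
        "yllcorner 0",
        f"cellsize {_FLOAT_FMT % cellsize}",
        "NODATA_value -9999",
    ]
    for r in range(n_rows):  # row 0 is the northernmost row
        row_vals = np.where(np.isnan(grid[r]), -9999.0, grid[r])
        lines.append(" ".join(_FLOAT_FMT % v for v in row_vals))
    path.write_text("\n".join(lines) + "\n")
    return path


def write_sweep(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path
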