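import numpy as np
import pandas as pd
import pytest

from spareshare import GeneratorConfig, Landscape, generate_landscape, toy_landscape
from spareshare.landscape import ClimateTrajectory


@pytest.fixture
def t4() -> Landscape:
    return toy_landscape()


@pytest.fixture(scope="session")
def default_landscape() -> Landscape:
    """The default seeded study landscape: 40x40 cells, 100 species, seed 42."""
    return generate_landscape(GeneratorConfig(seed=42))


def make_landscape(
    areas,
    yields,
    delta_grassland=None,
    delta_woodland=None,
    gamma=None,
    p0=None,
    beta=None,
    kappa=None,
    anomaly=None,
    lowyield_factor=0.1,
    n_cols=None,
):
    """Build a small landscape directly from arrays (single row of cells by
    default); response matrices default to a single indifferent species."""
    areas = np.asarray(areas, dtype=float)
    yields = np.asarray(yields, dtype=float)
    n = len(areas)
    n_cols = n_cols or n
    if delta_grassland is None:
        delta_grassland = np.zeros((1, n))
    delta_grassland = np.atleast_2d(np.asarray(delta_grassland, dtype=float))
    S = delta_grassland.shape[0]
    delta_woodland = (
        np.atleast_2d(delta_woodland) if delta_woodland is not None else np.zeros((S, n))
    )
    gamma = np.atleast_2d(gamma) if gamma is not None else np.zeros((S, n))
    p0 = np.atleast_2d(p0) if p0 is not None else np.full((S, n), 0.2)
    beta = np.atleast_2d(beta) if beta is not None else np.zeros((S, n))
    kappa = np.asarray(kappa, dtype=float) if kappa is not None else np.zeros(n)
    if anomaly is None:
        anomaly = np.zeros(41)
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "col": np.arange(n) % n_cols,
            "row": np.arange(n) // n_cols,
            "farmland_area": areas,
            "yield_rate": yields,
            "stratum": ["lowland"] * n,
            "kappa": kappa,
        }
    )
    return Landscape(
        cells=cells,
        p0=np.asarray(p0, dtype=float),
        delta_grassland=delta_grassland,
        delta_woodland=np.asarray(delta_woodland, dtype=float),
        gamma=np.asarray(gamma, dtype=float),
        beta=np.asarray(beta, dtype=float),
        climate=ClimateTrajectory(2020, 2020 + len(anomaly) - 1, np.asarray(anomaly, dtype=float)),
        lowyield_factor=lowyield_factor,
    )
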