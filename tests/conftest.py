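import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from arealrisk import geo, incidence, synth


def square_lattice(rows: int, cols: int, size: float = 1.0) -> list[geo.UnitGeometry]:
    """Regular grid of unit squares, ids 'r-c'."""
    units = []
    for r in range(rows):
        for c in range(cols):
            x0, y0 = c * size, r * size
            poly = Polygon(
                [(x0, y0), (x0 + size, y0), (x0 + size, y0 + size), (x0, y0 + size)]
            )
            units.append(geo.UnitGeometry(unit_id=f"{r}-{c}", polygon=poly))
    return units


@pytest.fixture(scope="session")
def lattice_3x3():
    return square_lattice(3, 3)


@pytest.fixture(scope="session")
def clustered_sim():
    """One simulated study with a planted RR-2 cluster, shared across tests."""
    cfg = synth.SimConfig(
        seed=7,
        clusters=[
            synth.PlantedCluster(
                center=(9500.0, 9500.0), radius=2700.0, disease="caries", rr=2.0
            )
        ],
    )
    units, grid = synth.simulate_geography(cfg)
    persons = synth.simulate_persons(cfg, grid)
    return cfg, units, grid, persons


@pytest.fixture(scope="session")
def sim_rate_table(clustered_sim):
    cfg, units, grid, persons = clustered_sim
    rook = geo.build_contiguity_weights(units, order="rook")
    pops = geo.unit_centroids(grid)["population"]
    return incidence.rate_table(
        persons, ["caries"], rook_weights=rook, populations=pops
    )


def make_persons(rows: list[dict]) -> pd.DataFrame:
    """Tiny person table from literal dicts; date strings become datetimes."""
    df = pd.DataFrame(rows)
    for col in df.columns:
        if col in ("entry", "exit") or df[col].dtype == object and col not in (
            "person_id",
            "unit_id",
            "sex",
        ):
            try:
                df[col] = pd.to_datetime(df[col])
            except (ValueError, TypeError):
                pass
    return df
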