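import numpy as np
import pytest
from hypothesis import settings

from anppgrid import features as feat
from anppgrid import world as wm

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_world() -> wm.SyntheticWorld:
    """A 16x16, 21-year world with all default forcing, shared across tests."""
    spec = wm.WorldSpec(
        rows=16, cols=16, year_start=1965, year_end=2005,
        baseline_start=1970, baseline_end=2000, seed=42,
    )
    return wm.generate_world(spec)


@pytest.fixture(scope="session")
def quiet_world() -> wm.SyntheticWorld:
    """A world with no trends, noise or climate sensitivity: truth is constant."""
    return wm.generate_world(
        wm.quiet_spec(rows=10, cols=10, year_start=1970, year_end=1990,
                      baseline_start=1970, baseline_end=1990, seed=7)
    )


def world_features(world: wm.SyntheticWorld):
    """Annual cubes, normals and the feature-table ingredients for a world."""
    annual = {
        n: feat.aggregate_annual(world.monthly[n], n)
        for n in ("temperature", "precipitation", "radiation", "pet")
    }
    annual["aridity"] = feat.annual_aridity(annual["precipitation"], annual["pet"])
    normals = {n: feat.compute_normals(c, world.spec.baseline_window) for n, c in annual.items()}
    return annual, normals


@pytest.fixture(scope="session")
def study(small_world):
    """Sites + feature table for the small world."""
    sites = wm.sample_sites(small_world, n_sites=120, obs_per_site=2, obs_noise_sd=20.0, seed=3)
    annual, normals = world_features(small_world)
    table = feat.build_feature_table(sites, normals, annual, small_world.mean_anpp, small_world.meta)
    return {"world": small_world, "sites": sites, "annual": annual, "normals": normals, "table": table}


@pytest.fixture(scope="session")
def pipeline40():
    """The desk-scale study system: 40x40 cells, 66 years, ~300 observations.

    Shared by the parameter-recovery and strategy-ordering end-to-end tests.
    """
    world = wm.generate_world(wm.WorldSpec(rows=40, cols=40, seed=11))
    sites = wm.sample_sites(world, n_sites=300, obs_per_site=1, obs_noise_sd=25.0, seed=5)
    annual, normals = world_features(world)
    table = feat.build_feature_table(sites, normals, annual, world.mean_anpp, world.meta)
    cols = feat.predictor_columns(table)
    strat = table[["mean_anpp"] + [c for c in table.columns if c.startswith("baseline_")]].values
    return {
        "world": world,
        "table": table,
        "X": table[cols].values,
        "y": table["anpp_g_m2"].values,
        "columns": cols,
        "strat": strat,
        "lon": table["lon"].values,
        "lat": table["lat"].values,
    }


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
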