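import numpy as np
import pandas as pd
import pytest

from phylodecline.synthetic import ClimateWorld, gen_climate, gen_tree
from phylodecline.trees import parse_newick


@pytest.fixture(scope="session")
def three_tip_tree():
    return parse_newick("((A:1.0,B:1.0):1.0,C:2.0);")


@pytest.fixture(scope="session")
def balanced_four_tip_tree():
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def bd_tree_50():
    return gen_tree(50, seed=11)


@pytest.fixture(scope="session")
def small_world():
    return gen_climate((16, 16), seed=5)


@pytest.fixture()
def flat_world():
    """Tiny hand-built world with known latitudes and layers."""
    lat = np.array([30.0, 10.0, -10.0, -30.0])
    amt = np.arange(16, dtype=float).reshape(4, 4)
    tar = np.full((4, 4), 12.0)
    cmi = np.linspace(-100, 100, 16).reshape(4, 4)
    mask = np.ones((4, 4), dtype=bool)
    return ClimateWorld(
        cell_area_km2=10.0,
        lat_centers=lat,
        layers={"amt": amt, "tar": tar, "cmi": cmi},
        land_mask=mask,
    )


@pytest.fixture()
def toy_species_table():
    """Small complete table with all raw predictor columns."""
    rng = np.random.default_rng(3)
    n = 24
    return pd.DataFrame(
        {
            "body_size_mm": rng.lognormal(3.5, 0.5, n),
            "range_size_km2": rng.lognormal(5.0, 1.0, n),
            "abs_lat_mid": rng.uniform(0, 60, n),
            "amt_mean": rng.uniform(-5, 28, n),
            "tar_mean": rng.uniform(5, 40, n),
            "cmi_mean": rng.uniform(-150, 250, n),
            "prev_amt": rng.uniform(0.001, 0.05, n),
            "prev_cmi": rng.uniform(0.001, 0.05, n),
            "trend": (["decreasing"] * 10 + ["stable"] * 10
                      + ["increasing"] * 1 + ["unknown"] * 3),
        },
        index=[f"s{i:03d}" for i in range(n)],
    )
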