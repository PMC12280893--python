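import datetime as dt

import numpy as np
import pytest

from nichetrack.io_formats import SpecimenRecord, Tree, TreeNode
from nichetrack.synthetic_data import ScenarioSpec, gen_scenario, gen_tree


def make_star_tree(n: int, branch: float = 1.0) -> Tree:
    root = TreeNode()
    for i in range(n):
        root.add_child(TreeNode(f"s{i}", branch))
    return Tree(root)


def make_record(specimen_id="sp1", species="A", lat=38.0, lon=-120.0,
                elevation_m=500.0, collection_date=dt.date(1983, 4, 25),
                error_radius_km=0.5, has_buds=False, has_flowers=True,
                has_fruits=False, county="county_0") -> SpecimenRecord:
    return SpecimenRecord(specimen_id, species, lat, lon, elevation_m,
                          collection_date, error_radius_km, has_buds,
                          has_flowers, has_fruits, county)


@pytest.fixture(scope="session")
def tree8():
    """8-tip reference tree shared with the frozen external-oracle values."""
    return gen_tree(8, 21)


@pytest.fixture(scope="session")
def traits8(tree8):
    rng = np.random.default_rng(99)
    x = np.round(rng.standard_normal(8) * 2 + 10, 6)
    y = np.round(x * 0.8 + rng.standard_normal(8), 6)
    labels = tree8.tip_labels
    return dict(zip(labels, x)), dict(zip(labels, y))


@pytest.fixture(scope="session")
def small_scenario():
    """A compact but full scenario bundle used by several module tests."""
    spec = ScenarioSpec(n_species=8, n_specimens_per_species=15, seed=17,
                        soil_whc_offset_mm=-20.0,
                        coarse_slope_pct_per_degc=-5.0)
    return gen_scenario(spec)
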