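import numpy as np
import pandas as pd
import pytest

from emsloc import synthetic as sc
from emsloc.network import od_matrix


@pytest.fixture(scope="session")
def small_city():
    """A 60-area, 8-site synthetic city shared across read-only tests."""
    return sc.generate_city(
        seed=11, n_rows=10, n_cols=10, spacing_m=500.0,
        n_areas=60, total_pop=25_000, n_sites=8, slots_per_site=2,
        n_admin=4, scatter_points=True,
    )


@pytest.fixture(scope="session")
def small_od(small_city):
    origins = small_city.areas.table.rename(
        columns={"centroid_x": "x", "centroid_y": "y"})[["x", "y"]]
    return od_matrix(small_city.graph, origins, small_city.sites[["x", "y"]])


@pytest.fixture()
def toy_od():
    """Two demand areas A, B and two sites s1, s2 with hand distances."""
    od = pd.DataFrame([[1000.0, 4000.0], [5000.0, 2000.0]],
                      index=pd.Index(["A", "B"], name="area_id"),
                      columns=pd.Index([1, 2], name="site_id"))
    weights = pd.Series([2.0, 3.0], index=od.index)
    return od, weights


def random_instance(seed, n_areas=30, n_sites=10):
    """A random weighted p-median instance (not a road network)."""
    rng = np.random.default_rng(seed)
    od = pd.DataFrame(rng.uniform(100, 10_000, (n_areas, n_sites)),
                      index=pd.RangeIndex(n_areas, name="area_id"),
                      columns=pd.Index(range(n_sites), name="site_id"))
    w = pd.Series(rng.integers(0, 20, n_areas).astype(float), index=od.index)
    return od, w
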