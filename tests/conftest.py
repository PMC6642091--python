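import numpy as np
import pandas as pd
import pytest

from divstab import synth
from divstab.data_core import Dataset


@pytest.fixture(scope="session")
def small_survey():
    """A compact survey (12 sites x 3 grids x 60 plots) with known truth."""
    cfg = synth.GeneratorConfig(n_sites=12, grids_per_site=(3, 3),
                                plots_per_grid=(60, 60), seed=42)
    return synth.generate(cfg)


@pytest.fixture()
def toy_dataset():
    """Two grids in one site, hand-sized for exact assertions."""
    rows = []
    rng = np.random.default_rng(0)
    for gid in ("g1", "g2"):
        for i in range(10):
            rows.append({"site_id": "s1", "grid_id": gid, "plot_id": f"{gid}p{i}",
                         "richness": int(rng.integers(1, 6)),
                         "biomass": float(rng.uniform(50, 400)),
                         "grassland_type": "temperate"})
    plots = pd.DataFrame(rows)
    sites = pd.DataFrame({"site_id": ["s1"], "longitude": [10.0],
                          "latitude": [45.0], "hemisphere": ["N"]})
    return Dataset(plots=plots, sites=sites)


def make_dataset(counts: dict[int, int], biomass=None) -> Dataset:
    """Dataset with a prescribed number of plots per richness level."""
    rows = []
    i = 0
    for rich, n in counts.items():
        for _ in range(n):
            b = biomass(rich, i) if biomass else 100.0 + 3.0 * rich + i
            rows.append({"site_id": "s1", "grid_id": "g1", "plot_id": f"p{i}",
                         "richness": rich, "biomass": float(b),
                         "grassland_type": "temperate"})
            i += 1
    return Dataset(plots=pd.DataFrame(rows))
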