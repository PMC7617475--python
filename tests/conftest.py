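import numpy as np
import pandas as pd
import pytest

from tikp.datatypes import FishTable, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_config():
    return SimulationConfig(seed=7, n_genes=300, n_peaks=400, n_cells=150)


def make_fish_table(bursts, n_cells, intensity=10.0, radius=2.0, condition=""):
    """Build a FishTable with the first `bursts` alleles bursting."""
    n_alleles = 2 * n_cells
    burst = np.zeros(n_alleles, dtype=bool)
    burst[:bursts] = True
    return FishTable(
        table=pd.DataFrame(
            {
                "cell_id": np.repeat([f"c{i}" for i in range(n_cells)], 2),
                "allele": np.tile([1, 2], n_cells),
                "burst": burst,
                "Intensity_MaxIntensity": np.where(burst, intensity, np.nan),
                "AreaShape_MeanRadius": np.where(burst, radius, np.nan),
            }
        ),
        condition=condition,
    )
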