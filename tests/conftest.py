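import numpy as np
import pandas as pd
import pytest

from cghcnv.genome import GenomeConfig, make_genome, plant_cnvs
from cghcnv.simulate import tile_probes


@pytest.fixture(scope="session")
def small_genome():
    """4 x 2 Mb genome for unit tests."""
    return make_genome(
        GenomeConfig(n_chromosomes=4, chrom_length=2_000_000), seed=11
    )


@pytest.fixture(scope="session")
def small_truth(small_genome):
    return plant_cnvs(
        small_genome,
        n_per_sample=4,
        length_range=(80_000, 200_000),
        shared_fraction=0.5,
        seed=21,
    )


@pytest.fixture(scope="session")
def small_layout(small_genome):
    return tile_probes(small_genome, target_spacing=7_900, seed=31)


def make_scan_frame(net_red, net_green, bg=100.0):
    """Build a minimal spot table from desired net intensities."""
    n = len(net_red)
    ncol = int(np.ceil(np.sqrt(n)))
    return pd.DataFrame(
        {
            "probe_id": [f"p{i:06d}" for i in range(n)],
            "grid_row": np.arange(n) // ncol,
            "grid_col": np.arange(n) % ncol,
            "ch_red_fg": np.asarray(net_red, dtype=float) + bg,
            "ch_red_bg": bg,
            "ch_green_fg": np.asarray(net_green, dtype=float) + bg,
            "ch_green_bg": bg,
            "qc_flag": "pass",
        }
    )
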