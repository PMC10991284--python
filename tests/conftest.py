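import numpy as np
import pandas as pd
import pytest

from gcbreg.simulate import SimConfig, gen_genome, gen_peak_counts


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(seed=7, n_peaks=200, n_genes=60, n_cells_per_group=150)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    genome = gen_genome(small_cfg)
    counts, groups, peaks, motifs, gc, truth = gen_peak_counts(small_cfg, genome)
    return {
        "cfg": small_cfg,
        "genome": genome,
        "counts": counts,
        "groups": groups,
        "peaks": peaks,
        "motifs": motifs,
        "gc": gc,
        "truth": truth,
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
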