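import numpy as np
import pandas as pd
import pytest

from cftrdms import simulate as sim
from cftrdms.scoring import FractionCountTable


@pytest.fixture(scope="session")
def small_library():
    return sim.make_variant_library(20, seed=11)


@pytest.fixture(scope="session")
def small_sort_seq(small_library):
    cfg = sim.SortSeqSimConfig(
        n_variants=20, cells_per_pool=20_000, reads_per_fraction=10_000,
        seq_error_rate=0.002, seed=12,
    )
    return sim.simulate_sort_seq(small_library, cfg)


@pytest.fixture
def toy_table():
    counts = pd.DataFrame(
        {
            "frac1": [10, 1, 0, 5],
            "frac2": [0, 1, 0, 5],
            "frac3": [0, 1, 0, 5],
            "frac4": [0, 1, 0, 5],
        },
        index=pd.Index(["A1G", "C2T", "D3E", "F4L"], name="variant_id"),
        dtype=np.int64,
    )
    return FractionCountTable(
        counts=counts, fraction_means=np.array([100.0, 200.0, 300.0, 400.0])
    )


@pytest.fixture(scope="session")
def tmt_sim():
    cfg = sim.InteractomeSimConfig(
        n_proteins=600, n_true_interactors=8,
        background_sigma=0.5, effect_sizes=tuple([2.5] * 8),
        n_replicates=3, both_cell_lines=True, ko_shift=0.8, seed=21,
    )
    return sim.simulate_tmt_interactome(cfg)
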