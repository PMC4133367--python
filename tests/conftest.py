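import numpy as np
import pandas as pd
import pytest

from ibselect.counts import CountTable
from ibselect.pipeline import default_sim_config
from ibselect.simulate import draw_library, evolve_rounds


@pytest.fixture(scope="session")
def small_sim():
    """One small six-round spiked experiment shared across tests."""
    cfg = default_sim_config(
        seed=7, n_clones=800, n_spiked=12, n_spike_clusters=4, depth_per_round=30_000,
        spike_naive_freq_range=(1e-4, 2e-4), spike_fold_range=(50.0, 100.0),
    )
    clones, truth = draw_library(cfg)
    table = evolve_rounds(clones, truth, cfg)
    return cfg, clones, truth, table


@pytest.fixture
def toy_table():
    """Tiny hand-built count table over the six-round design."""
    rounds = ["naive", "R3a", "R3", "R5", "R7", "R8"]
    counts = pd.DataFrame(
        [
            [10, 11, 9, 10, 10, 11],      # flat
            [2, 6, 7, 25, 80, 90],        # enriched
            [0, 0, 1, 4, 12, 15],         # enriched, absent from naive
            [50, 40, 42, 30, 20, 18],     # declining
            [5, 0, 6, 5, 4, 6],           # noisy flat
        ],
        index=pd.Index([f"t{i}" for i in range(5)], name="clone_id"),
        columns=rounds,
    )
    seqs = pd.Series(
        ["GCTAGCGCTAGCGCTAGCGCTAGCGCTAGC",
         "TGTGCTCGTGATTATGTTTGGGGTCAGGGT",
         "GCTCGTGATTATGTTTGA" + "GCTAGCGCTAGC",
         "TGTGCTCGTGATTATGTTCAGGGTACTACT",
         "GCTAGCGCTAGCGCTAGCGCTAGCGCTAG"],
        index=counts.index,
        name="sequence",
    )
    return CountTable(counts, seqs)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
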