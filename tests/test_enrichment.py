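"""Resampled rank statistic, permutation FDR, and enrichment factors."""

import numpy as np
import pandas as pd
import pytest

from ibselect.counts import CountTable
from ibselect.enrichment import (
    TestConfig,
    enrichment_factor,
    enrichment_factors,
    permutation_fdr,
    resampled_rank_statistic,
)
from ibselect.filters import filter_present_both
from ibselect.pipeline import default_sim_config
from ibselect.simulate import draw_library, evolve_rounds

ROUNDS = ["naive", "R3a", "R3", "R5", "R7", "R8"]


def _table(rows, depths=None, seqs=None):
    counts = pd.DataFrame(rows, columns=ROUNDS)
    counts.index = pd.Index([f"c{i}" for i in range(len(counts))], name="clone_id")
    if depths is not None:
        # pad with a filler clone so column sums equal the requested depths
        filler = np.asarray(depths) - counts.sum(axis=0).to_numpy()
        assert (filler >= 0).all()
        counts.loc["zfill"] = filler
    return CountTable(counts, seqs)


def test_identical_counts_equal_depths_statistic_zero():
    stat = resampled_rank_statistic([7, 7, 7, 7, 7, 7], [100] * 6, TestConfig())
    assert stat == 0.0


def test_extreme_separation_maximal_statistic():
    stat = resampled_rank_statistic([0, 0, 0, 10, 10, 10], [100] * 6, TestConfig())
    assert stat == pytest.approx(4.5)


def test_statistic_antisymmetric_under_group_swap(rng):
    counts = rng.integers(0, 50, size=6)
    depths = rng.integers(500, 1500, size=6)
    cfg = TestConfig(seed=5)
    a = resampled_rank_statistic(counts, depths, cfg)
    b = resampled_rank_statistic(
        np.concatenate([counts[3:], counts[:3]]),
        np.concatenate([depths[3:], depths[:3]]),
        cfg,
    )
    assert a == pytest.approx(-b, abs=0.15)  # thinning is re-randomized


def test_statistic_invariant_to_within_group_relabeling(rng):
    counts = rng.integers(0, 50, size=6)
    depths = [800] * 6  # equal depths: deterministic, exact invariance
    cfg = TestConfig()
    a = resampled_rank_statistic(counts, depths, cfg)
    swapped = counts[[1, 0, 2, 5, 3, 4]]
    b = resampled_rank_statistic(swapped, depths, cfg)
    assert a == b


def test_equal_depth_statistic_matches_mannwhitney_oracle(rng):
    """With equal depths (no thinning) the statistic is the centered
    Wilcoxon rank-sum, cross-checked against scipy's U statistic."""
    from scipy.stats import mannwhitneyu

    for _ in range(25):
        counts = rng.integers(0, 30, size=6)
        stat = resampled_rank_statistic(counts, [500] * 6, TestConfig())
        u = mannwhitneyu(counts[3:], counts[:3], alternative="two-sided").statistic
        assert stat == pytest.approx(u - 4.5)  # U = R_late - n(n+1)/2; center 3*3/2


def test_thinned_statistic_matches_bruteforce_oracle(rng):
    """Unequal depths: averaged thinned statistic agrees with an
    independent per-element binomial thinning oracle within MC error."""
    from scipy.stats import rankdata

    counts = np.array([4, 9, 6, 30, 45, 38])
    depths = np.array([1000, 2000, 1500, 3000, 900, 2500])
    cfg = TestConfig(n_resamples=4000, seed=9)
    mine = resampled_rank_statistic(counts, depths, cfg)
    dmin = depths.min()
    oracle_rng = np.random.default_rng(12345)  # independent stream
    vals = []
    for _ in range(4000):
        thinned = [oracle_rng.binomial(c, dmin / d) for c, d in zip(counts, depths)]
        r = rankdata(thinned)
        vals.append(r[3:].sum() - 10.5)
    oracle = np.mean(vals)
    se = np.std(vals) / np.sqrt(len(vals))
    assert mine == pytest.approx(oracle, abs=5 * se + 0.05)


def test_permutation_fdr_flags_spiked_not_depleted(small_sim):
    cfg, clones, truth, table = small_sim
    sub = table.subset(filter_present_both(table))
    rec = permutation_fdr(sub, TestConfig(seed=1))
    spiked = [c for c in truth.index[truth["is_spiked"]] if c in rec.index]
    assert (rec.loc[spiked, "direction"] == "enriched").all()
    assert (rec["direction"] == "depleted").sum() == 0
    assert rec["qvalue"].between(0, 1).all()


def test_null_table_produces_no_calls():
    cfg = default_sim_config(seed=42, n_clones=2000, n_spiked=0, depth_per_round=50_000)
    clones, truth = draw_library(cfg)
    table = evolve_rounds(clones, truth, cfg)
    sub = table.subset(filter_present_both(table))
    rec = permutation_fdr(sub, TestConfig(seed=2))
    assert (rec["direction"] != "null").sum() == 0


def test_qvalue_monotone_in_statistic(small_sim):
    """Nestedness: a larger statistic never has a larger q-value."""
    _, _, _, table = small_sim
    rec = permutation_fdr(table.subset(filter_present_both(table)), TestConfig(seed=3))
    pos = rec[rec["statistic"] > 0].sort_values("statistic")
    assert (pos["qvalue"].diff().dropna() <= 1e-12).all()
    neg = rec[rec["statistic"] < 0].sort_values("statistic", ascending=False)
    assert (neg["qvalue"].diff().dropna() <= 1e-12).all()


def test_call_sets_nested_across_thresholds(small_sim):
    _, _, _, table = small_sim
    sub = table.subset(filter_present_both(table))
    rec_strict = permutation_fdr(sub, TestConfig(seed=4, fdr_threshold=0.01))
    rec_loose = permutation_fdr(sub, TestConfig(seed=4, fdr_threshold=0.10))
    strict = set(rec_strict.index[rec_strict["direction"] == "enriched"])
    loose = set(rec_loose.index[rec_loose["direction"] == "enriched"])
    assert strict <= loose


def test_determinism_fixed_seed(small_sim):
    _, _, _, table = small_sim
    sub = table.subset(filter_present_both(table))
    a = permutation_fdr(sub, TestConfig(seed=11))
    b = permutation_fdr(sub, TestConfig(seed=11))
    pd.testing.assert_frame_equal(a, b)


def test_enrichment_factor_arithmetic():
    rows = [[10, 10, 10, 10, 17, 10],
            [10, 10, 10, 10, 10, 10]]
    depths = [100_000_000] + [10_000_000] * 3 + [1_000_000, 1_000_000]
    # clone 0: f(naive)=1e-7, f(R7)=1.7e-5, f(R8)=1e-5 -> E = 170
    table = _table(rows, depths=depths)
    assert enrichment_factor(table, "c0") == pytest.approx(170.0, rel=1e-6)
    # identical frequencies -> E = 1... clone 1 f(naive)=1e-6 but f(R7)=1e-5
    f = table.freqs
    expected = max(f.at["c1", "R7"], f.at["c1", "R8"]) / f.at["c1", "naive"]
    assert enrichment_factor(table, "c1") == pytest.approx(expected)


def test_enrichment_factor_is_frequency_ratio_not_count_ratio():
    rows = [[5, 0, 0, 0, 5, 5]]
    depths = [1000, 1000, 1000, 1000, 4000, 4000]
    table = _table(rows, depths=depths)
    # counts equal but depths differ 4x: E = (5/4000)/(5/1000) = 0.25
    assert enrichment_factor(table, "c0") == pytest.approx(0.25)


def test_enrichment_factor_undefined_without_naive_presence():
    table = _table([[0, 0, 0, 5, 50, 60]], depths=[1000] * 6)
    assert np.isnan(enrichment_factor(table, "c0"))


def test_median_spiked_enrichment_near_configured_fold(small_sim):
    cfg, clones, truth, table = small_sim
    ef = enrichment_factors(table)
    spiked = truth[truth["is_spiked"]]
    ratio = (ef.loc[spiked.index] / spiked["true_total_fold"]).dropna()
    assert 0.75 <= ratio.median() <= 1.25


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        TestConfig(group_early=("naive", "R5"), group_late=("R5", "R7"))
    with pytest.raises(ValueError):
        TestConfig(group_early=("naive",))
    with pytest.raises(ValueError):
        TestConfig(fdr_threshold=1.5)
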