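"""Loop distances, complete-linkage families, and family selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ibselect.clustering import (
    ClusterConfig,
    build_families,
    complete_linkage_cluster,
    distance_matrix,
    loop_distance,
    select_families,
)
from ibselect.counts import CountTable

AA = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=20)


@pytest.mark.parametrize(
    "a, b, d",
    [
        ("ARDY", "ARDYV", 1.0),   # unequal lengths
        ("ARDY", "ARDY", 0.0),
        ("ABCD", "ABXD", 0.25),
        ("AAAA", "CCCC", 1.0),
    ],
)
def test_loop_distance_values(a, b, d):
    assert loop_distance(a, b) == d


@given(AA, AA)
@settings(max_examples=100, deadline=None)
def test_loop_distance_semimetric(a, b):
    d = loop_distance(a, b)
    assert 0.0 <= d <= 1.0
    assert d == loop_distance(b, a)
    if len(a) == len(b):
        assert (d == 0.0) == (a == b)
    else:
        assert d == 1.0


def _brute_force_complete(labels, d, cut):
    """Independent oracle: recompute full max-linkage from scratch each merge,
    scanning all pairs, same tie rule (smallest label pair first)."""
    clusters = {lab: {lab} for lab in labels}
    idx = {lab: i for i, lab in enumerate(labels)}
    while len(clusters) > 1:
        candidates = []
        for a, b in itertools.combinations(sorted(clusters), 2):
            dist = max(d[idx[x], idx[y]] for x in clusters[a] for y in clusters[b])
            candidates.append((dist, a, b))
        dist, a, b = min(candidates)
        if dist > cut:
            break
        clusters[min(a, b)] = clusters.pop(a) | clusters.pop(b)
    return sorted(sorted(c) for c in clusters.values())


def _random_pool(rng, n=30):
    """Sequences with planted mutation clusters plus unrelated loops."""
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    seqs = set()
    while len(seqs) < n // 2:
        seqs.add("".join(rng.choice(alphabet, size=int(rng.integers(6, 14)))))
    base = sorted(seqs)
    out = set(base)
    for s in base:
        if len(out) >= n:
            break
        var = list(s)
        for p in rng.choice(len(s), size=max(1, len(s) // 5), replace=False):
            var[p] = str(rng.choice(alphabet))
        out.add("".join(var))
    return sorted(out)[:n]


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_complete_linkage_matches_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    seqs = _random_pool(rng)
    d = distance_matrix(seqs, {s: s for s in seqs})
    parts, _ = complete_linkage_cluster(seqs, d, cut=0.40)
    oracle = _brute_force_complete(seqs, d, 0.40)
    assert sorted(sorted(p) for p in parts) == oracle
    # complete-linkage guarantee: max intra-cluster distance <= cut
    idx = {s: i for i, s in enumerate(seqs)}
    for p in parts:
        for x, y in itertools.combinations(p, 2):
            assert d[idx[x], idx[y]] <= 0.40


def test_three_lengths_three_singletons():
    seqs = ["ARD", "ARDY", "ARDYV"]
    d = distance_matrix(seqs, {s: s for s in seqs})
    parts, _ = complete_linkage_cluster(seqs, d, cut=0.40)
    assert parts == [["ARD"], ["ARDY"], ["ARDYV"]]


def test_pair_plus_outlier():
    seqs = ["AAAA", "AAAC", "AACC"]  # d(1,2)=0.25, d(3,*)=0.5,0.25
    d = distance_matrix(seqs, {s: s for s in seqs})
    parts, _ = complete_linkage_cluster(seqs, d, cut=0.20)
    assert sorted(map(len, parts)) == [1, 1, 1]
    parts, _ = complete_linkage_cluster(seqs, d, cut=0.25)
    # AAAA+AAAC merge at 0.25; AACC joins only if max dist <= 0.25 (it is 0.5)
    assert sorted(sorted(p) for p in parts) == [["AAAA", "AAAC"], ["AACC"]]


def test_input_order_invariance(rng):
    seqs = _random_pool(rng, n=20)
    d = distance_matrix(seqs, {s: s for s in seqs})
    parts1, _ = complete_linkage_cluster(seqs, d, cut=0.40)
    order = list(rng.permutation(len(seqs)))
    seqs2 = [seqs[i] for i in order]
    d2 = distance_matrix(seqs2, {s: s for s in seqs2})
    parts2, _ = complete_linkage_cluster(seqs2, d2, cut=0.40)
    assert sorted(map(tuple, parts1)) == sorted(map(tuple, parts2))


def _table_for_families():
    rounds = ["naive", "R3", "R5", "R7", "R8"]
    rows = {
        # family A: two DNA variants of the same aa loop + one point variant
        "a1": ("TGTGCTCGTGAT", [10, 20, 40, 3000, 3500]),
        "a2": ("TGCGCTCGTGAT", [5, 10, 20, 1500, 1800]),   # same aa as a1 (CARD)
        "a3": ("TGTGCTATGGAT", [2, 6, 10, 600, 700]),      # CAMD, dist 0.25 to CARD
        # family B: different length -> its own family
        "b1": ("TGTCCTCCTCGTCCT", [8, 16, 30, 900, 1000]),
        # singleton at low frequency
        "c1": ("TGTAAAGATCAT", [1, 2, 4, 40, 50]),
    }
    counts = pd.DataFrame({r: [v[1][i] for v in rows.values()] for i, r in enumerate(rounds)},
                          index=pd.Index(rows.keys(), name="clone_id"))
    seqs = pd.Series({k: v[0] for k, v in rows.items()}, name="sequence")
    return CountTable(counts, seqs)


def test_build_families_pools_dna_variants_by_aa():
    table = _table_for_families()
    families, dendro = build_families(table, ClusterConfig())
    by_members = {tuple(f.members): f for f in families}
    fam_a = by_members[("a1", "a2", "a3")]
    assert fam_a.size == 2  # CARD (a1+a2 pooled) and CAMD: two distinct loops
    f = table.freqs
    assert fam_a.pooled_final_freq == pytest.approx(f.loc[["a1", "a2", "a3"], "R7"].sum())
    assert fam_a.representative == "CARD"  # aa loop of the most abundant member at R7
    exp = max(f.loc[["a1", "a2", "a3"], "R7"].sum(), f.loc[["a1", "a2", "a3"], "R8"].sum()) / \
        f.loc[["a1", "a2", "a3"], "naive"].sum()
    assert fam_a.family_enrichment == pytest.approx(exp)
    assert len(dendro) == len(families)


def test_select_families_size_and_frequency_rules():
    table = _table_for_families()
    families, _ = build_families(table, ClusterConfig())
    kept = select_families(families, min_members=2, min_final_freq=0.001)
    assert [tuple(f.members) for f in kept] == [("a1", "a2", "a3")]
    # singleton at high frequency still excluded by the size rule
    none = select_families([f for f in families if f.size == 1], min_members=2)
    assert none == []


def test_single_member_family_enrichment_reduces_to_clone_fold():
    table = _table_for_families()
    families, _ = build_families(table, ClusterConfig())
    b = next(f for f in families if f.members == ["b1"])
    f = table.freqs
    assert b.family_enrichment == pytest.approx(
        max(f.at["b1", "R7"], f.at["b1", "R8"]) / f.at["b1", "naive"]
    )


def test_newick_export_parses():
    import io

    from Bio import Phylo

    seqs = ["AAAA", "AAAC", "AACC", "GGGG"]
    d = distance_matrix(seqs, {s: s for s in seqs})
    _, dendro = complete_linkage_cluster(seqs, d, cut=0.5)
    for tree in dendro:
        parsed = Phylo.read(io.StringIO(tree.to_newick()), "newick")
        assert parsed.count_terminals() >= 1
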