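"""Clonotype family clustering of surviving VH CDR3 loops.

Distances between amino-acid loops follow a length-aware normalized Hamming
rule: 1.0 when the loops have different lengths, otherwise the fraction of
mismatched positions.  For equal-length loops, standardized antibody
numbering reduces to position-by-position comparison, so no gapped
alignment is needed.  Clustering is agglomerative with complete linkage
(cluster distance = maximum member pair distance) cut at 1 - identity
(default identity 0.60, cut 0.40), which guarantees a within-family
identity floor.  Ties in the merge order are broken by merging the
lexicographically smallest pair of cluster labels, where a cluster is
labelled by its smallest member label; the partition is therefore
independent of input order.

DNA variants translating to the same amino-acid loop are pooled before
clustering; family-level frequencies and enrichment are pooled over all
member DNA clonotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clones import translate_and_flag
from .counts import CountTable


def loop_distance(a: str, b: str) -> float:
    """Normalized Hamming distance; 1.0 when loop lengths differ."""
    if not a or not b:
        raise ValueError("empty loop sequence")
    if len(a) != len(b):
        return 1.0
    return sum(x != y for x, y in zip(a, b)) / len(a)


def distance_matrix(labels: list[str], seqs: dict[str, str]) -> np.ndarray:
    """Symmetric pairwise loop-distance matrix over ``labels``."""
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = loop_distance(seqs[labels[i]], seqs[labels[j]])
    return d


@dataclass
class Dendrogram:
    """Merge tree from agglomerative clustering (for Newick export)."""

    node: object  # label (leaf) or (left, right) tuple
    height: float = 0.0
    children: tuple = ()

    def to_newick(self) -> str:
        return self._fmt(self) + ";"

    @classmethod
    def _fmt(cls, t: "Dendrogram", parent_height: float | None = None) -> str:
        if not t.children:
            body = str(t.node)
        else:
            body = "(" + ",".join(cls._fmt(c, t.height) for c in t.children) + ")"
        if parent_height is None:
            return body
        return f"{body}:{max(parent_height - t.height, 0.0):.6g}"


def complete_linkage_cluster(
    labels: list[str],
    d: np.ndarray,
    cut: float = 0.40,
) -> tuple[list[list[str]], list[Dendrogram]]:
    """Complete-linkage agglomeration, stopped at the cut height.

    Returns (clusters, dendrograms); each cluster is the sorted member
    labels, ordered by cluster label.  Every within-cluster pair is at
    distance <= cut (the complete-linkage guarantee).
    """
    if d.shape != (len(labels), len(labels)):
        raise ValueError("distance matrix does not match labels")
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate labels")
    clusters: dict[str, list[int]] = {lab: [i] for i, lab in enumerate(labels)}
    trees: dict[str, Dendrogram] = {lab: Dendrogram(lab) for lab in labels}

    def linkage(a: str, b: str) -> float:
        ia, ib = clusters[a], clusters[b]
        return float(d[np.ix_(ia, ib)].max())

    while len(clusters) > 1:
        best = None
        names = sorted(clusters)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                dist = linkage(a, b)
                pair = (dist, a, b)
                if best is None or pair < best:
                    best = pair
        dist, a, b = best
        if dist > cut:
            break
        merged = min(a, b)
        clusters[merged] = clusters.pop(a) + clusters.pop(b) if merged == a else clusters.pop(b) + clusters.pop(a)
        ta, tb = trees.pop(a), trees.pop(b)
        trees[merged] = Dendrogram((ta.node, tb.node), dist, (ta, tb))

    parts = [sorted(labels[i] for i in idx) for _, idx in sorted(clusters.items())]
    dendro = [trees[k] for k in sorted(trees)]
    return parts, dendro


@dataclass
class Family:
    """A cluster of VH clonotypes sharing >= the identity floor.

    ``size`` counts distinct amino-acid loops; ``members`` lists all DNA
    clonotype ids pooled into the family.  Frequencies are pooled over
    members; the family enrichment is pooled max(f_R7, f_R8) over pooled
    f_naive.
    """

    family_id: str
    members: list[str]
    aa_seqs: list[str]
    size: int
    pooled_final_freq: float
    family_enrichment: float
    representative: str


@dataclass
class ClusterConfig:
    min_identity: float = 0.60
    naive: str = "naive"
    r7: str = "R7"
    r8: str = "R8"
    min_members: int = 2
    min_final_freq: float = 0.001
    chain: str = "VH"

    @property
    def cut(self) -> float:
        return 1.0 - self.min_identity


def build_families(
    table: CountTable,
    cfg: ClusterConfig | None = None,
    clone_ids=None,
) -> tuple[list[Family], list[Dendrogram]]:
    """Translate, pool DNA variants by amino-acid loop, cluster, summarize.

    ``table`` must be the full count table so family frequencies are
    fractions of each round's total depth; ``clone_ids`` restricts the
    clustering to the cascade survivors (default: all rows).  Clones that
    do not translate cleanly are rejected — the cascade's no_stop stage
    removes them beforehand.
    """
    cfg = cfg or ClusterConfig()
    if table.sequences is None:
        raise ValueError("count table has no sequences")
    ids = list(table.counts.index) if clone_ids is None else list(clone_ids)
    if not ids:
        return [], []

    aa_of: dict[str, str] = {}
    for clone_id in ids:
        seq = table.sequences[clone_id]
        rec = translate_and_flag(seq, clone_id, cfg.chain)
        if not (rec.valid and rec.in_frame and not rec.has_stop):
            raise ValueError(f"clone {clone_id} does not translate cleanly")
        aa_of[clone_id] = rec.cdr3_aa

    members_by_aa: dict[str, list[str]] = {}
    for clone_id, aa in aa_of.items():
        members_by_aa.setdefault(aa, []).append(clone_id)
    aa_labels = sorted(members_by_aa)
    d = distance_matrix(aa_labels, {a: a for a in aa_labels})
    parts, dendro = complete_linkage_cluster(aa_labels, d, cfg.cut)

    f = table.freqs
    families = []
    for aas in parts:
        members = sorted(m for aa in aas for m in members_by_aa[aa])
        naive = float(f.loc[members, cfg.naive].sum())
        f7 = float(f.loc[members, cfg.r7].sum())
        f8 = float(f.loc[members, cfg.r8].sum()) if cfg.r8 in f.columns else 0.0
        enr = max(f7, f8) / naive if naive > 0 else float("nan")
        rep_clone = max(members, key=lambda m: (f.at[m, cfg.r7], m))
        families.append(
            Family(
                family_id="",
                members=members,
                aa_seqs=sorted(aas),
                size=len(aas),
                pooled_final_freq=f7,
                family_enrichment=enr,
                representative=aa_of[rep_clone],
            )
        )
    families.sort(key=lambda fam: (-fam.pooled_final_freq, fam.members[0]))
    for i, fam in enumerate(families, 1):
        fam.family_id = f"F{i:03d}"
    return families, dendro


def select_families(
    families: list[Family],
    min_members: int = 2,
    min_final_freq: float = 0.001,
) -> list[Family]:
    """Retain families by size (distinct loops) and pooled final frequency.

    Singleton families are discarded; kept families must reach the final
    round at the minimum pooled frequency (default 0.1%).  Output is sorted
    by pooled final frequency, descending.
    """
    kept = [
        f
        for f in families
        if f.size >= min_members and f.pooled_final_freq >= min_final_freq
    ]
    return sorted(kept, key=lambda f: (-f.pooled_final_freq, f.family_id))


def family_enrichment(family: Family) -> float:
    """Pooled fold enrichment of a family (naive -> best final round)."""
    return family.family_enrichment


def families_to_frame(families: list[Family]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "family_id": [f.family_id for f in families],
            "size": [f.size for f in families],
            "members": [",".join(f.members) for f in families],
            "aa_seqs": [",".join(f.aa_seqs) for f in families],
            "pooled_final_freq": [f.pooled_final_freq for f in families],
            "family_enrichment": [f.family_enrichment for f in families],
            "representative": [f.representative for f in families],
        }
    ).set_index("family_id")
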