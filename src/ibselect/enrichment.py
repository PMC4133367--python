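"""Nonparametric enrichment testing between early and late selection rounds.

The test is a two-class unpaired resampling rank test on counts in the
SAM-seq style: sequencing depth differences between samples are removed by
binomially thinning every sample down to the minimum column depth, a
Wilcoxon rank-sum statistic of the late-group versus early-group samples is
computed per clonotype (midranks for ties, centered so 0 means no
difference), and the statistic is averaged over a number of independent
thinning resamples.  The false discovery rate is estimated from the full
set of distinct late-group label assignments (C(6,3) = 20 for the default
3v3 design): at a cutoff, FDR = (median number of clones exceeding the
cutoff across permutations + 1/2) / (observed number exceeding it + 1),
clipped to [0, 1] -- the half-count guard keeps a zero permutation count
from certifying a zero false-positive rate.  Per-clone q-values take the
minimum FDR over all cutoffs at or below the clone's statistic, which
makes call sets nested in the threshold.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .counts import CountTable

logger = logging.getLogger(__name__)


@dataclass
class TestConfig:
    __test__ = False  # not a pytest class, despite the name

    group_early: tuple[str, ...] = ("naive", "R3a", "R3")
    group_late: tuple[str, ...] = ("R5", "R7", "R8")
    n_resamples: int = 100
    fdr_threshold: float = 0.05
    seed: int = 0
    naive_round: str = "naive"
    final_rounds: tuple[str, ...] = ("R7", "R8")

    def __post_init__(self) -> None:
        if set(self.group_early) & set(self.group_late):
            raise ValueError("early and late groups must be disjoint")
        if len(self.group_early) < 2 or len(self.group_late) < 2:
            raise ValueError("each group needs at least 2 samples")
        if not 0.0 < self.fdr_threshold < 1.0:
            raise ValueError("fdr_threshold must be in (0, 1)")
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")


def _stat_matrix(
    counts: np.ndarray,
    depths: np.ndarray,
    n_early: int,
    n_resamples: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, ...]]]:
    """Averaged centered rank-sum statistics for every late-label assignment.

    Returns (observed statistic, all-assignment statistics of shape
    (n_clones, n_assignments), assignments).  The observed statistic is the
    assignment equal to the true labels (the last n_late columns).
    """
    n, s = counts.shape
    n_late = s - n_early
    combos = list(itertools.combinations(range(s), n_late))
    identity = tuple(range(n_early, s))
    id_pos = combos.index(identity)
    center = n_late * (s + 1) / 2.0

    dmin = depths.min()
    thin = not np.all(depths == dmin)
    n_iter = n_resamples if thin else 1
    p = (dmin / depths).astype(float)

    acc = np.zeros((n, len(combos)))
    for _ in range(n_iter):
        thinned = rng.binomial(counts, p[None, :]) if thin else counts
        ranks = rankdata(thinned, axis=1, method="average")
        for j, combo in enumerate(combos):
            acc[:, j] += ranks[:, list(combo)].sum(axis=1)
    acc /= n_iter
    stats = acc - center
    return stats[:, id_pos], stats, combos


def resampled_rank_statistic(
    counts_row,
    depths,
    cfg: TestConfig,
    rng: np.random.Generator | None = None,
) -> float:
    """Statistic for a single clone (early samples first, then late).

    Symmetric by construction: swapping the groups negates it, and it is
    invariant to relabeling samples within a group.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    counts = np.asarray(counts_row, dtype=np.int64).reshape(1, -1)
    depths = np.asarray(depths, dtype=np.int64)
    if (depths <= 0).any():
        raise ValueError("depths must be positive")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    obs, _, _ = _stat_matrix(counts, depths, len(cfg.group_early), cfg.n_resamples, rng)
    return float(obs[0])


def _side_qvalues(obs: np.ndarray, perm: np.ndarray, positive: bool) -> np.ndarray:
    """q-values for one direction (statistic > 0 or < 0)."""
    s = obs if positive else -obs
    ps = perm if positive else -perm
    mask = s > 0
    q = np.ones_like(s, dtype=float)
    if not mask.any():
        return q
    cut = s[mask]
    obs_sorted = np.sort(s)
    n = len(s)
    obs_count = n - np.searchsorted(obs_sorted, cut, side="left")
    perm_counts = np.empty((ps.shape[1], len(cut)))
    for j in range(ps.shape[1]):
        col = np.sort(ps[:, j])
        perm_counts[j] = n - np.searchsorted(col, cut, side="left")
    med = np.median(perm_counts, axis=0)
    # Guarded plug-in ratio: a permutation null count of zero is never
    # evidence of a zero false-positive rate, so the numerator carries a
    # half-count and the denominator counts the cutoff clone itself
    # (Phipson-Smyth-style protection against zero permutation p-values).
    fdr = np.clip((med + 0.5) / (obs_count + 1.0), 0.0, 1.0)
    # q-value: minimum estimated FDR over all cutoffs <= this statistic.
    order = np.argsort(cut)  # ascending cutoff
    running = np.minimum.accumulate(fdr[order])
    qv = np.empty_like(fdr)
    qv[order] = running
    q[mask] = qv
    return q


def permutation_fdr(table: CountTable, cfg: TestConfig) -> pd.DataFrame:
    """Per-clone enrichment records with permutation-estimated q-values.

    Returns a DataFrame indexed by clone_id with columns statistic, qvalue,
    direction (enriched / depleted / null) and enrichment_factor
    (max over final rounds of f(c, r) divided by f(c, naive); NaN when the
    clone is absent from the naive round).
    """
    samples = list(cfg.group_early) + list(cfg.group_late)
    missing = [r for r in samples if r not in table.rounds]
    if missing:
        raise ValueError(f"rounds missing from count table: {missing}")
    counts = table.counts[samples].to_numpy(np.int64)
    depths = table.counts[samples].sum(axis=0).to_numpy(np.int64)
    if (depths <= 0).any():
        raise ValueError("every sample needs positive depth")
    rng = np.random.default_rng(cfg.seed)
    obs, perm, combos = _stat_matrix(counts, depths, len(cfg.group_early), cfg.n_resamples, rng)
    if len(combos) < 10:
        logger.warning(
            "only %d distinct label permutations; FDR estimate is coarse", len(combos)
        )

    q_up = _side_qvalues(obs, perm, positive=True)
    q_down = _side_qvalues(obs, perm, positive=False)
    qvalue = np.where(obs > 0, q_up, np.where(obs < 0, q_down, 1.0))
    direction = np.where(
        (qvalue < cfg.fdr_threshold) & (obs > 0),
        "enriched",
        np.where((qvalue < cfg.fdr_threshold) & (obs < 0), "depleted", "null"),
    )
    ef = enrichment_factors(table, cfg)
    return pd.DataFrame(
        {
            "statistic": obs,
            "qvalue": qvalue,
            "direction": direction,
            "enrichment_factor": ef.to_numpy(),
        },
        index=table.counts.index,
    )


def enrichment_factors(table: CountTable, cfg: TestConfig | None = None) -> pd.Series:
    """E(c) = max over final rounds of f(c, r) / f(c, naive), as frequencies."""
    cfg = cfg or TestConfig()
    f = table.freqs
    late = f[list(cfg.final_rounds)].max(axis=1)
    naive = f[cfg.naive_round]
    ef = late / naive
    ef[naive == 0] = np.nan
    return ef.rename("enrichment_factor")


def enrichment_factor(table: CountTable, clone_id: str, cfg: TestConfig | None = None) -> float:
    """E(c) for one clone; NaN when it is absent from the naive round."""
    return float(enrichment_factors(table, cfg).loc[clone_id])
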