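"""Ordered post-test filter cascade with a stage-by-stage trace.

Stages, applied in fixed order to the enrichment test's input table:

1. present_both — clone observed (count > 0) in both the naive and the
   final selection round;
2. fdr_enriched — called enriched by the permutation-FDR test;
3. no_stop — the loop translates cleanly: in frame (length divisible by 3)
   and without a stop codon;
4. monotonic — frequency strictly increases over the selection
   (naive < R3 < R5 < R7, on frequencies, not counts);
5. fold100 — total enrichment E(c) strictly above the fold threshold.

Survivor sets are nested by construction and the trace records each stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clones import translate_and_flag
from .counts import CountTable
from .enrichment import TestConfig, enrichment_factors

STAGES = ("present_both", "fdr_enriched", "no_stop", "monotonic", "fold100")


@dataclass
class CascadeConfig:
    naive: str = "naive"
    r3: str = "R3"
    r5: str = "R5"
    r7: str = "R7"
    r8: str = "R8"
    fold_threshold: float = 100.0
    chain: str = "VH"

    @property
    def monotonic_rounds(self) -> tuple[str, ...]:
        return (self.naive, self.r3, self.r5, self.r7)

    @property
    def final_rounds(self) -> tuple[str, ...]:
        return (self.r7, self.r8)


@dataclass
class FilterTrace:
    """Per-stage survivor sets; counts are non-increasing along the cascade."""

    stages: tuple[str, ...]
    survivors: dict[str, list[str]] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        return {s: len(self.survivors[s]) for s in self.stages}

    def final_survivors(self) -> list[str]:
        return list(self.survivors[self.stages[-1]])

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"stages": list(self.stages), "counts": self.counts, "survivors": self.survivors},
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload


def filter_present_both(table: CountTable, cfg: CascadeConfig | None = None) -> set[str]:
    """Clones with count > 0 in both the naive and final (R7) rounds."""
    cfg = cfg or CascadeConfig()
    c = table.counts
    mask = (c[cfg.naive] > 0) & (c[cfg.r7] > 0)
    return set(c.index[mask])


def filter_monotonic(table: CountTable, clone_id: str, cfg: CascadeConfig | None = None) -> bool:
    """Strictly increasing frequency trajectory naive < R3 < R5 < R7."""
    cfg = cfg or CascadeConfig()
    f = [table.freq(clone_id, r) for r in cfg.monotonic_rounds]
    return all(a < b for a, b in zip(f, f[1:]))


def filter_fold(
    table: CountTable, clone_id: str, threshold: float = 100.0, cfg: CascadeConfig | None = None
) -> bool:
    """Total enrichment strictly above threshold (exactly 100x fails)."""
    cfg = cfg or CascadeConfig()
    tcfg = TestConfig(naive_round=cfg.naive, final_rounds=cfg.final_rounds)
    e = enrichment_factors(table, tcfg).loc[clone_id]
    return bool(e > threshold)


def _monotonic_mask(table: CountTable, cfg: CascadeConfig) -> pd.Series:
    f = table.freqs[list(cfg.monotonic_rounds)].to_numpy()
    ok = np.all(f[:, 1:] > f[:, :-1], axis=1)
    return pd.Series(ok, index=table.counts.index)


def run_cascade(
    table: CountTable,
    records: pd.DataFrame,
    cfg: CascadeConfig | None = None,
) -> FilterTrace:
    """Apply all five stages in order and return the trace.

    ``records`` is the enrichment-test output (must cover the same clones);
    the no_stop stage translates the table's sequences, so the table must
    carry them.
    """
    cfg = cfg or CascadeConfig()
    trace = FilterTrace(STAGES)

    surv = filter_present_both(table, cfg)
    trace.survivors["present_both"] = sorted(surv)

    enriched = set(records.index[records["direction"] == "enriched"])
    surv = surv & enriched
    trace.survivors["fdr_enriched"] = sorted(surv)

    if table.sequences is None:
        raise ValueError("count table has no sequences; cannot apply no_stop")
    ok = set()
    for clone_id in surv:
        rec = translate_and_flag(table.sequences[clone_id], clone_id, cfg.chain)
        if rec.valid and rec.in_frame and not rec.has_stop:
            ok.add(clone_id)
    surv = ok
    trace.survivors["no_stop"] = sorted(surv)

    mono = _monotonic_mask(table, cfg)
    surv = {c for c in surv if mono[c]}
    trace.survivors["monotonic"] = sorted(surv)

    tcfg = TestConfig(naive_round=cfg.naive, final_rounds=cfg.final_rounds)
    ef = enrichment_factors(table, tcfg)
    surv = {c for c in surv if ef[c] > cfg.fold_threshold}
    trace.survivors["fold100"] = sorted(surv)

    counts = [len(trace.survivors[s]) for s in STAGES]
    assert all(a >= b for a, b in zip(counts, counts[1:])), "survivor sets must be nested"
    return trace
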