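"""Demultiplex indexed amplicon reads and count CDR3 clonotypes.

Sorting rules: the first 2 bases of a read must exactly match a known round
index (no mismatch allowed); the following bases must match one of the
framework primer tails (VH-FR3, 20 nt, or VL-FR4, 18 nt) with at most one
Hamming mismatch, which also identifies the chain.  The variable region
starts immediately after the primer tail.  The clonotype counting key is
the full CDR3 loop up to the downstream framework anchor motif when the
anchor is present, otherwise the first 25 bases of the variable region;
a pure 25-base prefix mode is available as a config switch.  Reads from
the VL end are reverse-complemented to coding sense before key extraction.

Coordinates are 0-based half-open internally; N bases count as mismatches
everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam

from .clones import ANCHORS, PRIMER_TAILS, CloneRecord, revcomp, translate_and_flag
from .counts import CountTable

MIN_KEY_LEN = 25


@dataclass(frozen=True)
class ReadRecord:
    id: str
    sequence: str
    quality: str | None = None


@dataclass(frozen=True)
class DemuxResult:
    assigned: bool
    round_label: str | None = None
    chain: str | None = None
    region_start: int = -1
    reason: str | None = None


def _mismatches_leq(seq: str, start: int, pattern: str, k: int) -> bool:
    """True if seq[start:start+len(pattern)] matches pattern with <= k mismatches."""
    end = start + len(pattern)
    if end > len(seq):
        return False
    m = 0
    for a, b in zip(seq[start:end], pattern):
        if a != b:
            m += 1
            if m > k:
                return False
    return True


def demultiplex(
    read: ReadRecord,
    index_map: dict[str, str],
    primer_tails: dict[str, str] = PRIMER_TAILS,
    max_primer_mismatch: int = 1,
) -> DemuxResult:
    """Assign a read to (round, chain), or return why it was unassigned."""
    seq = read.sequence.upper()
    if len(seq) < 2:
        return DemuxResult(False, reason="too_short")
    round_label = index_map.get(seq[:2])
    if round_label is None:
        return DemuxResult(False, reason="no_index")
    hits = [
        chain
        for chain, tail in primer_tails.items()
        if _mismatches_leq(seq, 2, tail, max_primer_mismatch)
    ]
    if not hits:
        return DemuxResult(False, reason="no_primer")
    if len(hits) > 1:
        return DemuxResult(False, reason="ambiguous")
    chain = hits[0]
    return DemuxResult(True, round_label, chain, 2 + len(primer_tails[chain]))


def extract_cdr3(
    read: ReadRecord,
    chain: str,
    region_start: int,
    mode: str = "full_loop",
    anchors: dict[str, str] = ANCHORS,
) -> str | None:
    """Extract the clonotype counting key from an assigned read.

    Returns None when the read must be dropped (variable region shorter
    than 25 bases with no usable anchor).
    """
    if mode not in ("full_loop", "prefix25"):
        raise ValueError(f"unknown extraction mode {mode!r}")
    region = read.sequence.upper()[region_start:]
    if chain == "VH":
        if mode == "full_loop":
            i = region.find(anchors["VH"])
            if i > 0:
                return region[:i]
        if len(region) >= MIN_KEY_LEN:
            return region[:MIN_KEY_LEN]
        return None
    # VL: orient to coding sense; the loop ends the coding fragment and is
    # delimited upstream by the FR3 Y-C anchor.
    rc = revcomp(region)
    if mode == "full_loop":
        i = rc.rfind(anchors["VL"])
        if i >= 0 and i + len(anchors["VL"]) < len(rc):
            return rc[i + len(anchors["VL"]):]
    if len(region) >= MIN_KEY_LEN:
        return revcomp(region[:MIN_KEY_LEN])
    return None


@dataclass
class QCStats:
    """Partition of the input reads: assigned + unassigned + dropped = total."""

    total: int = 0
    assigned: dict = field(default_factory=dict)  # (round, chain) -> count
    unassigned: dict = field(default_factory=dict)  # reason -> count
    dropped: int = 0

    @property
    def n_assigned(self) -> int:
        return sum(self.assigned.values())

    @property
    def n_unassigned(self) -> int:
        return sum(self.unassigned.values())

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "assigned": {f"{r}/{c}": n for (r, c), n in sorted(self.assigned.items())},
            "unassigned": dict(sorted(self.unassigned.items())),
            "dropped": self.dropped,
        }


def read_fastx(path) -> "iter[ReadRecord]":
    """Stream FASTQ/FASTA records (plain or gzip) via pysam."""
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield ReadRecord(entry.name, entry.sequence, entry.quality)


def build_count_table(assigned, rounds) -> CountTable:
    """Exact multiset counts per (clonotype key, round).

    ``assigned`` yields (round_label, key) pairs.  Rows are ordered
    lexicographically by sequence; clone_ids are the keys themselves.
    """
    tallies: dict[str, dict[str, int]] = {}
    for round_label, key in assigned:
        row = tallies.setdefault(key, {})
        row[round_label] = row.get(round_label, 0) + 1
    keys = sorted(tallies)
    df = pd.DataFrame(
        [[tallies[k].get(r, 0) for r in rounds] for k in keys],
        index=pd.Index(keys, name="clone_id"),
        columns=list(rounds),
        dtype="int64",
    )
    return CountTable(df, pd.Series(keys, index=df.index, name="sequence"))


def demux_and_count(
    reads,
    index_map: dict[str, str],
    mode: str = "full_loop",
    chains: tuple[str, ...] = ("VH", "VL"),
    max_primer_mismatch: int = 1,
) -> tuple[dict[str, CountTable], QCStats]:
    """Full sorting pipeline: demultiplex, extract keys, count per chain.

    ``reads`` is an iterable of ReadRecord or a FASTQ/FASTA path.  Returns
    one CountTable per chain plus QC tallies.  The result is independent
    of read order.
    """
    if isinstance(reads, (str, Path)):
        reads = read_fastx(reads)
    rounds = list(dict.fromkeys(index_map.values()))
    qc = QCStats()
    per_chain: dict[str, list[tuple[str, str]]] = {c: [] for c in chains}
    for read in reads:
        qc.total += 1
        res = demultiplex(read, index_map, max_primer_mismatch=max_primer_mismatch)
        if not res.assigned:
            qc.unassigned[res.reason] = qc.unassigned.get(res.reason, 0) + 1
            continue
        if res.chain not in per_chain:
            qc.unassigned["chain_off"] = qc.unassigned.get("chain_off", 0) + 1
            continue
        key = extract_cdr3(read, res.chain, res.region_start, mode=mode)
        if key is None:
            qc.dropped += 1
            continue
        bucket = (res.round_label, res.chain)
        qc.assigned[bucket] = qc.assigned.get(bucket, 0) + 1
        per_chain[res.chain].append((res.round_label, key))
    tables = {c: build_count_table(pairs, rounds) for c, pairs in per_chain.items()}
    return tables, qc


def flag_clones(table: CountTable, chain: str = "VH") -> list[CloneRecord]:
    """Translate every clonotype key in a table and set stop/frame flags."""
    if table.sequences is None:
        raise ValueError("count table has no sequences")
    return [
        translate_and_flag(seq, clone_id, chain)
        for clone_id, seq in table.sequences.items()
    ]


def read_samplesheet(path) -> dict[str, str]:
    """Sample sheet TSV with columns round, index -> index_map (index -> round)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"round", "index"} <= set(df.columns):
        raise ValueError("sample sheet needs 'round' and 'index' columns")
    return {row["index"].upper(): row["round"] for _, row in df.iterrows()}
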