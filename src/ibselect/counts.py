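"""Clone-by-round count tables with per-round depths and frequencies."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CountTable:
    """Integer read counts for each clonotype (rows) in each round (columns).

    ``counts`` is indexed by clone_id; ``sequences`` maps clone_id to the
    CDR3 DNA key used for counting (may be None for externally supplied
    tables).  Frequencies are f(c, r) = count(c, r) / depth(r) where the
    depth is the column sum.
    """

    counts: pd.DataFrame
    sequences: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            raise ValueError("duplicate clone_ids in count table")
        arr = self.counts.to_numpy()
        if arr.size and (not np.issubdtype(arr.dtype, np.number) or (arr < 0).any()):
            raise ValueError("counts must be non-negative numbers")
        self.counts = self.counts.astype(np.int64)
        if self.sequences is not None:
            self.sequences = self.sequences.reindex(self.counts.index)

    # ------------------------------------------------------------------
    @property
    def rounds(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def clone_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def depths(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def freqs(self) -> pd.DataFrame:
        d = self.depths.astype(float)
        d[d == 0] = np.nan
        return self.counts / d

    def freq(self, clone_id: str, round_label: str) -> float:
        depth = int(self.counts[round_label].sum())
        if depth == 0:
            return float("nan")
        return float(self.counts.at[clone_id, round_label]) / depth

    # ------------------------------------------------------------------
    def subset(self, clone_ids) -> "CountTable":
        ids = [c for c in self.counts.index if c in set(clone_ids)]
        seqs = self.sequences.loc[ids] if self.sequences is not None else None
        return CountTable(self.counts.loc[ids].copy(), seqs)

    def sorted_by_sequence(self) -> "CountTable":
        """Deterministic row order: lexicographic by counting key."""
        if self.sequences is None:
            order = sorted(self.counts.index)
        else:
            order = sorted(self.counts.index, key=lambda c: (self.sequences[c], c))
        seqs = self.sequences.loc[order] if self.sequences is not None else None
        return CountTable(self.counts.loc[order], seqs)

    def equals(self, other: "CountTable") -> bool:
        """Exact equality of counts keyed by sequence (row order ignored).

        Rows that are zero in every round are ignored: a clone that drew no
        reads is unobservable from the read stream.
        """
        a = self._by_sequence()
        b = other._by_sequence()
        a = a[a.sum(axis=1) > 0]
        b = b[b.sum(axis=1) > 0]
        return a.shape == b.shape and list(a.columns) == list(b.columns) and a.equals(b)

    def _by_sequence(self) -> pd.DataFrame:
        df = self.counts.copy()
        if self.sequences is not None:
            df.index = self.sequences.values
        return df.sort_index()

    # ------------------------------------------------------------------
    def to_tsv(self, path) -> None:
        df = self.counts.copy()
        df.insert(0, "sequence", self.sequences if self.sequences is not None else "")
        df.to_csv(path, sep="\t", index_label="clone_id")

    @classmethod
    def from_tsv(cls, path) -> "CountTable":
        df = pd.read_csv(path, sep="\t", index_col="clone_id")
        seqs = None
        if "sequence" in df.columns:
            seqs = df.pop("sequence").astype(str)
        return cls(df, seqs)
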