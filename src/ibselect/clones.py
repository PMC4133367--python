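"""CDR3 clonotype records, translation flags, and the fixed amplicon landmarks.

The sequencing design reads a 100-base single-end amplicon from either end of
the scFv cassette: a 2-base round index, the 3' tail of the framework primer
(VH-FR3 forward or VL-FR4 reverse), and then the hypervariable CDR3 loop.
The constants below are the primer tails (index stripped) and the framework
anchor motifs that delimit the loop on the coding strand.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

# Primer 3' tails as sequenced, immediately after the 2-base index.
# The VH primer sits at the 3' end of heavy-chain FR3 (20 nt); the VL primer
# sits at the 5' end of light-chain FR4 (18 nt) and reads the antisense strand.
VH_PRIMER_TAIL = "CTGTTTATTACTGTGTGAGA"
VL_PRIMER_TAIL = "CTTGGTCCCTCCGCCGAA"
PRIMER_TAILS = {"VH": VH_PRIMER_TAIL, "VL": VL_PRIMER_TAIL}

# Coding-strand framework anchors delimiting the loop.
# VH: FR4 starts with the invariant Trp-Gly (W-G) codon pair.
# VL: FR3 ends with the Tyr-Cys (Y-C) codon pair just upstream of L3.
VH_ANCHOR = "TGGGGC"
VL_ANCHOR = "TACTGT"
ANCHORS = {"VH": VH_ANCHOR, "VL": VL_ANCHOR}

# Constant framework filler used by the simulator: heavy-chain FR4 plus the
# start of the inter-domain linker, beginning with the W-G anchor.  Must
# contain the anchor motif only at position 0.
VH_DOWNSTREAM_FR = (
    "TGGGGCCAAGGGACCACGGTCACCGTCTCCTCAGGTGGAGGCGGTTCAGGCGGAGGTGGCTCTGGCGGTGGCGGATCGCAGGCT"
)

# Constant light-chain FR3 3' region on the coding strand, ending with the
# Y-C anchor.  Must contain the anchor motif only as its suffix.
VL_UPSTREAM_FR = (
    "GGAGGCTCCGGCACCGACTTCACCCTGACCATCAGCAGACTGGAACCCGAAGATTTCGCCGTGTATTACTGT"
)

READ_LENGTH = 100

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CloneRecord:
    """One CDR3 clonotype.

    ``cdr3_aa`` is the frame-0 translation of the loop (including ``*`` for
    stop codons) and is None when the loop length is not a multiple of 3,
    i.e. the clone carries a frameshift.
    """

    clone_id: str
    chain: str  # "VH" | "VL"
    cdr3_dna: str
    cdr3_aa: str | None
    has_stop: bool
    in_frame: bool
    valid: bool = True


def translate_and_flag(cdr3_dna: str, clone_id: str | None = None, chain: str = "VH") -> CloneRecord:
    """Translate a CDR3 loop in frame 0 and set stop/frameshift flags.

    Translation uses the standard genetic code over the complete codons of
    the loop; ``has_stop`` is true when any of those codons is a stop.  A
    clone whose sequence contains characters outside {A,C,G,T} is flagged
    invalid and must be excluded from downstream analysis.
    """
    if not cdr3_dna:
        raise ValueError("empty CDR3 sequence")
    seq = cdr3_dna.upper()
    cid = clone_id if clone_id is not None else seq
    if any(b not in "ACGT" for b in seq):
        return CloneRecord(cid, chain, seq, None, False, False, valid=False)
    in_frame = len(seq) % 3 == 0
    n_codons = len(seq) // 3
    aa = str(Seq(seq[: 3 * n_codons]).translate()) if n_codons else ""
    has_stop = "*" in aa
    cdr3_aa = aa if in_frame else None
    return CloneRecord(cid, chain, seq, cdr3_aa, has_stop, in_frame, valid=True)
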