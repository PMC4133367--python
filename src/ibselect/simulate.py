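"""Synthetic multi-round FACS selection experiments for an scFv/VH library.

The generator emulates the statistical structure the downstream analysis
assumes: a naive library of distinct CDR3 DNA clonotypes with heavy-tailed
(symmetric Dirichlet) abundances, a stated fraction of stop-codon and
frameshift clones, per-clone multiplicative selection coefficients applied
over discrete selection rounds, multinomial read sampling at a configured
depth per round, and 100-base single-end indexed amplicon reads with
per-base substitution errors.  Ground-truth labels (which clones were truly
enriched, and by how much) are returned alongside so that every downstream
stage can be scored against the truth.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from Bio.Data import CodonTable

from .clones import (
    ANCHORS,
    PRIMER_TAILS,
    READ_LENGTH,
    VH_DOWNSTREAM_FR,
    VL_UPSTREAM_FR,
    CloneRecord,
    revcomp,
    translate_and_flag,
)
from .counts import CountTable

DEFAULT_ROUNDS = ("naive", "R3", "R5", "R7", "R8")
_INDEX_CODES = ("AA", "CC", "GG", "TT", "AC", "AG", "AT", "CA", "CG", "CT", "GA", "GC")

_STANDARD = CodonTable.unambiguous_dna_by_name["Standard"]
_CODONS_BY_AA: dict[str, tuple[str, ...]] = {}
for codon, aa in _STANDARD.forward_table.items():
    _CODONS_BY_AA.setdefault(aa, [])
    _CODONS_BY_AA[aa].append(codon)
_CODONS_BY_AA = {aa: tuple(sorted(cs)) for aa, cs in _CODONS_BY_AA.items()}
_STOP_CODONS = tuple(sorted(_STANDARD.stop_codons))
_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def default_index_map(rounds=DEFAULT_ROUNDS) -> dict[str, str]:
    """2-base index -> round label, assigned from a fixed code list."""
    if len(rounds) > len(_INDEX_CODES):
        raise ValueError("not enough built-in index codes; supply index_map")
    return {code: r for code, r in zip(_INDEX_CODES, rounds)}


@dataclass
class SimConfig:
    """Design of one simulated selection experiment.

    Defaults follow the experimental design being emulated: rounds naive,
    R3, R5, R7, R8 (one selection generation per successive round), 80% of
    naive clones in frame without stop codon, 1e6 reads per round with
    severalfold per-round yield variation, and spiked (truly enriched)
    clones with 100-500x total realized fold enrichment placed at naive
    frequencies where the naive sequencing sees them at 5-20 reads.
    """

    n_clones: int = 5000
    abundance_alpha: float = 2.0
    frac_stop: float = 0.1
    frac_frameshift: float = 0.1
    n_spiked: int = 10
    n_spike_clusters: int | None = None  # None: every spike is its own cluster
    spike_fold_range: tuple[float, float] = (100.0, 500.0)
    # None: spikes are placed at naive frequencies giving 5-20 expected
    # naive-round reads at the nominal depth, i.e. (5/depth, 20/depth) --
    # rare enough to sit far below the abundant clones, common enough to be
    # observable in the naive sequencing.
    spike_naive_freq_range: tuple[float, float] | None = None
    rounds: tuple[str, ...] = DEFAULT_ROUNDS
    round_generations: tuple[int, ...] | None = None  # None: 0,1,2,...
    depth_per_round: int | tuple[int, ...] = 1_000_000
    depth_jitter: float = 0.5  # lognormal sigma of per-round sequencing yield
    error_rate: float = 0.001
    cdr3_len_range: tuple[int, int] = (8, 16)  # amino acids
    index_map: dict[str, str] | None = None
    chains: tuple[str, ...] = ("VH",)
    seed: int = 0
    max_retries: int = 100

    def __post_init__(self) -> None:
        for name in ("frac_stop", "frac_frameshift"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.frac_stop + self.frac_frameshift > 1.0:
            raise ValueError("frac_stop + frac_frameshift exceeds 1")
        if self.n_clones <= 0:
            raise ValueError("n_clones must be positive")
        if self.n_spiked < 0 or self.n_spiked > self.n_clones:
            raise ValueError("n_spiked must be in [0, n_clones]")
        if self.spike_fold_range[0] <= 1.0 or self.spike_fold_range[1] < self.spike_fold_range[0]:
            raise ValueError("spike_fold_range must satisfy 1 < min <= max")
        if min(self.depths) <= 0:
            raise ValueError("depths must be positive")
        if self.round_generations is not None and len(self.round_generations) != len(self.rounds):
            raise ValueError("round_generations must match rounds")
        if self.cdr3_len_range[0] < 4 or self.cdr3_len_range[1] < self.cdr3_len_range[0]:
            raise ValueError("invalid cdr3_len_range")
        if self.index_map is None:
            self.index_map = default_index_map(self.rounds)
        for code in self.index_map:
            if len(code) != 2 or any(b not in "ACGT" for b in code):
                raise ValueError(f"index {code!r} is not 2 bases over ACGT")
        missing = set(self.rounds) - set(self.index_map.values())
        if missing:
            raise ValueError(f"rounds without an index: {sorted(missing)}")
        for chain in self.chains:
            if chain not in ("VH", "VL"):
                raise ValueError(f"unknown chain {chain!r}")

    @property
    def generations(self) -> tuple[int, ...]:
        if self.round_generations is not None:
            return tuple(self.round_generations)
        return tuple(range(len(self.rounds)))

    @property
    def depths(self) -> tuple[int, ...]:
        if isinstance(self.depth_per_round, (int, np.integer)):
            return tuple(int(self.depth_per_round) for _ in self.rounds)
        return tuple(int(d) for d in self.depth_per_round)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimConfig":
        kwargs = dict(raw)
        for key in ("spike_fold_range", "spike_naive_freq_range", "rounds",
                    "round_generations", "cdr3_len_range", "chains", "depth_per_round"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


# ----------------------------------------------------------------------
# Library generation
# ----------------------------------------------------------------------

def _random_inframe(rng: np.random.Generator, length_aa: int) -> tuple[str, str]:
    aa = "".join(_AA20[i] for i in rng.integers(0, len(_AA20), size=length_aa))
    return _reverse_translate(rng, aa), aa


def _reverse_translate(rng: np.random.Generator, aa: str) -> str:
    u = rng.random(len(aa))
    return "".join(
        _CODONS_BY_AA[a][int(x * len(_CODONS_BY_AA[a]))] for a, x in zip(aa, u)
    )


def _contains_anchor(dna: str) -> bool:
    return any(anchor in dna for anchor in ANCHORS.values())


def _mutate_aa(rng: np.random.Generator, aa: str, n_sub: int) -> str:
    pos = rng.choice(len(aa), size=n_sub, replace=False)
    out = list(aa)
    for p in pos:
        out[p] = _AA20[rng.integers(20)]
        while out[p] == aa[p]:
            out[p] = _AA20[rng.integers(20)]
    return "".join(out)


def draw_library(cfg: SimConfig) -> tuple[list[CloneRecord], pd.DataFrame]:
    """Draw the naive library and its ground truth.

    Returns ``(clones, truth)`` where truth is a DataFrame indexed by
    clone_id with columns sequence, naive_freq, selection_coefficient,
    is_spiked, spike_cluster and true_total_fold (the expected naive->final
    frequency ratio after renormalization across the whole library).

    Spiked clones are always in frame without stop codons and are generated
    as mutational clusters: members of a cluster share loop length and
    differ by at most ~20% of positions from the cluster seed, so the
    clustering stage can recover each cluster as one family.
    """
    rng = _rng(cfg.seed, 0)
    n = cfg.n_clones
    n_stop = int(round(cfg.frac_stop * n))
    n_fs = int(round(cfg.frac_frameshift * n))
    n_good = n - n_stop - n_fs
    if cfg.n_spiked > n_good:
        raise ValueError("n_spiked exceeds the number of in-frame stop-free clones")

    seen: set[str] = set()

    def _unique(make) -> str:
        for _ in range(cfg.max_retries):
            dna = make()
            if not _contains_anchor(dna) and dna not in seen:
                seen.add(dna)
                return dna
        raise RuntimeError(
            f"could not generate a distinct CDR3 after {cfg.max_retries} retries; "
            "the configured library is too dense for the sequence space"
        )

    lo, hi = cfg.cdr3_len_range
    sequences: list[str] = []
    spiked_flags: list[bool] = []
    cluster_ids: list[int] = []

    # Spike clusters first.
    n_clusters = cfg.n_spike_clusters if cfg.n_spike_clusters is not None else cfg.n_spiked
    if cfg.n_spiked and (n_clusters <= 0 or n_clusters > cfg.n_spiked):
        raise ValueError("n_spike_clusters must be in [1, n_spiked]")
    sizes = []
    if cfg.n_spiked:
        base, rem = divmod(cfg.n_spiked, n_clusters)
        sizes = [base + (1 if i < rem else 0) for i in range(n_clusters)]
    seeds_by_len: dict[int, list[str]] = {}
    for ci, size in enumerate(sizes):
        for _ in range(cfg.max_retries):
            length = int(rng.integers(lo, hi + 1))
            dna, aa = _random_inframe(rng, length)
            # Keep cluster seeds well separated from same-length seeds.
            others = seeds_by_len.get(length, [])
            if any(sum(x != y for x, y in zip(aa, o)) <= 0.6 * length for o in others):
                continue
            if not _contains_anchor(dna) and dna not in seen:
                break
        else:
            raise RuntimeError("could not place a distinct spike cluster seed")
        seen.add(dna)
        seeds_by_len.setdefault(length, []).append(aa)
        member_aas = {aa}
        sequences.append(dna)
        spiked_flags.append(True)
        cluster_ids.append(ci)
        max_sub = max(1, int(0.2 * length))
        for _ in range(size - 1):
            def make_variant() -> str:
                var = _mutate_aa(rng, aa, int(rng.integers(1, max_sub + 1)))
                return _reverse_translate(rng, var)

            for _ in range(cfg.max_retries):
                var_dna = make_variant()
                var_aa = translate_and_flag(var_dna).cdr3_aa
                if var_aa in member_aas or _contains_anchor(var_dna) or var_dna in seen:
                    continue
                seen.add(var_dna)
                member_aas.add(var_aa)
                sequences.append(var_dna)
                spiked_flags.append(True)
                cluster_ids.append(ci)
                break
            else:
                raise RuntimeError("could not generate a distinct spike variant")

    # Remaining in-frame stop-free clones.
    for _ in range(n_good - cfg.n_spiked):
        sequences.append(_unique(lambda: _random_inframe(rng, int(rng.integers(lo, hi + 1)))[0]))
        spiked_flags.append(False)
        cluster_ids.append(-1)

    # Stop-codon clones: in-frame with >=1 stop codon at a random position.
    for _ in range(n_stop):
        def make_stop() -> str:
            length = int(rng.integers(lo, hi + 1))
            dna, _ = _random_inframe(rng, length)
            k = int(rng.integers(length))
            stop = _STOP_CODONS[rng.integers(len(_STOP_CODONS))]
            return dna[: 3 * k] + stop + dna[3 * (k + 1):]

        sequences.append(_unique(make_stop))
        spiked_flags.append(False)
        cluster_ids.append(-1)

    # Frameshift clones: in-frame body plus 1-2 trailing bases, so the
    # length is not a multiple of 3 (and full codons stay stop-free).
    for _ in range(n_fs):
        def make_fs() -> str:
            length = int(rng.integers(lo, hi + 1))
            dna, _ = _random_inframe(rng, length)
            extra = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 3))))
            return dna + extra

        sequences.append(_unique(make_fs))
        spiked_flags.append(False)
        cluster_ids.append(-1)

    clone_ids = [f"c{i:06d}" for i in range(len(sequences))]
    chain = cfg.chains[0]
    clones = [translate_and_flag(s, cid, chain) for cid, s in zip(clone_ids, sequences)]

    # Abundances: symmetric Dirichlet over all clones, spiked frequencies
    # overwritten with log-uniform draws in the configured naive window.
    gamma = rng.gamma(cfg.abundance_alpha, size=len(sequences))
    freqs = gamma / gamma.sum()
    spiked = np.asarray(spiked_flags)
    if spiked.any():
        if cfg.spike_naive_freq_range is None:
            d_nom = min(cfg.depths)
            f_lo, f_hi = 5.0 / d_nom, 20.0 / d_nom
        else:
            f_lo, f_hi = cfg.spike_naive_freq_range
        fs = np.exp(rng.uniform(np.log(f_lo), np.log(f_hi), size=int(spiked.sum())))
        if fs.sum() >= 0.5:
            raise ValueError("spiked clones would dominate the naive library")
        freqs[spiked] = fs
        freqs[~spiked] *= (1.0 - fs.sum()) / freqs[~spiked].sum()

    gens = cfg.generations
    n_gen = max(gens)
    if n_gen == 0 and cfg.n_spiked:
        raise ValueError("spiked clones require at least one selection generation")
    n_gen = max(n_gen, 1)
    folds = np.ones(len(sequences))
    w = np.ones(len(sequences))
    if spiked.any():
        lo_f, hi_f = cfg.spike_fold_range
        folds[spiked] = np.exp(rng.uniform(np.log(lo_f), np.log(hi_f), size=int(spiked.sum())))
        # Fitness is calibrated so the *realized* naive->final frequency
        # ratio equals the drawn fold: growth of the spiked clones deflates
        # every frequency by the mean fitness Z, so w must absorb it.
        # Z = sum_c f_c w_c^G with w^G = fold * Z for spiked clones gives
        # Z = null_mass / (1 - sum_spiked f_c * fold_c) in closed form.
        spike_mass_final = float((freqs[spiked] * folds[spiked]).sum())
        if spike_mass_final >= 1.0:
            raise ValueError("spiked clones would take over the library entirely")
        z = float(freqs[~spiked].sum()) / (1.0 - spike_mass_final)
        w[spiked] = (folds[spiked] * z) ** (1.0 / n_gen)

    f_final = freqs * w**n_gen
    f_final = f_final / f_final.sum()
    truth = pd.DataFrame(
        {
            "sequence": sequences,
            "naive_freq": freqs,
            "selection_coefficient": w,
            "is_spiked": spiked,
            "spike_cluster": cluster_ids,
            "true_total_fold": f_final / freqs,
        },
        index=pd.Index(clone_ids, name="clone_id"),
    )
    return clones, truth


# ----------------------------------------------------------------------
# Selection dynamics
# ----------------------------------------------------------------------

def evolve_rounds(
    library: list[CloneRecord],
    truth: pd.DataFrame,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> CountTable:
    """Apply discrete-generation selection and multinomial read sampling.

    Each generation multiplies every clone's frequency by its selection
    coefficient and renormalizes; each round draws ``depth`` reads from the
    frequency vector of its generation.  Rounds that share a generation
    index (e.g. the same pool sequenced before and after a recloning step)
    get independent multinomial draws from the same frequencies.

    Per-round sequencing yield varies in practice; the realized depth of a
    round is its nominal depth scaled by a lognormal factor with sigma
    ``depth_jitter`` (set 0 for exactly-nominal depths).
    """
    if rng is None:
        rng = _rng(cfg.seed, 1)
    f0 = truth["naive_freq"].to_numpy(float)
    if abs(f0.sum() - 1.0) > 1e-9:
        raise ValueError("naive frequencies are not normalized")
    w = truth["selection_coefficient"].to_numpy(float)
    depths = list(cfg.depths)
    if cfg.depth_jitter > 0:
        factors = rng.lognormal(0.0, cfg.depth_jitter, size=len(depths))
        depths = [max(1, int(round(d * f))) for d, f in zip(depths, factors)]
    cols = {}
    for round_label, gen, depth in zip(cfg.rounds, cfg.generations, depths):
        f = f0 * w**gen
        f = f / f.sum()
        cols[round_label] = rng.multinomial(depth, f)
    counts = pd.DataFrame(cols, index=truth.index)
    return CountTable(counts, truth["sequence"].copy())


# ----------------------------------------------------------------------
# Read synthesis
# ----------------------------------------------------------------------

def _template(chain: str, index_code: str, cdr3: str, clone_id: str) -> str:
    """Error-free 100-base read for one clone/round/chain."""
    if chain == "VH":
        prefix = index_code + PRIMER_TAILS["VH"] + cdr3
        if len(prefix) + len(ANCHORS["VH"]) > READ_LENGTH:
            raise ValueError(
                f"CDR3 of clone {clone_id} ({len(cdr3)} nt) too long for a "
                f"{READ_LENGTH}-base read"
            )
        read = prefix + VH_DOWNSTREAM_FR
        return read[:READ_LENGTH]
    # VL: the primer reads the antisense strand, so the loop appears
    # reverse-complemented; coding sense is upstream-FR3 + loop.
    room = READ_LENGTH - 2 - len(PRIMER_TAILS["VL"])
    if len(cdr3) + len(ANCHORS["VL"]) > room:
        raise ValueError(
            f"CDR3 of clone {clone_id} ({len(cdr3)} nt) too long for a "
            f"{READ_LENGTH}-base read"
        )
    pad = room - len(cdr3)
    coding = VL_UPSTREAM_FR[-pad:] + cdr3
    return index_code + PRIMER_TAILS["VL"] + revcomp(coding)


def synthesize_reads(table: CountTable, library: list[CloneRecord], cfg: SimConfig, path) -> int:
    """Write the FASTQ implied by a count table; returns reads written.

    Reads are 100 bases: 2-base round index, framework primer tail, the
    CDR3 loop, then constant framework filler (VL reads antisense).  Each
    base is substituted independently with probability ``error_rate``.
    Quality strings are constant Q30 (never used downstream).
    """
    rng = _rng(cfg.seed, 2)
    index_of = {r: code for code, r in cfg.index_map.items()}
    seqs = {c.clone_id: c.cdr3_dna for c in library}
    qual = "?" * READ_LENGTH  # Phred+33 Q30
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    n_written = 0
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for round_label in table.rounds:
            code = index_of[round_label]
            col = table.counts[round_label]
            for chain in cfg.chains:
                for clone_id, count in col.items():
                    if count == 0:
                        continue
                    tmpl = _template(chain, code, seqs[clone_id], clone_id)
                    arr = np.frombuffer(tmpl.encode(), dtype=np.uint8)
                    if cfg.error_rate > 0:
                        n_err = rng.binomial(READ_LENGTH, cfg.error_rate, size=count)
                    else:
                        n_err = np.zeros(count, dtype=int)
                    for i in range(count):
                        if n_err[i]:
                            mut = arr.copy()
                            pos = rng.choice(READ_LENGTH, size=n_err[i], replace=False)
                            for p in pos:
                                b = bases[rng.integers(4)]
                                while b == mut[p]:
                                    b = bases[rng.integers(4)]
                                mut[p] = b
                            seq = mut.tobytes().decode()
                        else:
                            seq = tmpl
                        fh.write(f"@{clone_id}|{round_label}|{chain}|{i}\n{seq}\n+\n{qual}\n")
                        n_written += 1
    return n_written


@dataclass
class SimResult:
    clones: list[CloneRecord]
    truth: pd.DataFrame
    table: CountTable
    config: SimConfig


def simulate_experiment(cfg: SimConfig) -> SimResult:
    """Library draw + selection dynamics in one call (no read synthesis)."""
    clones, truth = draw_library(cfg)
    table = evolve_rounds(clones, truth, cfg)
    return SimResult(clones, truth, table, cfg)
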