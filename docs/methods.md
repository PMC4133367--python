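# Methods

`ibselect` analyses multi-round phenotypic selections of an intracellular
antibody (intrabody) library read out by amplicon sequencing of CDR3
loops.  This note describes the models and procedures the package
implements, the choices that were genuinely open, and what the synthetic
data generator does and does not emulate.

## The experimental design being emulated

A single-chain antibody fragment (scFv) library is expressed inside
mast-cell-line cells; cells whose intrabody blocks IgE-receptor-triggered
degranulation are enriched by repeated FACS sorting.  After selected
rounds, the hypervariable VH CDR3 loops are PCR-amplified with primers
ending in the conserved framework regions, tagged with a 2-base round
index, and sequenced as 100-base single-end reads.  Analysis asks: which
CDR3 clonotypes rose over the rounds by more than sampling noise, and do
the survivors group into mutationally related antibody families?

Read layout, as synthesized and as parsed:

    [2-base round index][FR primer tail][CDR3 loop][constant framework]

The primer tails are the heavy-chain FR3 3' end (20 nt,
`CTGTTTATTACTGTGTGAGA`) and the light-chain FR4 5' end (18 nt,
`CTTGGTCCCTCCGCCGAA`); the VL primer reads the antisense strand, so VL
reads are reverse-complemented before loop extraction.  Demultiplexing
allows no index mismatches and at most one primer-tail mismatch (Hamming,
no indels; `N` always counts as a mismatch).  The clonotype key is the
full loop up to the downstream framework anchor (`TGGGGC`, the invariant
Trp-Gly opening FR4) when present, else the first 25 bases of the variable
region; a pure 25-base-prefix mode is available (`mode="prefix25"`).
Reads whose variable region is shorter than 25 bases with no anchor are
dropped and tallied.

## Selection model and simulator

Each clone `c` carries a per-generation multiplicative fitness `w_c`; one
generation per selection round.  Frequencies evolve as
`f_{g+1}(c) = f_g(c) w_c / sum_j f_g(j) w_j`, and each sequenced round
draws a multinomial sample of reads from its generation's frequency
vector.  Two rounds may share a generation (the round-3 pool sequenced
before and after a recloning step) and then receive independent draws.

Generator defaults, and why:

- **Abundances** — symmetric Dirichlet, concentration `abundance_alpha=2`.
  This gives clone-to-clone abundance dispersion (CV ~ 0.7) typical of a
  cloned, unselected library, and keeps the most abundant clonotypes near
  1e-3 rather than the percent-level a heavy-tailed prior would give a
  5,000-clone pool; a real naive library spreads its mass over 1e5-1e6
  clonotypes and has no percent-level clones.
- **Frame defects** — `frac_stop=0.1`, `frac_frameshift=0.1`: 80% of
  clones in frame without stop codons, matching the composition such
  libraries show.  Stop clones carry one stop codon at a random loop
  position; frameshift clones carry 1-2 extra bases.
- **Spiked (truly enriched) clones** — total realized fold enrichment
  drawn log-uniform from `spike_fold_range=(100, 500)`.  Fitness is
  calibrated in closed form so the *realized* naive-to-final frequency
  ratio equals the drawn fold despite compositional renormalization
  (`Z = null_mass / (1 - sum_spiked f0*fold)`, `w = (fold*Z)^(1/G)`).
  Spikes are placed at naive frequencies giving 5-20 expected naive-round
  reads at the nominal depth — observable in the naive sequencing (a
  clone absent from the naive pool can never pass the present-in-both
  filter) yet 1-2 orders of magnitude below the abundant clones.  Spikes
  are generated as mutational clusters (members share loop length and
  differ at <= ~20% of positions) so the clustering stage can be scored
  against them.
- **Depth** — nominal 1e6 reads/round (the emulated experiment sequenced
  about 1e6 clones per pool), with per-round yield scaled by a lognormal
  factor, sigma `depth_jitter=0.5`.  Multiplexed sequencing yields vary
  severalfold between libraries on one run; exactly equal depths are an
  artifact no real experiment shows, and the depth differences are what
  the test's thinning resampler exists to remove.
- **Errors** — per-base substitutions at `error_rate=1e-3` (Q30);
  quality strings are constant and never used.  No indels, chimeras, or
  PCR amplification bias are modeled.

What passing tests on this generator do *not* show about real data: PCR
jackpotting and amplification bias, index hopping, within-round selection
kinetics, cell-population bottleneck drift between rounds, and
VH/VL pairing are all absent.  The generator makes the *statistical*
structure the analysis assumes (multinomial counting noise on top of
exponential enrichment, depth imbalance, frame-defect contamination)
available with known ground truth; it is not a sequencing-run emulator.

## Enrichment test

A two-class unpaired resampling rank test on counts, comparing early
pools (naive, R3 before and after recloning) against late pools (R5, R7,
R8):

1. Thin every sample binomially to the minimum column depth (skipped when
   depths are already equal), making counts exchangeable across samples.
2. Per clone, compute the Wilcoxon rank-sum statistic of late vs early
   samples, midranks for ties, centered so 0 means no difference (range
   +-4.5 for 3v3).
3. Average over `n_resamples=100` independent thinnings.  With a 3v3
   design the single-resample statistic is coarse (19 atoms); averaging
   many thinnings separates clones that are consistently extreme from
   clones that reach the extreme by one lucky draw.  100 resamples makes
   this separation sharp at negligible cost.
4. Build the null from all C(6,3)=20 distinct late-label assignments
   (the observed labeling included).  At a cutoff `c`, the false
   discovery rate is estimated as

       FDR(c) = (median_b N_b(c) + 1/2) / (N_obs(c) + 1)

   where `N_b(c)` counts clones beyond `c` in permutation `b`.  The
   half-count guard keeps a zero permutation count from certifying a
   zero false-positive rate — with only 20 permutations the unguarded
   ratio calls a lone noise clone "FDR 0" whenever it exceeds every
   permutation column's maximum, which exchangeability makes a coin
   flip per dataset.  The guard caps resolution at
   `0.5/(N_obs+1)`: a call set must contain at least 10 clones to clear
   FDR < 0.05.  This floor is a property of the tiny permutation set,
   not of the guard; it matches the method's intended regime (hundreds
   to thousands of enriched sequences).
5. A clone's q-value is the minimum estimated FDR over all cutoffs at or
   below its statistic, making call sets nested in the threshold.
   Clones are flagged enriched when `q < 0.05` with a positive statistic,
   depleted when negative.

The test is run on the clones present in both the naive and final
libraries, as the emulated analysis did; clones failing that restriction
cannot survive the cascade regardless.

The per-clone enrichment factor is a ratio of frequencies, never counts:
`E(c) = max(f(c,R7), f(c,R8)) / f(c,naive)`, undefined (NaN, no
pseudocount) when the clone is absent from the naive round.

## Filter cascade

Applied in fixed order, each stage restricted to the survivors of the
previous one; survivor sets are therefore nested by construction:

1. `present_both` — count > 0 in both naive and R7;
2. `fdr_enriched` — flagged enriched by the test;
3. `no_stop` — the loop translates cleanly: length divisible by 3 *and*
   no stop codon (a frameshifted loop has no reading-frame translation,
   and every later stage works on translated loops);
4. `monotonic` — strictly increasing frequencies
   `f(naive) < f(R3) < f(R5) < f(R7)` (R3 is the post-recloning pool;
   the pre-recloning pool enters only the test's early group);
5. `fold100` — `E(c)` strictly greater than 100 (an exact 100x fails).

All comparisons are on frequencies because depths differ by round.

## Clustering into families

Surviving loops are translated; DNA variants with identical amino-acid
loops are pooled first.  The distance between two loops is 1.0 when their
lengths differ and the fraction of mismatched positions otherwise (for
equal-length CDR3 loops, standardized antibody numbering reduces to
position-by-position comparison, so no gap placement is needed).
Agglomerative complete-linkage clustering is cut at distance 0.40 (60%
identity); complete linkage guarantees every within-family pair meets the
identity floor, asserted post hoc.  Merge ties are broken by joining the
lexicographically smallest pair of cluster labels (a cluster is labelled
by its smallest member), which makes the partition independent of input
order and lets a brute-force oracle reproduce it exactly.  Families are
summarized by pooled final-round frequency, pooled fold enrichment
(`max(pooled f_R7, pooled f_R8) / pooled f_naive`), and the amino-acid
loop of the member most abundant at R7.  Retention keeps families with at
least 2 distinct loops and pooled final-round frequency >= 0.1%.

## Phenotype statistics

- Degranulation release %: `S1/(S1+S2) x 100` (released vs unreleased
  enzyme signal), optionally expressed relative to a control clone.
- Stimulation index: ratio of geometric-mean fluorescence of stimulated
  to unstimulated cells; 1.0 means a fully abolished response.
- Normality: Jarque-Bera statistic `n/6 (S^2 + K^2/4)` against
  chi-square(2), plus the D'Agostino skewness z-test (both via scipy;
  these are the named standard tests, not package contributions).
- Two-normal mixture of release distributions: maximum-likelihood EM on
  raw values, two-center 1D k-means initialization with jittered quantile
  starts, best of 5 restarts by log-likelihood, convergence at loglik
  change < 1e-8 or 500 iterations.  A component collapsing below
  1e-3 of the data SD aborts the restart; if all restarts collapse the
  fit is flagged degenerate.  Components are reported high-mode first
  (mu1 > mu2).  Fitting the histogram by least squares is provided as a
  secondary mode for fidelity to curve-on-histogram fitting, but MLE on
  raw values is the primary estimator because it is testable by
  parameter recovery.

## Numerical and interface choices

- Coordinates are 0-based half-open internally.
- Count tables are pandas DataFrames keyed by clone id with the CDR3 DNA
  as the counting key; TSV round-trips preserve them exactly.  Depths are
  column sums; frequencies are counts over depths.
- All randomness flows through `numpy.random.Generator` seeded from the
  config; a config plus seed reproduces FASTQ output byte-identically.
- Demultiplexing is independent of read order; counting is an exact
  multiset count with lexicographic row order.

## Problem sizes used in tests

The automated checks simulate 5,000-clone libraries: round-trip exactness
at depth 1e5 with zero errors; enrichment-test calibration on 50
no-selection runs at depth 1e5; spike recovery (20 spiked clones in 10
clusters, depth 1e6) over 20 seeds; clustering and distance exactness on
30- and 100-sequence pools; mixture recovery at n=500 over 50 seeds.
These sizes hold the full suite to a few minutes on one CPU while keeping
every per-clone count regime (absent, marginal, abundant) represented.

## Known limitations

- With 3v3 groups the permutation set has only 20 members; FDR estimates
  are coarse, and call sets smaller than 10 clones cannot clear the 0.05
  threshold under the guarded estimator.
- The rank statistic saturates at +-4.5, so the test ranks clones only
  weakly within a strong call set; the enrichment factor, not the
  statistic, quantifies effect size.
- In a closed pool, strong enrichment necessarily depresses every other
  clone's frequency.  At high depth and low diversity this compositional
  decline becomes statistically visible and genuinely declining abundant
  clones can be flagged depleted; the package's defaults (diversity,
  depth, spiked mass) sit in the regime the emulated experiment occupied,
  where that decline stays within counting noise.
- Sensitivity of the full cascade is limited at the 100-fold boundary:
  clones whose true fold is within estimate noise of 100 fail the strict
  cut about half the time, by design.
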