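# ibselect

Sequencing analysis for intrabody-based phenotypic selections.

In an intrabody screen, a large single-chain antibody (scFv) library is
expressed *inside* cells, and cells whose intrabody perturbs a phenotype —
here, IgE-receptor-triggered mast-cell degranulation — are enriched over
repeated rounds of FACS sorting.  The readout is amplicon sequencing of the
hypervariable VH CDR3 loops across selection rounds: clonotypes whose
frequency climbs faster than sampling noise mark inhibitory intrabodies and,
through them, their cellular targets.  `ibselect` is for scientists running
or simulating such selections: it turns indexed single-end reads into
per-round clonotype count tables, calls significantly enriched clonotypes,
applies the standard post-test filter cascade, and clusters survivors into
antibody families — plus the small phenotype statistics used to score
individual clones (degranulation release %, stimulation index, normality
tests, two-Gaussian mixture of release distributions).

## The statistics at its core

For clone *c* and round *r*, let `f(c,r) = count(c,r) / depth(r)`.

- **Enrichment test** — a two-class unpaired resampling rank test on
  counts: samples are binomially thinned to the minimum depth, the
  centered Wilcoxon rank-sum of late rounds (R5, R7, R8) versus early
  pools (naive, R3 before/after recloning) is averaged over 100
  thinnings, and the FDR is estimated from all C(6,3)=20 label
  permutations as `(median perm count + ½) / (observed count + 1)` at
  each cutoff, with per-clone q-values taken as the minimum over
  admissible cutoffs.  Clones with q < 0.05 are called enriched or
  depleted by the sign of their statistic.
- **Enrichment factor** — `E(c) = max(f(c,R7), f(c,R8)) / f(c,naive)`.
- **Filter cascade** — present in naive *and* R7 → FDR-enriched → clean
  translation (in frame, no stop codon) → strictly increasing
  `f(naive) < f(R3) < f(R5) < f(R7)` → `E(c) > 100`.
- **Families** — amino-acid loop distance = 1 if lengths differ, else the
  fraction of mismatched positions; complete-linkage clustering cut at
  60% identity; families retained with ≥ 2 distinct loops and pooled
  final-round frequency ≥ 0.1%.

Because no raw data from such screens is generally available, the package
ships a first-class simulator (`ibselect.simulate`) that generates the
whole experiment — library, selection dynamics, indexed 100-base reads —
with ground-truth labels, so every stage is testable end to end.  See
`docs/methods.md` for models, defaults, and limitations.

## Worked example

```python
from ibselect import (
    TestConfig, default_sim_config, draw_library, evolve_rounds,
    permutation_fdr, run_cascade, build_families, select_families,
)
from ibselect.filters import filter_present_both

cfg = default_sim_config(seed=2001, n_clones=5000, n_spiked=20,
                         n_spike_clusters=10, depth_per_round=1_000_000)
clones, truth = draw_library(cfg)          # 5,000 clonotypes, 20 truly enriched
table = evolve_rounds(clones, truth, cfg)  # clone x round counts, 6 rounds

universe = table.subset(filter_present_both(table))
records = permutation_fdr(universe, TestConfig(seed=1))
trace = run_cascade(table, records)
print(trace.counts)

families, _ = build_families(table, clone_ids=trace.final_survivors())
retained = select_families(families)
print(len(retained), sorted(round(f.family_enrichment) for f in retained))
```

Output:

```
{'present_both': 4998, 'fdr_enriched': 20, 'no_stop': 20, 'monotonic': 20, 'fold100': 20}
10 [138, 139, 140, 187, 228, 247, 252, 262, 307, 323]
```

Of 4,998 clonotypes present in both endpoint libraries, exactly the 20
spiked clones survive the test and every filter; they cluster into the 10
seeded families, enriched 138–323-fold from naive to the final round.

The same pipeline runs from a shell:

```bash
ibselect run --config config.yaml --out results/
ibselect demux --reads reads.fastq.gz --samplesheet ss.tsv --out counts.tsv
ibselect test --counts counts.tsv --early naive,R3a,R3 --late R5,R7,R8 --out enr.tsv
ibselect filter --counts counts.tsv --enrichment enr.tsv --out trace.json
ibselect cluster --survivors surv.tsv --counts counts.tsv --out families.tsv
```

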