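# cistromeshift

Tools for asking how induced binding of one transcription factor redistributes
the genomic binding of others — and how those binding shifts couple to gene
expression. The motivating setting is an ETS factor (ELF5) induced in ER+
breast cancer cells, where the pioneer factor FOXA1 and the estrogen receptor
(ER) move to new genomic sites; the machinery is generic to any
induced-binding ChIP-seq + RNA-seq design.

The package is aimed at computational biologists who have per-replicate peak
calls, region read counts, and differential-expression tables, and want a
tested, scriptable implementation of the full analysis chain:

- **Consensus peaks** — regions covered by ≥ *k* of *n* replicate peak sets
  (default 3 of 4), computed as maximal per-base support runs.
- **Differential binding** — a moderated t-statistic on normalized log2
  region counts. With median-of-ratios size factors *s_j* and
  *y_gj = log2(c_gj / s_j + 0.5)*, each region's pooled variance *s_g²* is
  shrunk toward an empirical-Bayes prior, *ṽ_g = (d₀s₀² + df·s_g²)/(d₀+df)*,
  and *t_g = Δȳ_g / √(ṽ_g(1/n₁+1/n₂))* is referred to t with df + d₀ degrees
  of freedom. Benjamini–Hochberg FDR splits regions into gained / lost /
  unchanged at α = 0.05.
- **Motif centrality** — best log2-odds PWM hits within a window around peak
  summits, binned by offset, with all curves jointly normalized to total
  probability 1; plus per-peak motif presence rates.
- **Context enrichment** — per-peak 2×2 odds ratios of a focus set versus an
  explicit background/universe in annotation tracks (repeats, enhancers,
  super enhancers, HOT regions, open chromatin), with Haldane–Anscombe
  correction, Woolf standard errors, Fisher exact p-values, and a chi-squared
  test for the overlap of two cistrome-shift site sets.
- **Co-binding** — φ-coefficient association between factors at classified
  loci and UpSet-style exact-pattern combination counts.
- **Rank enrichment** — a weighted Kolmogorov–Smirnov running-sum statistic
  (GSEA-style ES/NES) over ranked gene lists with gene-set permutation nulls,
  ChIP-derived gene sets (peak summit within 10 kb of a TSS), and matched
  primary/metastasis patient rankings in replicate or single-pair mode.
- **Synthetic data** — a generator that emits every input the pipeline
  consumes (FASTA, narrowPeak, BED, count/DE/patient tables) with planted
  ground truth, so the whole chain is testable without any external download.

## Worked example

Simulate a complete input bundle and run the pipeline on it:

```bash
cistromeshift simulate --seed 1 --out data/
cistromeshift run --input-dir data/ --out results/ --seed 1
```

which prints

```
wrote 45 files to data/
{"consensus": {"ELF5": 266, "FOXA1": 226, "ER": 229},
 "differential_binding": {"n_tested": 253, "n_gained": 25, "n_lost": 14}}
```

Reading `results/summary.json`: 266 ELF5 consensus peaks were called from 4
replicates at 3-of-4 support; of 253 FOXA1 consensus regions tested between
induced and vehicle counts, 25 were gained and 14 lost at FDR < 0.05 (the
generator planted 10% gained and 5% lost). ELF5 consensus peaks overlap the
planted MIR-like repeat track at an odds ratio of 2.18 (Fisher p = 7.0e-4)
against the universe set — the generator planted a 2-fold enrichment. The
gained-site gene set (genes with a gained peak within 10 kb of their TSS) is
strongly positively enriched in the differential-expression ranking
(NES = 2.19, padj = 2.1e-4 at 10⁴ permutations), while the lost-site set is
not (padj = 0.89) — recovering the planted binding→expression coupling. In
the synthetic patient cohort, exactly the 3 responsive pairs of 7 show
significant single-pair enrichment of the induced signature.

Every stage is also runnable standalone (`consensus`, `diffbind`, `motif`,
`context`, `cobind`, `gsea`, `report`); see `cistromeshift --help`.

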