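# Methods

This note documents the statistical models, the defaults and why they were
chosen, what the synthetic-data generator does and does not emulate, and the
numerical conventions used throughout the package.

## Coordinates and interval algebra

All coordinates are 0-based half-open (BED convention). Overlap means ≥ 1
shared base pair, so `[100,200)` and `[200,300)` do not overlap; bookended
intervals do merge at gap 0 (documented because both conventions exist in the
wild). Peaks are unstranded; only TSS records carry strand. A narrowPeak
summit is an offset from the interval start; a missing summit (column value
−1, or fewer than 10 columns) resolves to the floored midpoint.

Consensus peaks are the maximal runs of base pairs covered by at least
`min_support` replicates, after unioning each replicate's intervals so a
replicate can contribute at most one unit of support per base. This is the
strictest reading of a "peak in k of n replicates" rule and is checkable
against a per-base counting oracle, which the test suite does exactly. The
default 3-of-4 matches the replicate design the pipeline targets. Consensus
summits are midpoints: the input replicates' summit calls are not propagated
because a support run may combine offset peaks.

Nearest-TSS distances are signed by gene orientation (positive = downstream
of the TSS); ties on absolute distance resolve to the lexicographically
smallest gene id for determinism. Promoter distance bins default to ≤1 kb /
1–2 kb / 2–3 kb / distal; the bins are an argument since annotation
conventions vary.

## Differential binding

The test operates on a region × sample count matrix with ≥ 2 replicates per
condition. Counts are normalized by median-of-ratios size factors (geometric
mean reference over regions with all-nonzero counts), transformed as
`y = log2(count/sf + 0.5)`, and contrasted with a moderated t:

- per-region pooled variance `s²` with `df = n1 + n2 − 2`;
- empirical-Bayes prior `(d0, s0²)` estimated by moment matching on
  `log s²` (the excess of its variance over `trigamma(df/2)` identifies the
  prior degrees of freedom; the inverse trigamma is solved by Newton
  iteration). Homogeneous true variances drive `d0` large (capped at 1e6),
  recovering a calibrated pooled test; heterogeneous variances yield a finite
  `d0` and partial shrinkage.
- `t = Δȳ / sqrt(ṽ (1/n1 + 1/n2))` with `ṽ = (d0·s0² + df·s²)/(d0 + df)`,
  referred to t with `df + d0` degrees of freedom.

The prior weight can be fixed via the `d0` argument (then the prior scale is
the across-region mean variance). The default estimates it because a fixed
prior weight with an inflated reference df systematically understates the
denominator variability of null regions: in simulation with homogeneous
variances a fixed `d0 = 4` gave empirical type-I error ≈ 0.036 at nominal
0.05, while the estimated prior restores ≈ 0.05. The package therefore treats
the fixed weight as an option, not the default.

Multiple testing uses Benjamini–Hochberg (implemented in-repo, cross-checked
against statsmodels in tests). Gained means q < α and log2FC > 0; lost is the
mirror; α defaults to 0.05. Swapping condition labels negates every log2FC
and exchanges gained/lost exactly (tested).

## Motif analysis

PWMs are probability matrices over ACGT with a background composition
(default uniform); zero cells are replaced with pseudo-probability 1e-4 and
columns renormalized before taking log2 odds, avoiding −∞. Scanning scores
both strands at every offset; N bases contribute 0 (background-neutral). Ties
resolve to the leftmost offset, then the + strand. The default score
threshold is 60% of a PWM's maximum achievable score — a relative rule that
transfers across PWMs of different information content and width; it is a
parameter everywhere it is used.

Centrality profiles take the single best hit per peak per PWM within
± `half_window` (default 250 bp) of the summit, keep it if it passes the
threshold, and bin the hit-center offset (default 10 bp bins). By default all
curves in one profile set share a joint normalization so the grand total over
every curve is 1 — this makes curve heights comparable across motifs in one
figure; per-curve normalization is available via `joint_normalization=False`.
A profile with no passing hits reports total 0 and `empty=True` rather than
raising.

## Context enrichment

The counting unit is the peak: a 2×2 table cross-classifies a focus set and
an explicit background/universe set by annotation overlap. The universe is
always an argument — an odds ratio without a stated universe is meaningless,
so there is no silent genome-wide default. The Haldane–Anscombe +0.5 is
applied to all four cells only when some cell is zero (flagged in the
result); Woolf's `sqrt(Σ 1/cell)` gives the log-OR standard error and a 95%
normal-theory CI; the p-value is always the two-sided Fisher exact test on
the uncorrected counts (tail-probability summation). Windowed profiles expand
*both* focus and background peaks to summit ± window/2 before counting:
expanding only the focus would conflate window size with footprint and
produce spurious enrichment under a uniformly placed annotation (the null
calibration test demonstrates OR ≈ 1 at every window with both expanded).

The chi-squared comparison of two gained-site sets cross-classifies a shared
universe of regions by membership in each set and uses the Pearson statistic
without continuity correction (df = 1), appropriate for the large-count
regime it targets; degenerate margins raise.

## Co-binding

Factor association is the φ coefficient — Pearson correlation of 0/1
membership vectors — which is the natural association measure for
presence/absence data. Constant columns give undefined φ, reported as NaN and
excluded from cofactor selection with a warning. Cofactors of a target are
factors with φ ≥ `min_phi` (default 0.2), sorted by descending φ then name.
Combination counts use exact-pattern (UpSet "distinct") semantics: each locus
contributes to exactly one combination, so counts always partition the class.

## Rank enrichment

The running sum over a ranked list increments by `|score|^weight / Σ_S
|score|^weight` at set members and decrements by `1/(N − |S|)` elsewhere; ES
is the extreme deviation with sign kept (ties between equal-magnitude
positive and negative extremes resolve positive). Weight defaults to 1
(weighted ES); 0 gives the classic statistic. If all member scores are
exactly zero the increments fall back to `1/|S|`.

The null permutes gene sets (random same-size draws without replacement),
matching the model of set-permutation GSEA tools and requiring no
sample-level data. When `C(N, |S|)` is no larger than the permutation budget
the null is enumerated exhaustively and the p-value is exact. Otherwise
p = (1 + #{same-sign null ES with |ES_null| ≥ |ES|}) / (1 + #same-sign),
an add-one estimator that cannot return 0; NES divides ES by the mean |null
ES| of the same sign. Fewer than 10 same-sign permutations triggers an
`UnstableNullWarning`. The leading edge contains the set members up to the ES
extreme (on the extreme's side); the trailing edge contains members beyond
the opposite extreme when the curve crosses it.

DE-based rankings score genes by `sign(log2FC) · (−log10 p)` — monotone in
both direction and evidence — with ties broken by gene id. ChIP gene sets
include a gene when any peak summit lies within `max_distance` (default
10 kb) of its TSS.

Patient pairs are ranked by a moderated metastasis/primary log2 ratio after
median-of-ratios normalization (pseudo-count 0.5). In `replicates` mode the
score is the mean ratio over pairs divided by a moderated standard error
(prior weight 4 toward the across-gene mean variance); in `single_pair` mode
one pair's ratio is standardized by a dispersion estimated from the remaining
pairs — the analysis a cohort of matched tumor pairs supports when asking
whether one patient's metastasis is enriched for a signature.

## Synthetic data generator

The generator emulates the statistical structure of an induced-binding study
and emits every file the pipeline consumes, with ground-truth sidecars.

Shipped defaults (the study conditions all tests run under): a 3 Mb two-
chromosome genome with i.i.d. uniform base composition; 150 MIR-like repeats
per Mb (180 bp each), every repeat carrying an embedded ETS instance sampled
from the PWM (rejection-sampled to stay detectable at the default threshold);
400 genes with uniform TSS; 300 base peaks per factor (200 bp, summit
centered); 4 replicates per factor/condition, each keeping a base peak with
probability ρ = 0.85 and jittering boundaries by N(0, 10 bp); a 2000-peak
uniform universe set. ELF5 base peaks sit on repeats with exactly the
probability that yields a planted per-peak odds ratio of 2 against the
universe (computed from the universe's empirical background overlap rate);
FOXA1/ER base peaks co-locate with ELF5 sites at rate 0.6.

Counts over the FOXA1 consensus are negative binomial in the linear-variance
(NB1) parametrization, `var = μ(1 + φ)` with φ = 0.1 at mean 100, sample
library factors uniform in [0.8, 1.25], and lognormal per-region baselines
(sd 0.3 on the log scale). NB1 was chosen over the quadratic-variance
parametrization because it keeps the planted effect sizes (2-fold, 4 + 4
replicates) in a regime where a well-calibrated test attains high
sensitivity, which is the property the planted-recovery suite is designed to
demonstrate; `dispersion → 0` recovers Poisson-like variance in either
parametrization. Gained regions (10%) get mean × 2 in induced samples; lost
regions (5%) the inverse. Differential structure is planted in counts only —
replicate variability is planted in peak presence — so consensus calling and
differential testing are validated independently.

After gained/lost regions are decided, ETS instances are planted at ELF5 base
summits (rate 0.8), gained-region summits (rate 0.7), and lost-region summits
(rate 0.1), so gained sites carry the inducing motif more often than lost
sites, as induced-binding biology predicts.

The DE table couples to binding: genes with a planted gained region within
10 kb of their TSS draw log2FC ~ N(1.5, 0.5²), others N(0, 0.5²), and
p = 2Φ̄(|log2FC|/0.5) — so null p-values are exactly uniform and effect sizes
and p-values are mutually consistent. Patient tables have 7 matched
primary/metastasis pairs, 3 responsive: responsive metastases multiply the
coupled-gene means by 2^1.5 (NB1 dispersion 0.2, lognormal gene baselines).
A separate binding-compendium simulator plants a 5-factor co-binding block
(latent state probability 0.35, in-block rate 0.9) among 10 independent
background factors.

Randomness is hierarchical: one named child stream per artifact, spawned from
the master seed, so regenerating one artifact never perturbs another; every
emitted byte is reproducible from the seed (checksummed in `manifest.json`).

What the generator does **not** emulate: realistic sequence composition (GC
structure, repeat families beyond a single planted class), read-level noise
(no FASTQ/BAM), peak-width or signal-strength distributions of real ChIP,
correlated gene expression, or batch structure. Passing planted-recovery
tests therefore demonstrates correctness of the statistical machinery under
its stated model, not performance on real data.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` use the shipped 3 Mb / 300-peak /
400-gene configuration, 2000–5000 regions for calibration and recovery
measurements, 10–20 seeds for seed-averaged properties, and 10³–10⁴
permutations for enrichment tests — sizes chosen so the planted effects are
measured with comfortable margins while the whole suite stays fast. All
stochastic steps take explicit seeds; pipeline outputs are pure functions of
(inputs, config, seed).

## Known limitations

- The moderated t assumes approximate normality of log2 counts; very low
  means (< ~10) or extreme dispersions leave that regime.
- Exact Fisher p-values are computed per table; for very large tables the
  chi-squared path is the practical choice.
- The single-pair patient score borrows dispersion from the other pairs;
  genes that respond in *other* pairs have inflated dispersion estimates and
  correspondingly shrunken scores in the tested pair — a conservative bias
  shared by the blind-dispersion strategy it mirrors.
- `windowed_profile` treats each window independently; no multiplicity
  adjustment is applied across windows.
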