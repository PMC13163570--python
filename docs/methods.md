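# Methods

This note documents the models and procedures implemented in `buffatlas`,
the choices made where the methods literature leaves options open, and what
the synthetic-data generators do and do not emulate.

## Expression handling

The expression container is a gene × sample matrix of TPM (transcripts per
million), a within-sample-normalized abundance unit, with per-sample
metadata (tissue, optional lactation stage among dry/early/peak/mid/late,
data source). Validation rejects duplicate identifiers, negative or
non-finite values, and samples without metadata. The detection filter keeps
genes with TPM strictly above 1 in at least one sample; per-tissue
"expressed gene" counts use TPM > 0 in at least one replicate, a stand-in
threshold documented here because detection conventions vary. Replicate
averaging is the arithmetic mean of TPM over a tissue's (or stage's)
samples. Correlation p-values use the t-approximation on n−2 degrees of
freedom (scipy's `pearsonr`/`spearmanr`); Spearman uses tie-corrected
average ranks; missing values are dropped pairwise and zero-variance
columns yield a missing coefficient with a warning rather than an error.

## Housekeeping-gene screen

CV is computed on replicate-averaged tissue means, not raw samples, so
biological between-tissue variation is not conflated with replicate noise.
The standard deviation uses the sample (n−1) denominator by default
(`ddof` is exposed because either convention is defensible). Quartiles of
the CV distribution are computed by linear interpolation (the type-7
estimator, numpy's default). Group assignment checks `cv <= Q1` (low)
before `cv >= Q3` (high); in the degenerate case Q1 = Q3 every gene
satisfies both inequalities and the low-before-high order makes all of
them low — deterministic and conservative for stability calls. Expression
bins are (1, 10], (10, 50], (50, ∞) in mean TPM; core HKGs are low-CV
genes above the high-expression threshold (default 50 TPM). Because
raising the threshold only removes genes, the 50/70/100 rescreens are
nested by construction, which the robustness report exploits. Top-stable
ranking sorts core HKGs by ascending CV, ties broken by descending mean
TPM then lexicographic gene id.

## Smooth quantile normalization and specificity calling

`qsmooth_normalize` implements smooth quantile normalization: sort each
sample; the reference quantile at each rank is the across-sample mean and
the group quantile is the group-wise mean; the per-rank weight is the
within-group share of total variance at that rank
(w = 1 − SSB/SST, clipped to [0, 1], with w = 1 where total variance is
zero), median-smoothed with a running window of 5% of the gene count
(forced odd); the normalized sorted value is w·reference +
(1 − w)·group quantile, mapped back to each sample's original order with
tied input values receiving the mean of their normalized values. Two
numerical details: (i) because the weight varies across ranks, the blended
sequence can be locally non-monotone when group and reference quantiles
diverge strongly, so a cumulative-maximum clamp restores monotonicity and
guarantees exact within-sample rank preservation; (ii) with a single group
SSB = 0 at every rank, all weights are 1, and the procedure reduces exactly
to classic quantile normalization.

TSG calling operates on the qsmooth-normalized, replicate-averaged
profile. A gene is specific to the tissue of its maximal mean when that
mean is ≥ fold × the largest other-tissue mean (fold > 1 makes the call
unique); genes below 1 TPM in every tissue are excluded first. When all
other tissues are exactly zero, the ratio is +∞ and the call stands
provided the target tissue reaches 1 TPM — this convention keeps exclusive
markers inside the TSG universe, so every marker is also a TSG. Markers
require ≥ 1 TPM in exactly one tissue; the threshold mirrors the global
TPM > 1 detection convention. Stage-specific screening reuses the same
fold rule on per-stage means of the mammary samples; the rule transfer is
a documented choice (other criteria, e.g. ANOVA-based, are possible) and
the fold is configurable. The fold-sensitivity report recomputes calls at
3/4/5-fold and tabulates pairwise retention; nesting of the call sets is
analytically forced.

## Reference-gene stability

Relative quantities assume a common amplification efficiency E (default 2,
exposed as a knob because efficiencies were not measured):
Q = E^(Cqmin − Cq) per gene, so the best-expressed sample has Q = 1.

* geNorm: V[j,k] = sample SD over samples of log2(Q_j/Q_k);
  M_j = mean over partners. Stepwise exclusion drops the highest-M gene
  (ties broken by gene id) until two remain; those two are inseparable by
  a ratio-based measure and share the top of the stepwise ranking. The
  pairwise-variation table V_{n/n+1} compares normalization factors
  (means of the top-n log quantities) for consecutive n. The rank vector
  fed to RefFinder orders genes by M on the full panel.
* NormFinder: on log2 quantities, the additive model
  x[g,s] = gene + sample + residual is fitted by two-way centering and a
  gene's stability is the sample SD of its residuals. Published
  bias-corrected variants of the ungrouped estimator are monotone
  transforms of this quantity and therefore produce the same ranking. The
  grouped variant (off by default; no grouping is assumed) scores
  mean over groups of |gene × group interaction| + within-group residual
  standard error, capturing the published model's intergroup term in a
  simplified, documented form.
* BestKeeper: per-gene dispersion of raw Cq (sample SD by default; the
  original tool's mean-absolute-deviation variant via
  `dispersion="mad"`), percent CV, and Pearson correlation with the
  BestKeeper index (per-sample geometric mean of all genes' Cq). Ranking
  is by ascending dispersion.
* RefFinder-style aggregation: geometric mean of each gene's ranks across
  geNorm, NormFinder, BestKeeper and the comparative ΔCt method (mean over
  partners of the SD of pairwise Cq differences). Final ranking ascends by
  geometric mean, ties broken by best single-algorithm rank then gene id.

A known limit worth stating: with six genes and five samples, the
NormFinder residual estimator mixes 1/G of every gene's noise into each
gene's score through the per-sample centering, which caps how often the
single quietest gene can be separated from its nearest competitor; the
aggregate ranking is more reliable than any single algorithm here.

## Trend clustering

Stage profiles are z-scored per gene (sample SD, n−1), dropping flat
profiles, so clustering sees only trajectory shape. Fuzzy c-means uses the
standard alternating optimization of Σ_{g,k} u_{gk}^m‖z_g − v_k‖² with
Σ_k u_{gk} = 1, fuzzifier m = 2 and c = 6 by default (both configurable; c
is a user choice, no selection criterion is implemented). Memberships are
initialized uniformly at random from a seeded generator, making runs
bit-for-bit reproducible per seed; convergence is declared when the
largest membership change drops below 1e−6 (max 300 iterations); a point
coinciding with a centroid gets its membership split evenly among the
coinciding centroids. The objective is recorded every iteration and is
non-increasing. Trait matching z-scores the per-stage trait vector and
takes the centroid with maximal Pearson correlation; hard assignments (for
cluster sizes) take the maximal membership, ties to the lower cluster
index; matching is invariant to cluster relabeling.

## Lactation traits

Stage representatives are days 7 (early), 85 (peak), 145 (mid) and 285
(late); per animal the nearest record within ±5 days is used (the window
is a documented default), then traits are averaged across animals.
Trait correlations are Spearman over all time points. Stage comparisons
use the two-sided Wilcoxon rank-sum test (exact for small untied samples
via `scipy.stats.mannwhitneyu`; identical samples are reported as p = 1),
with Welch's t as an option, and Benjamini–Hochberg adjustment across the
six stage pairs; annotations use *** (p < 0.001), * (p < 0.05), ns. The
test and the adjustment are defaults of this package, not reconstructions
of any particular study's (usually unreported) choices.

## Synthetic data: what it emulates, and what it does not

`simulate_atlas` (default 5,000 genes, 20 tissues, 2–4 replicates;
mammary carries two replicates in each of the four lactation stages)
draws background genes log-normally (median 3 TPM, log-sd 1.2) with
tissue-level log-normal heterogeneity (log-sd 0.5) and multiplicative
replicate noise (log-sd 0.2). These values were fixed once so that the
screening thresholds (TPM 1/10/50; 3-fold) are discriminative but not
trivial: a percent-level background false-positive rate for the fold rule
survives, as in real atlases. Planted classes are disjoint: HKGs
(uniform 60–500 TPM, cross-tissue log-sd 0.03 — low CV and high expression
by construction), TSGs (8× one tissue over a basal level), markers
(5–50 TPM in exactly one tissue, zero elsewhere), and stage genes
(expressed body-wide at a basal level, 8× in one mammary stage —
body-wide expression matters, otherwise stage genes masquerade as mammary
TSGs). Defaults plant 10% HKGs, 10% TSGs, 0.5% markers, 2% stage genes.

`simulate_cq` (6 genes × 5 samples) adds a shared per-sample offset
(default SD 0.2 cycles, modeling well-normalized cDNA input) and per-gene
Gaussian noise whose ascending order is the true stability ranking. geNorm
and NormFinder cancel the offsets exactly; BestKeeper does not, so its
ranking is only informative when loading variation is small relative to
the gene-noise spread — the default models that regime.

`simulate_lactation` (6 animals; dense sampling days 1–25, then every 10
days to day 285) uses a rise–plateau–decline yield curve (saturating rise
to ~10 kg/day by day ~35, plateau to day 115, exponential decline to
4.42 kg at day 285) with animal- and day-level multiplicative noise.
Composition traits couple to the standardized yield with strength
`dilution_strength` ∈ [0, 1]: protein and fat negatively, lactose
positively; protein–lactose inherit a negative correlation through their
opposite couplings. At strength 0 the traits are independent noise. The
companion mammary stage matrix plants three gene groups (yield-like,
inverse, flat trajectories; 200 genes, noise log-sd 0.15).

None of the generators emulate library-size artifacts, batch effects,
count-level sampling noise, gene–gene correlation structure, or annotation
error. Passing the planted-recovery tests therefore demonstrates that the
screening rules and rankings are implemented correctly and behave sanely
under realistic dispersion levels — not that the thresholds would achieve
the same precision on real sequencing data.

## Problem sizes

The test suite and the reproduction script run the atlas pipeline at
5,000 genes × 20 tissues × 3 replicates, stability recovery over 100
seeded 6 × 5 Cq tables, trend recovery over 100 seeded 60-gene stage
matrices, and trait simulations over 100 seeds — sizes chosen to exercise
every code path with stable statistics on a laptop-class machine.
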