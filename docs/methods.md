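# Methods

## The model

`metaplast` detects *metabolic switches*: pathway pairs whose within-sample
dominance relationship differs between age groups of a tumor cohort. The
procedure has four stages.

**1. Pathway activity scoring.** For a pathway *P* with gene weights
*w_g* ≥ 0 and a sample *s* with log-scale expression *x_{g,s}*,

    score(P, s) = Σ_{g ∈ expressed(P)} w_g · x_{g,s} / Σ_{g ∈ expressed(P)} w_g .

Linear-scale input (TPM/FPKM or protein abundance) is transformed to
log2(v + 1) first; without the log, scores are dominated by a handful of
high-abundance genes and the downstream dominance calls become sensitive to
cross-pathway scale. A gene counts as *expressed* when it is present in the
matrix and nonzero in at least one sample of the analyzed cohort (the
minimum sample count is configurable). A pathway is scored only when at
least 30% of its genes are expressed (boundary inclusive); this coverage
gate keeps sparsely measured pathways — common in proteomics — from being
scored on a non-representative gene subset.

**Gene weights.** By default every gene weighs 1. When a protein–protein
interaction edge list is supplied, each pathway's genes are weighted by
their connectivity *within that pathway*: with *d_g* the weighted degree of
gene *g* in the PPI subgraph induced by the pathway's gene set,

    w_g = floor + d_g / max_h d_h ,    floor = 1 by default,

so hub genes count at most (floor + 1)/floor = 2× as much as peripheral
genes. A pathway with no internal edges keeps uniform weights. The exact
weighting used by the original framework is not published in a reusable
form, so this bounded, scale-robust scheme is the package's own choice; it
is isolated behind `attach_ppi_weights` and trivially swappable.

**2. Intra-sample dominance.** For each unordered pathway pair (A, B) with
A < B lexicographically and each sample, the dominance call is +1 when
score(A) − score(B) > τ, −1 when < −τ, and 0 (tie) otherwise, with
τ = 1e−9 absolute by default (exact float equality is fragile). Because the
call compares two scores *within* one sample, it is invariant to any
strictly monotone per-sample transformation applied uniformly to all
pathway scores of that sample — this is what removes sample-level batch
effects, and it is asserted directly by a test that rescales every sample
affinely and checks that no call changes.

**3. Switch testing.** Dominance calls are tabulated per pair into a
group × {first-dominant, second-dominant} contingency table (rows ordered
youngest → oldest; ties are excluded and counted, since a tie carries no
dominance information). The test of independence is:

- chi-square without continuity correction when every expected count is
  ≥ 5 (Fisher handles the small-table regime, so Yates is unnecessary);
- Fisher's exact test for small 2×2 tables;
- a seeded Monte-Carlo permutation test for small r×2 tables with r > 2
  (chi-square statistic under margin-fixed resampling, 10,000 draws by
  default; the seed is mandatory so runs reproduce).

P-values are Benjamini–Hochberg adjusted across all pairs of one cohort,
and switches are screened at adjusted p < 0.05 (strict).

**Odds ratio and direction.** For the 2×2 young/old table the package
defines

    OR = odds(first-dominant | old) / odds(first-dominant | young),

with the Haldane–Anscombe +0.5 added to every cell when any cell is zero.
OR > 1 therefore means the old group is enriched for first-pathway
dominance (direction `toward_first`); OR < 1 means the switch runs toward
the second pathway with age. Swapping the group rows inverts the OR and
flips the direction, and the p-value is unchanged (tested). For three-group
tables the direction is taken from the youngest-vs-oldest margin. Note the
two published conventions for the 2×2 cross-product differ only in row
orientation; the package fixes the orientation by the stated direction
semantics.

**4. Downstream.** The top-k (default 200) significant events per cohort,
ordered by adjusted p with pair-id tie-breaks, become edges of the
*metabo-plastic network*, a multigraph across cohorts: recurrence of the
same pair in several cohorts deliberately counts multiple times toward node
degree, so hubs reflect recurrently rewired pathways. Weighted degree sums
−log10(adjusted p) clipped at 50 per edge (adjusted p can underflow to 0).
Betweenness is computed with exact Brandes traversal on the simple graph
collapsed across cohorts and reported as an auxiliary attribute; hub
ranking is by degree, then weighted degree, then pathway id, making the
"hub node" notion deterministic rather than visual.

## Age grouping

Two modes. *Quartile*: young = age ≤ Q1, old = age ≥ Q3, quartiles by
linear interpolation between order statistics, with boundary samples placed
in the extreme groups so membership is deterministic. *Fixed*: half-open
intervals [0, t1), [t1, t2), [t2, ∞) — with the conventional thresholds
(50, 65), age 50 is middle and age 65 is old. Middle samples stay in the
metadata but are excluded from the default two-group switch contrast;
three-group contingency is supported (used with the fixed grouping in
single-cell work).

## Association with continuous age surrogates

For a pair (A, B) the per-sample signal is score(A) − score(B); its Pearson
correlation with any continuous covariate (chronological age, methylation
age, transcriptional age, pseudotime) is computed on the samples where the
covariate is present (≥ 3 required), with the usual two-sided t-test
p-value. Zero-variance signal or covariate yields a flagged result with
undefined r and p = 1 rather than an error, so cohort-wide scans do not
abort on degenerate pairs.

## Immune profiling and cell-type enrichment

**ssGSEA.** Per sample, genes are ranked by descending expression with ties
broken by gene id. Position *i* (1-based) carries rank weight N − i + 1; a
signature member at position *i* increments the running sum by
(N − i + 1)^α / Σ_{j ∈ S} w_j^α and a non-member decrements it by
1/(N − |S|); the score is the sum of the running sum over all positions,
with α = 0.25. Scores for a run are linearly rescaled so the full
signature × sample matrix spans [0, 1]. The statistic is purely rank-based,
hence invariant to monotone transforms of a sample's expression vector. A
kernel-density variant of the ranking metric exists in some
implementations; this package uses the classic rank statistic because only
ordering and relative enrichment are consumed downstream. Signature gene
sets are user-supplied GMT (the canonical immune signature collections are
third-party tables and are not redistributed; tests use synthetic sets).

**R_o/e.** Observed cell counts per (cell type, group) are compared with
expected counts under independence (row total × column total / grand
total); values > 1 indicate enrichment. For every cell type the
expected-count-weighted mean of its R_o/e values equals 1 exactly (mass
conservation; property-tested to 1e−12). The table is descriptive — no test
statistic is attached.

## Single-cell QC

Per-cell metrics from the raw gene × cell UMI matrix: total UMIs, detected
genes, mitochondrial UMI percentage, and the complexity ratio
log10(genes)/log10(UMIs) (0 when either count is ≤ 1). Five drop rules with
strict comparisons, so boundary cells are kept: UMIs < 200, UMIs > 20,000,
genes > 4,500, mitochondrial % > 10, ratio < 0.8. The ratio is interpreted
on the log scale because a *raw* genes/UMI quotient of 0.8 would reject
essentially every genuine cell (a cell with 5,000 UMIs would need 4,000
distinct genes); raw mode is available via configuration for datasets where
that is really meant. Doublet detection is out of scope; an external
per-cell doublet flag can be passed and is applied after the five rules.

## Synthetic cohorts

**Bulk.** Gene log2-expression = baseline + group effect + N(0, σ), with
per-gene baselines uniform on [2, 8] log2-units (a realistic dynamic range
for log TPM) and σ = 0.5 by default. Baselines are re-centred so every
pathway has the same mean baseline: without this, random pathway-level
baseline gaps (sd ≈ 0.55 log2-units at these ranges) would swamp a planted
1-unit reversal for a material fraction of pairs and the planted switch
would not actually be a dominance reversal. A planted switch (A, B, δ) adds
+δ to all of A's genes in young samples and +δ to all of B's genes in old
samples — planted at the gene level so the coverage gate, weighting and
scoring path are all exercised. Ages are drawn uniformly from disjoint
blocks [35, 50) / [50, 65) / [65, 80) per group, so fixed thresholds
(50, 65) always recover the labels; with equal extreme groups and
n_middle = n_young + n_old the interpolated quartiles fall strictly inside
the block gaps and quartile mode recovers them exactly.

The truth table is a first-class output. It records the planted pairs *and*
the full set of truly switching pairs: planting a group effect on pathway A
necessarily changes A's marginal activity, so every pair (A, C) with C
untouched also has a genuinely group-dependent dominance distribution.
Sensitivity is therefore measured on the planted pairs and empirical FDR
against the truly-null set (pairs whose two pathways carry identical group
effect profiles) — the standard definition of FDR with respect to the
generating model.

**Age covariate.** Given a pair's activity-difference signal, the covariate
is sign(r)·z(signal) + Gaussian noise with variance 1/r² − 1, affinely
mapped to an age-like scale; for n ≥ 100 the realized correlation is
checked against ±0.1 and redrawn up to 10 times.

**Single-cell.** Library sizes are negative-binomial (gamma–Poisson) per
cell type, clipped to [300, 12,000] so clean cells pass every QC rule;
counts are spread over a type-specific profile (Dirichlet-like weights on a
3,000-gene subset of 8,000 genes, mitochondrial genes held near 2% of
mass). Cell-type composition per age group follows the configured
frequencies. QC violators are not sampled but *constructed*: each violator
cell's count vector is built to break exactly one named rule with a wide
margin (e.g. 80 UMIs over 60 genes for `umi_low`) while keeping every other
metric comfortably inside the pass region, so the planted and dropped sets
can be compared exactly.

All generators are pure functions of their config; the same seed produces
identical output.

**What the generators do not emulate** — and hence what passing tests do
not show about real data: gene–gene correlation within and between
pathways, library-size and batch artefacts in bulk data, zero inflation
beyond NB sampling, doublets, ambient RNA, and cell-type-specific
mean–variance trends. The generators exist to verify the statistical
machinery under a known truth, not to imitate any particular dataset.

## Numerical choices and problem sizes

- Tie tolerance 1e−9 absolute on activity differences; ties excluded from
  tables, not split.
- Quartiles by linear interpolation; boundary samples in the extreme group.
- Coverage gate boundary inclusive (3 of 10 genes passes 30%).
- Haldane–Anscombe +0.5 applied to all four cells whenever any cell is 0.
- Permutation p reported as (1 + #{T_sim ≥ T_obs}) / (1 + N_perm).
- BH via the standard step-up; ranking by adjusted p preserves ranking by
  raw p up to ties.
- Degenerate tables (an empty row or column) return p = 1, direction
  `none`, and a flag, rather than raising — cohort-wide scans keep going.
- The recovery study runs 20 seeds of a 50-pathway, 30 + 30-sample cohort
  with 10 planted 1-unit reversals (≈ 1,225 pairs per seed), and the null
  calibration runs 1,000 replicates of a 2-pathway, 50 + 50-sample cohort —
  sizes chosen so the full suite re-runs in about a minute on one core
  while keeping binomial counting error well below the tolerance bands.

## Known limitations

- The activity score is a weighted mean; rank-based or network-propagated
  scores are plausible alternatives and would change absolute scores,
  though dominance calls are robust to per-sample monotone rescaling by
  construction.
- The two-sided Fisher p and the uncorrected chi-square p can differ by a
  few percent even when all cells are ≥ 50 (the exact two-sided definition
  is lumpy near p = 1); the switch rule at expected counts ≥ 5 means the
  choice only matters for tables near the small-count boundary.
- Odds ratios are defined on the two extreme groups; middle-group
  information enters only the r×2 tests.
- No covariate-adjusted (stratified) switch testing; survival screening of
  cohorts is out of scope.
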