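# Methods

`dimetab` analyzes direct-injection FT-ICR MS metabolomics reports: tables
of detected peaks with assigned molecular formulas (CHONSP element counts)
and one intensity column per sample, as produced by formula-assignment
software after spectral processing. The package deliberately starts *after*
formula assignment; raw-spectra processing and formula calling are out of
scope.

## Filtering

Peaks pass four sequential filters: a closed m/z window, removal of ¹³C
isotopologues (their intensities are redundant with the monoisotopic peak),
a maximum absolute formula-assignment error (default 0.5 ppm, inclusive;
peaks without a formula or without a reported error pass this rule — an
unknown error is not evidence of a bad assignment), and a minimum number of
samples with detection (count, or fraction of samples, rounded up). The
removal audit reports counts per rule in application order, attributing a
peak that violates several rules to the first; the counts always sum to
input − kept. Peaks without a molecular formula (C = 0 or H = 0) survive
filtering and appear in diagnostics, but are excluded from indices,
classes, exploration and networks, where a formula is required.

## Thermodynamic and molecular indices

For a neutral formula C_c H_h N_n O_o P_p S_s (charge Z = 0):

- NOSC = 4 − (4c + h − 3n − 2o + 5p − 2s)/c, the nominal oxidation state
  of carbon; −4 (methane) to +4 (CO2) for ordinary compositions.
- GFE = 60.3 − 28.5·NOSC, the Gibbs free energy of the carbon
  half-oxidation reaction in kJ (mol C)⁻¹: reduced compounds are
  thermodynamically costlier to degrade.
- DBE = 1 + (2c − h + n + p)/2, double-bond equivalents.
- AImod = (1 + c − o/2 − s − (n + p + h)/2)/(c − o/2 − n − s − p), the
  modified aromaticity index. It is reported as 0 both when the denominator
  is ≤ 0 **and** when the numerator is negative (e.g. glucose); negative
  values of this index family are conventionally truncated at zero since a
  "negative density of C=C bonds" is not interpretable.

## Compound classes

Classes are assigned on the van Krevelen plane from (O/C, H/C), using an
ordered rectangular region table; lower bounds are inclusive, upper bounds
exclusive, and the first matching region wins, making border assignments
deterministic:

| class | O/C | H/C |
|---|---|---|
| Lipid | [0, 0.3) | [1.5, 2.5) |
| Protein (protein/amino sugar) | [0.3, 0.67) | [1.5, 2.3) |
| Carbohydrate | [0.67, 1.2) | [1.5, 2.5) |
| Unsaturated hydrocarbon | [0, 0.1) | [0.7, 1.5) |
| Lignin | [0.1, 0.67) | [0.7, 1.5) |
| Tannin | [0.67, 1.2) | [0.5, 1.5) |
| Condensed aromatic | [0, 0.67) | [0.2, 0.7) |
| Other | everything else | |

These bounds follow the region tables in common use for natural organic
matter; different laboratories draw the rectangles slightly differently, so
the table is a package constant (`COMPOUND_CLASS_REGIONS`) that can be
replaced wholesale.

## Normalization

Each method is expressed as x′ = (x − location)/scale per sample column:
max (0, max), minmax (min, range), mean (mean, range), median (median,
range), sum (0, Σx), zscore (mean, sd with ddof = 1). Zeros encode
*absence*, not a measured zero: they are excluded from every column
statistic and remain exactly 0 after normalization. This prevents
detection dropout from dragging location estimates toward zero; the
alternative (zeros as true measurements) is a real modelling choice and
the main place where another implementation could differ. Degenerate
columns (zero range or zero sd) raise an error naming the sample.

## Normalization selection (bias scoring)

The selection procedure scores every combination of a peak-subset method
(all peaks; top-L fraction by mean detected log10 intensity, L ∈
{0.05, 0.1, 0.2, 0.5}; presence proportion ≥ p, p ∈ {0.5, 0.75, 1.0}) and
a normalization method. Per cell, the per-sample normalization factors are
computed on the subset's log10 intensities and each factor vector is tested
against the group labels with a Kruskal–Wallis test (midranks,
tie-corrected statistic, chi-square p). The cell score is the mean of
log10 p over the method's factors (location; plus scale for zscore), so 0
means no detectable group association and large-negative means the
normalization would remove group structure. The recommendation is the
method of the maximal-score cell, ties broken by the canonical method
order (max, minmax, mean, median, sum, zscore). This scoring is this
package's own construction in the SPANS spirit — monotone in the same
bias evidence and heatmap-comparable — not a port of any existing
procedure's internals.

## Chemodiversity

Diversity always starts from the **raw** matrix: per sample, detected
intensities are sum-normalized to relative abundances p_i. Shannon
H′ = −Σ p_i ln p_i (nats), Gini–Simpson 1 − Σ p_i², richness = number of
detections. Chao1 is count-based, so intensities are converted to
pseudo-counts by dividing by the sample's smallest positive intensity and
rounding; F1/F2 are the peaks with pseudo-count 1/2 and
chao1 = S + F1(F1 − 1)/(2(F2 + 1)). Under this quantum convention the
minimum peak always has pseudo-count 1, so F1 ≥ 1; the estimator's
no-singleton limit (chao1 = richness) is reached whenever F1 ≤ 1. Rao's
quadratic entropy Q = Σᵢⱼ d_ij p_i p_j uses Gower distances (equal
weights, per-trait range scaling; zero-range traits are uninformative and
excluded from the average) on three trait sets: elemental composition
(C,H,O,N,S,P counts), unsaturation/aromaticity (DBE, AImod) and reactivity
(GFE); abundances are restricted and renormalized to formula-bearing peaks.

## Multivariate statistics

Sample distances follow the normalization: signed outputs (mean, median,
zscore) use Euclidean distance; non-negative outputs (max, minmax, sum,
raw) use Bray–Curtis; Jaccard (presence/absence) is available by explicit
request. PERMANOVA Gower-centers −½D² and partitions tr(G) by projecting
onto design-matrix spans: one-way for one grouping variable, two-way with
interaction and sequential (Type-I) sums of squares, in the given order,
for two. The pseudo-F is calibrated by freely permuting samples;
permutations that merely reproduce the observed design partition (e.g. a
wholesale group swap in a balanced one-way layout) tie F exactly by
symmetry and are rejected and redrawn, so the permutation distribution
runs over distinct label assignments and the observed assignment
contributes the "+1" in p = (1 + #{F* ≥ F})/(1 + n_perm) — the convention
of exact two-sample permutation tests.

NMDS minimizes Kruskal stress-1 by alternating a Guttman (SMACOF) update
with isotonic regression of configuration distances on the dissimilarity
rank order; a run stops as soon as an iteration fails to improve stress by
the tolerance (1e-6), so the reported stress trajectory is non-increasing
by construction. Defaults: k = 2, 20 random restarts (best kept), 300
iterations. Final scores are centered and rotated to principal axes for a
reproducible orientation.

Two PCA summaries are provided on standardized variables (zero mean, unit
variance; constant variables dropped with a warning, detected with a
1e-12 relative tolerance because column means carry round-off): (1) the
per-sample compound-class percentage table and (2) per-sample
"magnitude-averaged" indices Σ(I_i·index_i)/ΣI_i over detected
formula-bearing peaks, with raw intensities as weights.

Group tests on index distributions treat each (peak, sample) detection as
one unweighted observation, run a one-way ANOVA per index and Tukey HSD
(studentized range) for all group pairs; intensity weighting is deliberately
left to the magnitude-averaged PCA view.

## Transformation networks

For each sample, every unordered pair of detected formula-bearing peaks is
matched against a key of named exact mass differences; a pair is an edge
for key entry δ when |Δm − δ| ≤ δ·tol·1e-6 (default tol = 1 ppm). The
tolerance is relative to the *key's* mass difference by default — the
strict reading, since 1 ppm of a small Δm is far below instrument accuracy
at the peak masses; an alternative mode relates the tolerance to the
heavier peak's mass. A pair matching several entries keeps parallel edges
(a best-match mode keeps the minimum-error one). The matcher is a per-key
windowed sweep over the sorted mass list, exactly equivalent to the
O(n²·K) brute force (property-tested). The shipped default key (~30
entries: H2, H2O, CH2, O, NH3, CO/CO2, CH2O, acetyl, sulfonate, phosphate,
sugar and amino-acid residues, …) has its masses computed at runtime from
IUPAC monoisotopic atomic masses; its composition and biotic/abiotic
labels are this package's curation and are meant to be replaced by a
study-specific key CSV.

Per-sample graphs (multigraphs; nodes annotated with mass, class and
indices) are exported as edge-list CSVs and GraphML; statistics cover node
and edge counts, density 2E/(N(N−1)), mean degree, connected components,
per-key and biotic/abiotic counts, and per-sample transformation
percentages with a global top-15 ranking.

## Synthetic studies

The generator emulates a small two-group direct-injection study and is the
test bed for every stage. Defaults: 12 samples in two equal groups, 800
peaks with CHONSP formulas drawn with C ∈ [4, 40], H/C ∈ [0.5, 2.2],
O/C ∈ [0, 1.1] and occasional N/S/P; exact masses from the atomic-mass
table (no jitter by default — the 1 ppm-of-key matching tolerance
corresponds to absolute errors of ~1e-5 Da, so simulated mass noise would
have to be far below instrument-realistic levels anyway to keep planted
edges recoverable, and jitter is available as an option bounded at 0.2 ppm
of the mass); log-normal intensities (log10 mean 6, peak sd 0.5, residual
sd 0.3), 10 % dropout, a 0.3 log10 fold-change on 30 % of peaks for group
B, 5 % formula-less rows and 5 % ¹³C rows to exercise the filters; planted
homologous series (CH2 ladders etc.) detected in every sample guarantee
known network edges. What the generator does *not* emulate: correlated
peak families, intensity-dependent detection limits, isotopic fine
structure, instrument drift or batch effects — passing tests demonstrate
algorithmic correctness and calibration under clean conditions, not
robustness to those artifacts.

## Problem sizes and numerical choices

The shipped checks use desk-scale sizes chosen to exercise every code
path: 500 null simulations × 199 permutations for PERMANOVA type-I
calibration (2 groups × 5 samples), 50 random 200-peak/25-key instances
for the matcher oracle, 20 seeded repeats for bias detection, and a
12-sample/800-peak end-to-end run. Tolerances: 1e-9 for index oracles and
normalization round-trips, 1e-12 for Rao vs. brute force; isotonic
regression from scikit-learn; linear-algebra pseudo-inverses for hat
matrices (rank-deficient designs are handled by construction).

## Known limitations

- The compound-class rectangle bounds and the builtin transformation key
  are curated package constants, not community standards; both are
  replaceable via configuration and should be for publication-grade work.
- Chao1 on intensities relies on the pseudo-count adaptation above;
  treat it as a comparative, not absolute, richness estimate.
- The bias score is a reimplementation in spirit, not a port; absolute
  score values are not comparable to other software, only the ranking
  pattern is.
- Two-way PERMANOVA uses sequential sums of squares; term order matters
  for unbalanced designs.
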