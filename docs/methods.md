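# Methods

This note documents the models and procedures the package implements,
the defaults that matter and why they were chosen, what the synthetic
generator emulates, and the numerical conventions used where the
underlying definitions leave room.

## Abundance-class partition

OTU tables are rarefied to a common depth (multivariate hypergeometric
subsampling without replacement; default depth is the minimum sample
total, since surveys rarely publish theirs) and OTUs with fewer than 20
total reads are removed — low-frequency OTUs are the main source of
spurious "rare taxa" and of unstable correlations downstream. The default
order is rarefy → filter; the reverse is available
(`filter_before_rarefy`) because the two readings of "standardize then
filter" are both found in practice and the choice shifts a handful of
boundary OTUs.

Relative abundance is pooled (OTU total reads over grand total reads).
With equal post-rarefaction depths this equals the per-sample mean, which
is also available (`abundance_mode="mean"`) for unrarefied inputs.
Classification thresholds: abundant strictly above 0.1%, rare strictly
below 0.01%, intermediate otherwise — an OTU sitting exactly on a
boundary is intermediate, since the defining inequalities ("more than",
"below") are strict.

Occupancy is presence/absence based (count > 0) and therefore invariant
to any strictly positive monotone transform of counts. The
abundance–occupancy relationship is a Spearman correlation between log10
mean relative abundance and occupancy, reported overall and per class;
classes with fewer than 3 OTUs or zero variance are flagged undefined
rather than raising.

The taxonomic census counts *distinct* non-"unclassified" names per rank.
An OTU annotated "unclassified" at a rank contributes nothing to that
rank's count, so per-class counts need not sum to the whole-community
count across ranks (they cannot exceed it).

## Co-occurrence networks

All-pairs Spearman correlations use midranks for ties and the
large-sample t approximation for p-values. Benjamini–Hochberg adjustment
is applied over the upper-triangle p-values of the analyzed OTU subset —
one family per network build; the family choice is the main unstandardized
degree of freedom in this kind of analysis, and per-build is the least
surprising. An edge requires |r| strictly above the threshold (default
0.65) *and* adjusted p strictly below alpha (default 0.05); its sign is
the sign of r and its weight |r|. Constant OTUs produce undefined
correlations and simply contribute no edges. Isolated nodes are retained
so densities refer to the analyzed community, not the connected part.

Topology conventions (each one matched by an independent brute-force
oracle in the test suite on graphs of ≤ 30 nodes):

- betweenness: unnormalized shortest-path pair counts, unweighted skeleton;
- closeness: within-component distances only ((reachable−1)/Σd, 0 for
  isolated nodes);
- eigenvector centrality: dense symmetric eigendecomposition of the
  |r|-weighted adjacency of the largest component, |entries| scaled to
  max 1, zero elsewhere (a deterministic solver is used on purpose:
  iterative solvers with random starts make reruns non-reproducible at
  the 1e-6 level);
- clustering: unweighted triangle coefficient;
- graph density 2L/(N(N−1)); average weighted degree is the node mean of
  summed incident |r|.

Printed percentages (positive-link shares, class fractions) are rounded
half-away-from-zero to two decimals; this convention reproduces every
percentage in the published link-decomposition table, which plain
round-half-even does not.

Per-class networks can be built either from class-subset correlation
matrices (`otu_subset=`) or read off the full network by label
(`link_decomposition`); health-group comparison rebuilds the network per
group with identical thresholds while keeping the pooled class labels.

## OPLS-DA

No installed package provides OPLS, so the decomposition is implemented
directly: y-orthogonal components are extracted and removed NIPALS-style
(default 1; "auto" adds components while cross-validated Q2 improves by
more than 0.01, capped at 3), then a single predictive component is fit.
Default scaling is unit variance on relative abundances; pareto and none
are available, and the transform choice is the main reason published
R2Y/Q2Y values are hard to reproduce exactly from counts alone. R2Y is
the in-sample explained class variance; Q2Y uses 7-fold class-stratified
cross-validation with a fixed fold seed. VIP is computed over the single
predictive component, `VIP_j = sqrt(J)·|w_j|` with unit-norm weights, so
mean(VIP²) = 1 holds exactly and is asserted after every fit.

The permutation test refits under shuffled labels and regresses R2 and Q2
on the |correlation| between shuffled and true labels, including the
original model at correlation 1. An overfitting flag (reported, never
decided for the caller) is raised when the Q2 intercept is ≥ 0 or
permuted Q2 exceeds 0 in more than 5% of draws. Differential OTUs combine
VIP > 1 with a two-sided Welch t-test at p < 0.05 — Welch rather than
Student because group variances of abundances are rarely equal, and the
choice is recorded in the output metadata.

## Ecological-preference traits

A trait cell is the sign of a significant Spearman correlation between an
OTU's relative abundance and one soil indicator: +1 if r > 0 and p <
alpha, −1 if r < 0 and p < alpha, else 0. p-values are deliberately *not*
multiple-testing corrected by default: the published count rows this
module's census reproduces are only consistent with raw per-cell p < 0.05
calls, and the trait set is descriptive, not a discovery list. A BH
option exists for the conservative variant. Mean trait score is
(#positive − #negative)/class size; preference breadth is the fraction
of nonzero OTU × indicator cells per class. One published mean-score cell
(intermediate class, fourth indicator, printed −0.6667) disagrees with
its own count row, which gives −0.0667 under the formula that reproduces
every other cell; the package follows the formula and treats the printed
value as a misprint.

Under a permutation null the nonzero-cell rate is ≈ alpha; the test suite
checks this at 500 null OTUs × 6 indicators (±3 binomial SE).

## Threshold indicator taxa analysis

Candidate change points are midpoints between consecutive distinct sorted
gradient values leaving at least `min_split` (default 3, the survey's
setting) samples on each side. At each candidate the larger side's
IndVal (100 × relative mean abundance × occurrence frequency) is
standardized against permutations of sample order (default 250; the
permutation set is shared across candidates, and the whole per-taxon
computation is vectorized with cumulative sums so a taxon costs
O(n_perm · n)).

The change point is the candidate maximizing the *observed* IndVal.
Maximizing the permutation z-score instead is available
(`cp_criterion="z"`) but measurably noisier: the permutation-estimated
standard deviation in the denominator jitters the argmax, and in recovery
simulations (40 samples, planted step, 20 seeds) the z-criterion misses
the flanking candidate interval in 15–25% of seeds at any noise level
while the IndVal criterion recovers all of them. Direction is the winning
side at the change point: left → Z− (decreaser along the gradient),
right → Z+ (increaser). The permutation p is the fraction of permuted
IndVals at the change point reaching the observed one.

Bootstrap purity is the fraction of with-replacement resamples agreeing
with the observed direction, reliability the fraction significant at
0.05 (defaults 500 replicates; degenerate replicates are skipped and
counted). Note that a pure-noise taxon does *not* have purity 0.5:
bootstrap replicates re-observe the same accidental asymmetry, so null
purities cluster around 0.8 in simulation — the 0.95 purity/reliability
filters, which a genuine indicator saturates, are what separate signal
from noise, not distance from 0.5.

Community curves sum per-taxon z values (floored at zero, so the curves
accumulate evidence and stay nonnegative) at every candidate, separately
for decreasers and increasers, optionally restricted to pure-and-reliable
taxa; community change points are the argmax of the filtered curves. The
intended input is the abundant class only — summing over sparse rare taxa
mostly adds double-zero noise.

Analysis abundances are used as given (counts or relative abundances):
IndVal's A-term is scale-free per taxon and permutation z-scores are
insensitive to a monotone rescaling of a single taxon.

## Soil-function coupling

Each indicator is Z-scored across plots with the sample standard
deviation (ddof = 1). Alpha diversity is bias-corrected Chao1
(S_obs + F1(F1−1)/(2(F2+1)); the correction avoids division by zero when
doubletons are absent), computed per sample on each class's OTU subset.
Beta diversity is Bray–Curtis on relative abundances.

The α–function fits are plain per-indicator OLS (n = number of plots)
with two-sided slope p-values and the usual significance flags (* p<0.05,
** p<0.01). The β design regresses pairwise distance on |ΔZ| over all
unordered sample pairs (n = N(N−1)/2); because pairs are not independent,
a Mantel-style permutation p (default 999 when requested) is reported
alongside the OLS p, and an ordination alternative (first principal
coordinate of the distance matrix, n = N) is available via
`beta_pcoa_axis` for designs that want independent observations. The
healthy-vs-diseased α comparison is a two-sided Wilcoxon rank-sum test.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes:
20 samples split evenly into healthy/diseased, ~1000 OTUs, six soil
indicators drawn around realistic ranges (pH ≈ 4.5 ± 0.9 and so on),
log-normal base abundances, multinomial counts at fixed depth (sample
totals are exact), latent-factor co-occurrence modules (negative-sign
modules split into anti-correlated halves), linear or step-shaped
environmental responses with known locations, and per-OTU log-normal
disease fold changes applied to diseased samples only. One seeded
generator drives all randomness; identical seeds give byte-identical
tables.

The log-normal σ defaults to 3.0. At the emulated scale (1000 OTUs,
depth 50 000) σ = 2 produces *more* abundant than rare OTUs after the
<20-read filter, inverting the dominance structure real surveys show;
σ = 3 yields the expected ordering (≈97 abundant < 203 intermediate <
233 rare among 533 retained OTUs at seed 7) while keeping all three
classes well populated and the true class recoverable from counts for
>95% of retained OTUs.

What the generator does **not** emulate: sequence-level artifacts
(chimeras, clustering errors), compositional closure effects beyond the
multinomial draw, spatial autocorrelation between plots, and phylogenetic
signal in abundances. Passing recovery tests therefore show the
estimators work when the model's assumptions hold, not that those
assumptions hold in any particular soil.

## Problem sizes used by the test suite

Stochastic suites run at desk scale: TITAN recovery at 20 seeds × 40
samples with 100 permutations and 100 bootstrap replicates; OPLS-DA
permutation properties at 50 refits; the trait null at 500 OTUs × 6
indicators; the regression type-I check at 1000 replicates. Tolerances
are binomial standard errors at those sizes (±3 SE for rates, ±2 SE for
the regression type-I rate). Oracle-equivalence checks run at 1e-10 to
1e-12 absolute tolerance; graph oracles use graphs of ≤ 30 nodes where
explicit path enumeration is exact.

## Known limitations

- Spearman p-values use the t approximation, which is mildly
  anticonservative below ~10 samples; the trait false-positive
  calibration is verified at n = 20.
- OPLS-DA Q2 on 10-vs-10 designs is high-variance; published R2Y/Q2Y
  values are not reproducible without the original data and transform.
- The β–function OLS p treats dependent pairs as independent (the
  figure-style convention); use the Mantel p for inference.
- TITAN per-taxon outputs depend on permutation/bootstrap sizes; the
  published survey does not state its settings, so defaults follow the
  method's own conventions (250/500) and are configurable.
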