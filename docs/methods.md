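# Methods

`hifnet` reconstructs a disease-specific transcriptional subnetwork from two
independent expression cohorts by anchoring a mutual-information relevance
network on a seed gene list, intersecting the two cohort networks, and pruning
the consensus to transcripts concordantly differential in the disease subtype.
This note records the model, the numerical choices, and what the synthetic
benchmark does and does not demonstrate.

## Preprocessing

The two cohorts are measured on different array platforms, so the analysis is
restricted to the probe sets present in both. Each probe row is
log2-transformed (for raw positive intensities; synthetic data are already on
an additive scale) and then mean-centered within its cohort — equivalently,
expressed as the log2 ratio to the probe's geometric mean. Centering *after*
the log transform is the only well-defined order (centered intensities can be
non-positive) and is standard microarray practice.

Low-information probes are removed by an entropy filter: each probe's values
are binned into `ceil(sqrt(n_samples))` equal-width bins over the probe's own
observed range and probes whose histogram entropy falls strictly below the
10th percentile are dropped (ties at the cutoff are kept). The square-root bin
rule is scale-robust and keeps the statistic comparable across probes; the
filter targets probes whose distribution is concentrated in few bins —
unexpressed probes whose range is set by occasional spikes. An optional
differential prefilter (Welch t-test case-vs-rest, BH-FDR at 0.05, the same
convention as the downstream contrast) removes probes that do not distinguish
the case subtype; it is off by default in the pipeline driver because it is
counterproductive when the wiring of interest includes non-differential seed
stars (see *Synthetic benchmark* below).

## Mutual-information estimation

Pairwise dependence is estimated by Darbellay–Vajda adaptive partitioning on
rank-transformed data (average ranks for ties). A cell of the rank square is
split at its rank-midpoints into four quadrants when it holds at least
`min_split = 8` points and the quadrant-count uniformity statistic
`sum_q (n_q − n_c/4)^2 / (n_c/4)` exceeds the chi-square(3 df) critical value
at `alpha_split = 0.05`; otherwise it becomes a leaf contributing
`(n_c/n) ln[(n_c/n) / ((w_x/n)(w_y/n))]`, and the total is floored at zero.
All MI values are in nats.

Two numerical details matter:

- **Leaf widths are marginal occupancies.** `w_x` is the number of marginal
  ranks inside the leaf's x-interval, which equals the geometric interval
  width for untied data but equals the tie-block multiplicity under ties.
  With geometric widths the estimator would measure divergence from the
  *area* measure of the rank square, which is not the product of the
  marginals when tie blocks are unequal; with occupancies it reproduces the
  discrete plug-in MI exactly once the partition isolates tie blocks (tested
  against a brute-force plug-in estimator on few-valued data).
- **Single-coordinate cells keep narrowing.** A cell whose points all share
  one (x, y) coordinate cannot be separated, but further midpoint splits
  still shrink the interval around the tie block until the occupancy equals
  the block multiplicity; splitting stops only when that has converged (with
  a depth cap of 64 as a guard).

The estimator is unbiased enough at `n = 5000` to match the bivariate-Gaussian
closed form `−ln(1−ρ²)/2` within ±0.1 nats at ρ ∈ {0, 0.5, 0.9}; at cohort-
scale `n ≈ 150` it attenuates strong dependencies (a known resolution limit of
partition estimators), which is why edge detection is calibrated against a
permutation null at the same sample size rather than against absolute MI.
The kernel is compiled with numba; the pipeline evaluates ~10^6 probe pairs in
seconds on one core.

## Edge significance and thresholds

For each cohort, `n_pairs` random probe pairs are drawn, one member of each is
permuted, and MI is estimated, giving a cohort-specific null (the null scale
depends on the sample count). The log empirical survival function (Hazen
plotting positions) is fitted by least squares over the top decile of the
samples: `ln P(MI > m) ≈ a + b·m`, `b < 0`. Edge p-values are
`min(1, exp(a + b·mi))` and thresholds invert the line. The fit is
deliberately extrapolated far below the smallest achievable permutation
frequency — this is how thresholds such as 1e-15 are realized at feasible
permutation counts.

Under the conservative 3-df split rule the null has a large point mass at
exactly zero (the root test rarely rejects — rank margins are fixed, so the
quadrant table has fewer effective degrees of freedom than the nominal 3).
The decile fit therefore spans the point mass: the zero block anchors the
intercept and stabilizes the slope, at the cost of a conservative survival
estimate near zero (which only affects p-values far above any threshold in
use). A fit needs at least a few positive samples in the tail; the
`calibrate_null` default of 1000 pairs is adequate for exploratory use, and
the pipeline driver uses 5000 pairs per cohort for a stable extrapolation
slope. The calibration seed, `a`, `b` and pair count are recorded in the
outputs.

Cohort edge thresholds default to the asymmetric pair p < 1e-15 (first
cohort) and p < 1e-10 (second), reflecting that different sample sizes
require different cuts to yield comparably sized networks.

## Network construction, DPI, consensus, subnetwork

The default network mode computes MI for every (seed probe, other probe) pair
(`seed_restricted`); `all_pairs` is available. Edges with calibrated p below
the cohort threshold are kept. Indirect edges can be pruned with the
data-processing inequality: in each triangle, edge (i, j) is marked when
`mi(i,j) < (1 − tolerance) · min(mi(i,k), mi(j,k))`, all marks evaluated on
the input graph and removed simultaneously (order-independent, idempotent at
tolerance 0). The default tolerance is 0.1, the convention of
relevance-network tools; a purely seed-restricted star network is
triangle-poor, so DPI mostly matters in `all_pairs` mode.

The consensus keeps edges significant in both cohorts (unordered-pair
intersection, both cohorts' attributes retained). Case-vs-rest differential
expression is a per-probe Welch t-test with BH-FDR; a consensus node survives
when q < 0.05 in *both* cohorts and, by default, with concordant direction
(strict concordance; the single color per node in the subnetwork view
presumes it — a non-strict flag is provided). Connected components with at
most 10 distinct genes (counted through the probe→gene annotation, not at
probe level) are discarded as isolated transcripts or small circuits.
"Modules" are connected components, labeled largest-first with ties broken by
smallest node id; community detection is out of scope. The hub table reports
per-node degree against the *worse* (larger) of the two cohorts' raw
differential p-values; adjusted q-values are used only for inclusion
decisions.

## Profiling

- **Subtype coloring**: each subtype versus the rest, restricted to the
  subnetwork's probes with BH-FDR within that probe set (the correction scope
  is a package choice; the per-subtype procedure is one-vs-rest for symmetry
  with the case contrast). Subtypes with fewer than two samples yield an
  all-`ns` column with a warning.
- **Promyelocyte separation**: hierarchical clustering of samples with
  1 − Pearson correlation distance and average linkage, cut into k = 2
  clusters, plus PCA of the same submatrix; agreement with known labels is
  the adjusted Rand index (the package's quantitative stand-in for a visual
  segregation).
- **Treatment reversal**: given per-gene log2 fold changes relative to t = 0,
  the reversal fraction is the share of subnetwork genes moving strictly
  against their disease direction at the final time point; genes without a
  consensus direction are excluded from numerator and denominator. Gene
  direction is the shared direction of the gene's subnetwork probes (`ns`
  when probes disagree). Replicated time-courses should be averaged per
  time point before scoring.

## miRNA integration

miRNAs up-regulated in the case subtype (Welch t-test, Bonferroni over all
tested miRNAs, adjusted p < 0.05, positive mean difference) are ranked by the
number of down-regulated subnetwork transcripts with Pearson r strictly below
−0.4 over the shared samples (the boundary value itself is excluded; ties in
the count are broken by miRNA id). Correlations are computed at probe level
and collapsed to genes for the predicted-target fraction — a gene counts once
if any of its probes passes. Binding-site predictions are consumed as an
external two-column table; an empty anti-correlated list yields NA, not 0.

## Over-representation analysis

A generic hypergeometric upper tail `P(X ≥ k)` with parameters (N background,
K set members in background, n query genes), equivalent to the one-sided
Fisher exact test (verified against both an exhaustive-enumeration oracle and
`fisher_exact`). The background defaults to the genes surviving
preprocessing, not the genome; BH is the default correction.

## Synthetic benchmark

The generator plants, under a linear-Gaussian structural model (chosen so MI
has a closed form and DPI behaviour is predictable):

- 100 seed anchor genes ~ N(0,1), each driving `members_per_anchor = 5`
  member genes as `member = β·anchor + N(0, σ_gene)` with β = 1,
  σ_gene = 0.3 (probe-level correlation ≈ 0.88); anchor–member pairs are the
  planted edges, member–member pairs of a star are deliberately *indirect*;
- an up-regulated case module (30 genes: 2 seed anchors + 28 members) and a
  larger down-regulated module (60 genes: 4 anchors + 56 members), all
  mean-shifted by ±1.5 in the M3 samples of both cohorts — mirroring a small
  up-module and a wide down-module anchored on seed hubs;
- FAB labels M0–M5 with 150 / 145 samples per cohort (20 M3 each, matching
  the disease prevalence of the real cohorts);
- 1–3 probes per gene (cycling deterministically so dimensions are
  seed-independent), probe noise σ_probe = 0.3;
- platform nesting: cohort A's ~2,200 probes are a subset of cohort B's
  (`shared_probe_fraction = 0.9` of B's probes are shared), so the
  cross-platform intersection is A's probe set — the nested-platform
  geometry of the real cohorts;
- 200 "dead" genes with near-constant values and rare spikes, the intended
  victims of the entropy filter — without such probes the 10th-percentile
  cut would cull informative probes at random, an artifact of synthetic
  homogeneity rather than a property of the method;
- 3 regulator miRNAs (plus 20 decoys), up-shifted by 1.5 in M3, each adding
  a −0.8 loading to 20 disjoint down-module genes (planted anti-correlation
  ≈ −0.77); the loading is written into the passed cohort's probe rows, so
  the pipeline runs network inference before miRNA generation and the
  coupling affects only the anti-correlation stage;
- a treatment time-course in which each module gene's shift relaxes as
  `shift·e^(−t/τ)` (τ = 12 h, sampled at 0–72 h, noise sd 0.05, reported as
  log2 fold change versus t = 0), and a 5 + 14 sample normal-vs-leukemic
  promyelocyte cohort over the module probes in which both groups carry
  distinct mean profiles.

Everything is bit-reproducible under (config, seed). What the benchmark does
*not* emulate: heavy-tailed expression noise, batch and scanner effects,
probe-level sequence biases, count-based RNA-Seq noise, correlated background
structure, or realistic miRNA target promiscuity. Passing the recovery tests
therefore shows that the implementation is correct and well-calibrated under
its stated model, not that the model captures every property of real arrays.

### Problem sizes used in the checks

The end-to-end recovery checks run the full default generator (~2,200 shared
probes, 150 + 145 samples, ~550 planted edges). The consensus-versus-single-
cohort precision comparison uses 20 replicates of a scaled-down configuration
(20 anchors, ~330 probes, ~70 samples per cohort) with a loose edge threshold
(1e-4) so that single-cohort false positives occur at a measurable rate — at
the default scale and 1e-15/1e-10 thresholds all precisions are ≈ 1.0 and the
comparison is vacuous. Recovery is scored at gene level: a probe-pair edge
maps to its gene pair, and same-gene probe pairs (trivial self-associations)
are excluded from both numerator and denominator.

## Known limitations

- The 3-df uniformity test is conservative at the root cell (rank margins are
  fixed), so the null MI distribution is nearly degenerate at zero and the
  tail fit leans on few positive samples; the split constants are
  configurable if a sharper null is wanted.
- Extrapolating the exponential tail to p = 1e-15 is a modeling convention,
  not a validated tail probability; thresholds should be read as ranking
  cutoffs, as in the tools this design follows.
- Strict seed-restricted networks cannot produce modules centered on
  non-seed genes; `all_pairs` mode exists for that but scales quadratically.
- The estimator attenuates strong dependencies at n ≲ 200; comparisons
  between MI values are reliable, absolute values at small n are not.
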