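# Methods

This note documents the models, estimators, conventions and synthetic-data
design behind `r2sn`, including every place where the method family leaves
a choice open and what this package chose.

## Regional radiomics profiles

Each atlas region of a preprocessed, atlas-aligned scalar volume is
described by 47 features.

**First-order (14).** energy Σx², entropy and uniformity over an
equal-width histogram (default 32 bins, log base 2), kurtosis (non-excess,
population moments), maximum, mean, mean absolute deviation, median,
minimum, range, root-mean-square, skewness (population moments), standard
deviation and variance (N−1 denominator). A zero-variance region returns
skewness = kurtosis = 0 with a logged warning instead of NaN, so a
degenerate region can never silently poison a downstream correlation.

**Quantization.** Texture features need discrete gray levels. The package
uses fixed-bin-count equal-width quantization over each region's own
min–max range, default 32 levels; the maximum maps to the top level and a
constant region maps to level 1. Per-region (rather than global)
normalization makes texture features invariant to any positive affine
rescaling of the image intensities, which the test suite verifies.

**GLCM (22).** Co-occurrence matrices are accumulated symmetrically (both
orderings of each voxel pair) at distance 1 for each of the 13 unique 3D
offset directions, restricted to voxel pairs lying entirely inside the
region (masked, never zero-padded), then normalized to probabilities.
The 22 features (autocorrelation, cluster prominence/shade/tendency,
contrast, correlation, difference entropy, dissimilarity, energy, entropy,
homogeneity 1/2, IMC 1/2, IDMN, IDN, inverse variance, maximum
probability, sum average, sum entropy, sum variance, variance) follow the
classical catalog with two deliberate conventions:

- *sum variance* is centered on the sum average (it is the variance of the
  i+j distribution). The historical catalog centers it on sum entropy — a
  typographical artifact propagated through the literature — which mixes
  units; the centered form is the meaningful second moment.
- degenerate matrices (a single nonzero cell) make correlation and the
  information measures 0/0; they are returned as 0 with a warning.

Directions in which a region admits no voxel pair are skipped and the
remaining directions are averaged; a one-voxel region has no valid GLCM in
any direction and its GLCM features are 0 with a warning.

**GLRLM (11).** Run-length matrices count maximal runs of equal level
along each of the 13 directions, truncated at the region boundary. The
implementation is a vectorized recurrence (run length ending at a voxel =
predecessor's length + 1 if the predecessor is an in-region voxel of equal
level), validated against an exhaustive run-walking oracle; a conservation
property (Σ counts × length = region voxel count, per direction) is
tested. Features: SRE, LRE, gray-level nonuniformity, run-length
nonuniformity, run percentage, LGRE, HGRE, SRLGE, SRHGE, LRLGE, LRHGE.

**Catalog subsets.** The full catalog has 14 + 22 + 11 = 47 entries. The
default marker set for network construction is the fixed 25-feature subset
(7 intensity: energy, kurtosis, maximum, MAD, minimum, skewness, entropy;
12 GLCM; 6 GLRLM) that survives redundancy removal; using the fixed list
keeps results independent of the data-dependent filter. The filter itself
(`remove_redundant_features`) is also provided: it pools all (region,
subject) rows, computes absolute Pearson correlations between features and
greedily keeps the first feature of each correlated group in catalog order
(|R| > 0.9 drops a feature), which makes it deterministic and idempotent.
Pooling across subjects (rather than one reference subject) is a choice;
a flag would be trivial to add but the pooled form is the default.

## Network construction

Features are min-max normalized per column *within subject* across
regions, so each subject's network is self-contained; a constant column
maps to 0.5 with a warning. The edge between regions i and j is the
Pearson correlation of their normalized 25-vectors; the diagonal is 1.
Cohorts are aggregated entrywise (mean, or std with N−1). The edge
ordering used by every vectorized statistic is the row-major upper
triangle (i < j), fixed and shared package-wide.

## Graph topology

Networks are binarized by strict `weight > threshold` (diagonal off) over
the default sweep 0.50–0.75 in steps of 0.01 (26 thresholds). Metrics:

- degree; neighbor degree (mean degree over a node's neighbors, 0 if
  isolated); betweenness centrality (reported raw and normalized by
  (n−1)(n−2)/2); local clustering (0 for degree < 2) and its mean C;
- characteristic path length L averaged over *connected ordered pairs
  only*, with the connected fraction reported — this keeps L finite on the
  fragmented graphs that high thresholds produce; an empty graph has L
  undefined (flagged);
- sparseness 2m/(n(n−1)); global efficiency = mean of 1/d over all ordered
  pairs with 0 for unreachable pairs, plus per-node efficiency
  contributions.

Shortest paths use breadth-first search (scipy csgraph); betweenness uses
networkx; both are cross-checked in the tests against a pure-Python
brute-force oracle (BFS, explicit triangle counting, exhaustive
shortest-path enumeration) on small graphs.

**Small-world indices.** γ = C/C_rand and λ = L/L_rand, where C_rand and
L_rand are means over an ensemble (default 100, seeded) of uniform random
simple graphs with the same node and edge count — edge-count-matched, not
degree-preserving, which is the stated null for this method family.
σ = γ/λ; σ > 1 indicates small-world organization. Degenerate cases
(zero-clustering nulls, undefined L) yield NaN with flags rather than
exceptions mid-sweep.

## Reliability

**Split-half.** The cohort is randomly split into disjoint halves
(floor/ceil for odd sizes) `n_iter` times; each iteration correlates the
two half-mean edge vectors. Correlations are computed on raw edge values
(no Fisher z).

**Feature-subset robustness.** Each iteration draws k of the features
without replacement (uniformly), rebuilds every subject's network and the
mean network, and correlates it against the full-feature mean network.
Subsets that leave a region with a constant vector are flagged and
redrawn.

**Edge-wise ICC.** Per edge, a one-way random-effects ANOVA over subjects
× sessions gives BMS (between-subject mean square) and WMS (within-subject
mean square). The package reports, per the printed formula of this method
family, the *average-measures* form ICC = (BMS − WMS)/BMS, which under the
one-way model estimates kσ_b²/(kσ_b² + σ_w²) — the reliability of the
k-session mean. Because that formula does **not** estimate the raw
variance ratio σ_b²/(σ_b² + σ_w²) for k > 1, the *single-measures* form
(BMS − WMS)/(BMS + (k−1)WMS) is exposed as `variant="single"`; it is the
estimator used in the variance-ratio recovery tests. Negative estimates
are reported as computed (a truncation flag clips at 0); BMS = 0 gives
NaN.

**Node-size control.** Pearson r (with the exact t-transform p) between
per-node mean connective strength and region voxel count; a size-unbiased
network should show no correlation.

## Associations

The gene similarity network correlates regional expression profiles with
the *same* correlation kernel as the radiomics network (one shared
implementation, asserted identical in the tests). Network-to-network edge
correlation optionally residualizes both edge vectors on the interregional
centroid Euclidean distance by least squares and correlates the residuals
(first-order partial correlation, df reduced by one); the covariate is
applied to both networks symmetrically. Both the adjusted and unadjusted
coefficients are available, since either may be wanted.

Edge-wise and node-wise score associations use the exact t-transform of
Pearson r with n−2 df and Bonferroni correction over the family (4,005
edges or n_regions nodes at 90 regions); corrected p = min(1, p × N).
Whether to associate scores with raw edge weights or with binarized-graph
nodal metrics is analysis-dependent; the package does raw weights for
edges and nodal metrics at a single chosen threshold for nodes.

## Synthetic data

The generators define the package's study conditions; all are pure
functions of a spec plus a seed and return their planted ground truth.

**Phantoms.** Non-overlapping block (or sphere) regions on a 3D grid,
default 90 regions of 10×6×4 voxels on a 30×30×24 grid. Regions belong to
a small number of texture classes (default 6); a class fixes the intensity
mean (80–130), noise amplitude (4–10) and spatial smoothing length
(0.4–1.6 voxels of Gaussian smoothing applied to a standardized noise
field), and regions add a small seeded mean jitter. Smoothed noise is the
simplest mechanism that makes co-occurrence and run-length features
discriminative between regions. Phantom *cohorts* share all class/region
parameters and differ only in the noise realization — subjects from one
population. What phantoms do **not** model: anatomical geometry, bias
fields, partial-volume effects, scanner differences; passing tests
demonstrate correctness and statistical behavior of the estimators, not
performance on real MRI.

**Network cohorts.** A shared latent similarity matrix with modular
structure (default 9 modules over 90 regions; within-module edge weights
uniform on 0.68–0.90, between-module on 0.15–0.65 — the community-like
structure typical of brain covariance networks, and one that stays
non-empty across the whole 0.50–0.75 sweep). Each subject adds symmetric
edge-wise Gaussian effects (sd σ_b, default 0.10), each session adds noise
(sd σ_w, default 0.05); matrices are clipped to [−1, 1] with a warning if
clipping touches > 1% of edges. The implied edge ICC is
σ_b²/(σ_b² + σ_w²).

**Gene tables and scores.** Gene profiles mix a random linear map of the
standardized regional feature profile with independent noise at a tunable
strength in [0, 1], so the network-to-network correlation is monotone in
the coupling. Scores are the standardized mean of planted edge values
scaled by an effect size plus unit noise.

## Problem sizes and numerical choices

The bundled analyses run at desk scale, chosen so the full suite completes
in a couple of minutes: 12-subject phantom cohorts for split-half/subset
statistics (1,000 iterations each), a 40-subject cohort for the
small-world sweep (26 thresholds × 100 nulls), 50 × 4 for ICC recovery,
100 subjects for planted-signal detection and 200 replicate cohorts for
the family-wise error simulation. Consequences of the scale: split-half r
concentrates near 0.9 rather than the ≈ 1 expected of cohorts hundreds of
subjects deep, and σ magnitudes depend on the latent modular structure;
the qualitative facts (σ > 1 across the sweep, γ ≫ 1, λ ≈ 1 in the
connected regime, subset r > split-half noise floor) are scale-stable.

Other numerics: equality comparisons against brute-force oracles are at
1e-10 relative; CSV output uses `%.17g` (round-trip exact doubles) with
`float_precision="round_trip"` parsing; every stochastic routine takes an
explicit seed and derives child seeds from a `numpy` Generator, never
global state; constant-vector detection uses exact max == min on raw
inputs and a 1e-12-relative guard on computed quantities (node strengths,
least-squares residuals) where rounding noise is expected.

## Known limitations

- 2D slice-wise extraction, wavelet/shape feature families, weighted-graph
  metrics, degree-preserving rewiring nulls, community detection and
  spatial-autocorrelation-preserving permutation nulls are out of scope.
- The distance covariate enters linearly; strongly nonlinear spatial
  decays leave residual autocorrelation.
- The redundancy filter's greedy keep-first rule is order-dependent by
  design (deterministic), not an optimal feature selection.
- Regions smaller than 27 voxels (a 3×3×3 neighborhood) are unreliable for
  texture; they are flagged, or rejected in strict mode.
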