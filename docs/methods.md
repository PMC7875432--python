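# Methods

## The mechanism

`splitsort` is a pre-processing layer around off-the-shelf clustering: the
spike feature matrix is subdivided into contiguous subsets of a
per-algorithm optimal length, each subset is clustered independently, and
the resulting sub-clusters are merged back into global clusters by
bounded-region overlap. The layer never modifies a clustering algorithm's
internals; it only changes the size of the inputs the algorithm sees. The
gain comes from the superlinear time complexity of most clustering
algorithms: clustering *N* subsets of size *O_L* costs roughly
*N·f(O_L)* ≪ *f(N·O_L)* when *f* is superlinear.

### Optimal subset length

The estimator probes a backend on growing prefixes (default grid 20, 40, …,
2000, giving ~100 points), smooths the raw wall-clock times with a centered
moving average of window 20 (edge-truncated; even windows take the extra
element from the left, matching the common movmean convention), computes the
discrete rates Δt/Δs on the smoothed curve, and returns the last probed
size before the first rate exceeding 0.1 × the maximum rate. Degenerate
curves are handled explicitly: an all-flat curve returns the largest probed
size with a warning (no inflection ⇒ no reason to subdivide below the
probed range), and an exactly linear curve trips at the first size with a
linearity warning. The probe-smooth-detect cycle is repeated (default 10
repeats, each on a seeded reshuffle of the rows) and the per-repeat values
averaged. The rate rule is deliberately the simple threshold form rather
than a penalized change-point optimization. O_L is machine- and
algorithm-dependent, not data-dependent, so it is estimated once per
backend; all timing-dependent tests inject a deterministic fake clock and
never assert real timings.

### Subdivision

N = ⌈L / O_L⌉ contiguous chunks in recording order (no shuffling). The
ceiling keeps every spike when O_L ∤ L. A final remainder shorter than 10%
of O_L (configurable; 0 disables) is merged into the preceding chunk,
because several backends misbehave on very small inputs. Indices are
0-based with half-open [start, end) bounds.

### Outlier filter and bounded regions

For each (subset, label) sub-cluster with member feature rows S (each row a
single point in m-dimensional feature space):

* centroid C = column mean; ED_l = ‖S_l − C‖₂ gives the distance vector EDM;
* μ = mean(EDM), σ = population SD (divide by n, exactly as defined — not
  the n−1 sample SD); Z = (ED − μ)/σ, with Z ≡ 0 when σ = 0 (a zero-spread
  cluster has no outliers and the standardization is otherwise undefined);
* quartiles use the median-exclusive (Tukey) convention on the ascending
  EDM: Q1/Q3 are medians of the lower/upper halves, the overall median
  belonging to neither half when n is odd;
* the distance distribution is *symmetric* when |(Q3 − med) − (med − Q1)| ≤
  0.2·IQR (strict equality almost never holds for continuous data; the 0.2
  relative tolerance is configurable and 0 recovers the literal rule), and
  *skewed* otherwise; zero IQR counts as symmetric;
* symmetric ⇒ empirical-rule fence [μ − 2σ, μ + 2σ] (≈95% coverage for
  normal data); skewed ⇒ Tukey fence [Q1 − 1.5·IQR, Q3 + 1.5·IQR], applied
  two-sided for both skew directions;
* if the fence would reject every member, all are retained (with a warning)
  so a bounded region always exists.

The bounded region is the per-dimension [min, max] envelope over inlier
members only; filtering can only shrink it. Outliers are excluded solely
from region estimation — they keep their sub-cluster's final label, since
the filter exists to stabilize the merge decision, not to discard spikes.

### Unification

Two regions overlap iff their closed intervals intersect in every one of
the m dimensions; boundary touching counts (closed intervals make overlap
reflexive, and no tie rule is otherwise forced). All k sub-clusters
participate symmetrically, including pairs from the same subset — so the
mechanism can also repair a backend's over-splitting within a subset.
Connected components of the pairwise overlap graph (union-find) become the
global clusters; ids are densified in order of each component's smallest
member row, which makes the final labeling invariant to sub-cluster
enumeration order and directly comparable with a densified conventional
run. Spikes in no sub-cluster (backend noise, label −1) stay −1.

### Evaluation

The confusion matrix is built at ground-truth cluster count q: when the
backend finds m > q clusters only the q largest (dominant) enter, ties
broken toward the earlier first-member row; when m < q the matrix is
zero-padded. Because no canonical ordering of estimated vs true clusters
exists, rows are matched by the one-to-one assignment maximizing the
diagonal (Hungarian method; brute-force permutation enumeration serves as
the test oracle for q ≤ 5) — any fixed ordering would understate accuracy
arbitrarily. Accuracy = 100 × diagonal sum / total spikes; noise spikes
count in the denominator only. Time saved is (C_t − P_t)/C_t × 100, where
P_t includes per-subset clustering plus unification (subdivision is O(1)
index arithmetic) and C_t is the single whole-data run; feature extraction
is timed separately and excluded from both.

## Feature extraction

Both routes reduce 64-sample waveforms to m = 10 features, the
dimensionality used throughout:

* **PCA** — mean-centered projection onto leading axes, scores unscaled (no
  whitening). Fixed mode returns exactly m components; threshold mode
  returns the smallest count reaching 85% cumulative explained variance.
  Axis signs are fixed by forcing each axis's largest-magnitude loading
  positive, for bitwise run-to-run stability.
* **Haar wavelets** — four-level orthonormal (1/√2) multiresolution
  decomposition, coefficient layout [approx L4 | detail L4 | L3 | L2 | L1];
  orthonormality conserves energy exactly, which the tests exploit as a
  free oracle. Per-coefficient deviation from normality is scored with the
  Lilliefors statistic (KS distance to a normal with sample-estimated mean
  and SD, evaluated on both sides of every ECDF jump) and the 10
  highest-scoring coefficients are kept — multimodal coefficients separate
  spike classes, normal-looking ones are mostly noise. Ranking uses the
  statistic itself rather than a p-value, since only the ordering matters;
  zero-variance columns score 0 and ties break toward the lower index.

## Clustering backends

Eight backends are thin adapters over scikit-learn (MeanShift, DBSCAN,
KMeans, AgglomerativeClustering, Birch, OPTICS, GaussianMixture,
BayesianGaussianMixture). K-medoids (Voronoi iteration with
k-means++-style distance-proportional seeding — plain random seeding
converges to poor local optima even on well-separated data) and fuzzy
c-means (Bezdek updates, fuzzifier 2.0, tolerance 1e−5, hard labels by
membership argmax) are implemented in-package. Supervised backends take the
cluster count k as a parameter, applied globally (the same k for every
subset). Density-based backends may return −1 for noise; all backends are
deterministic given the spec (name, params, seed), and per-subset runs use
seed = master seed + subset index so subsets are differently initialized
yet reproducible.

## Synthetic data

The generator emulates labeled 64-sample spike benchmark sets without
external downloads. Templates are differences of two Gaussian bumps
(depolarization peak, delayed hyperpolarization trough) with class-indexed
latency and width offsets, peak-normalized to |amplitude| 1. Spikes are
template × (1 + N(0, amp_jitter)) + i.i.d. Gaussian noise per sample,
shuffled into recording order. Defaults (3 classes, noise SD 0.05,
amplitude jitter SD 0.05) give clearly separable classes comparable to a
clean recording with ground truth; the generative model is a stand-in, not
a reconstruction of any published dataset's simulator. It deliberately
omits features of real recordings — correlated/colored noise, spike
overlap, electrode drift, bursting amplitude decrement — so passing tests
demonstrate the mechanics of subdivision/unification, not robustness to
those artifacts. Feature-space fixtures are isotropic Gaussian mixtures
whose centers are placed uniformly in a box of side 3 × separation × sd and
rejected until all pairwise distances ≥ separation × sd; the generous box
keeps per-dimension center gaps typically larger than bounded-region
widths, so distinct true clusters rarely overlap in every dimension at
once.

## Problem sizes and numerical choices

The test suite and acceptance script use n between 500 and 20 000 spikes
with 3–4 classes: large enough that subdivision produces several subsets
and DBSCAN's superlinear scaling is visible, small enough for quick
single-CPU runs. The kitchen-sink quantities reported by
`scripts/acceptance.py` use 3741 spikes (subdivided at O_L = 935 into 4
subsets), an 8000-point 4-class mixture at O_L = 1000, and 20 000 points
for the DBSCAN timing contrast; the k-means O_L estimate averages 3 probe
repeats over the 20…2000 grid. All randomness flows from the `--seed`
argument.

Tolerances: Haar energy conservation is asserted at relative 1e−10;
distance-statistic worked examples are exact; unification has no tolerance
(interval overlap is exact arithmetic on floats). Timing assertions are
directional only (proposed < conventional), never numeric, since wall-clock
values are machine-dependent.

## Known limitations

* Unification merges by axis-aligned bounding boxes: elongated or oblique
  adjacent clusters can merge spuriously in low dimensions; the m = 10
  feature spaces used here make all-dimension overlap stringent.
* With heavy per-subset noise labeling (DBSCAN/OPTICS at small subset
  sizes, where density drops), the proposed route can mark more spikes as
  noise than the conventional run; O_L should not be pushed far below the
  estimated value.
* The repeat count for O_L estimation defaults to 10; the estimate is
  machine-dependent by construction and not portable across hardware.
* No parallel subset execution, online sorting, raw-signal filtering,
  spike detection or overlapping-spike resolution; inputs are detected,
  aligned spike snippets or precomputed features.
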