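# Methods

## Model and solver

DEC maximizes `Tr(QᵀStQ) − λ‖QᵀXc − GFᵀ‖²_F` over orthonormal `Q` (D×d),
centroids `G` (d×C) and a hard indicator `F` (n×C), where `Xc` is the
feature-centered data and `St = XcXcᵀ` its scatter matrix. The objective
couples the PCA criterion (variance retained in the subspace) with the
K-means distortion measured in that subspace; λ ≥ 0 sets the trade-off.

Centering convention: features (rows of X) are mean-centered across samples
once, before fitting, and the centered matrix is used in **both** objective
terms. `St` is left unnormalized. A single convention keeps the meaning of
λ fixed across data sets; rescaling `St` would silently rescale λ.

Block updates are exact maximizers, derived in closed form:

* fixing `F`: the optimal centroids are the embedded cluster means
  `G = QᵀXcF(FᵀF)⁻¹`; substituting them back reduces the objective to
  `Tr(QᵀMQ)` with `M = St − λ·Xc(I − F(FᵀF)⁻¹Fᵀ)Xcᵀ`
  `= (1−λ)·St + λ·Σ_c n_c m_c m_cᵀ` (m_c = centered cluster means), whose
  maximizer is the top-d eigenvector basis of `M`;
* fixing `Q, G`: each sample goes to its nearest embedded centroid, ties to
  the lowest cluster index; an emptied cluster is re-seeded with the sample
  farthest from its assigned centroid.

Because each block update is exact, the objective is non-decreasing. The
implementation enforces this literally: a step that would lower the
objective — possible only through empty-cluster re-seeding, or at the level
of eigensolver round-off — terminates the run with the previous state kept,
so `objective_trace` is non-decreasing by construction.

Eigenvector sign is fixed by making each column's largest-magnitude entry
positive; this removes the sign indeterminacy of eigendecompositions and
makes runs bit-reproducible.

Convergence: a run stops when the indicator is unchanged, the relative
objective change falls below `tol` (default 1e-6), or `max_iter` (default
100) is reached.

### Restarts and the small-problem polish

Alternating maximization is a local method. The solver runs `n_restarts`
initializations (default 10): the first is PCA + K-means (the canonical
warm start), even-numbered restarts run K-means on a random orthonormal
d-projection of the data, odd-numbered restarts use uniform random labels.
Random-projection K-means starts proved markedly better at escaping local
optima than uniform random labels alone: partitions proposed this way are
geometrically plausible yet diverse.

On small problems (n·C ≤ 200) each restart is finished with an exact
single-move local search: one sample at a time is tentatively relabeled and
the move is kept only if the closed-form reduced objective (sum of the
top-d eigenvalues of `M(F)`) strictly increases. The polish costs one
eigendecomposition per candidate move, which is why it is gated on problem
size; at connectivity scale (hundreds of voxels) the restart scheme alone
is used. With the default 10 restarts plus polish, the solver reaches the
exhaustive-partition optimum on ~99% of random instances with n ≤ 8, C = 2.

λ → 0 limit: with λ = 0 the subspace update no longer depends on `F`, so the
alternation is exactly K-means in the fixed PCA subspace; with a shared
initialization and a single restart the labels equal stepwise PCA + K-means
bit-for-bit. (An analogous equivalence for λ = 1 and the orthogonal
centroid method is documented in the literature but not used as a test
oracle here, since the precise OCM formulation varies.)

## Connectivity features

Features are Fisher-z transformed Pearson correlations between each in-mask
voxel time series and the mean series of R target ROIs (R = 114 in the
default atlas table, grouped into six functional networks). Correlations
are clipped to ±(1 − 1e−7) before `arctanh` so z stays finite; a
zero-variance series yields z = 0 with a warning rather than an error,
because region masks routinely touch flat voxels.

Half-length scans for the stability analysis are contiguous windows of
⌊T/2⌋ time points with uniformly drawn start offsets (with replacement,
seeded; SC = 20 windows by default, T = 1200 at the targeted acquisition
shape). Contiguous windows rather than random time-point subsampling
preserve temporal autocorrelation; whether windows may overlap was an open
choice and overlapping is the implemented default. Leave-one-out stability
correlates, per voxel, the left-out scan's connectivity row with the mean
row of the remaining scans, averaged over all SC passes.

## Stability entropy, silhouette, grid search

Cross-scan label probabilities are per-voxel frequencies over aligned scans;
voxel entropy uses the natural log (recorded in the result so other bases
are convertible) with 0·log 0 := 0, and the summary `H` is the voxel mean,
bounded by [0, ln C]. Labels must be aligned before entropy is meaningful:
clusters are renamed by ascending centroid coordinate along the anatomical
long axis (default the anteroposterior axis, matching an
anterior/middle/posterior reading); without coordinates, alignment falls
back to optimal assignment (Hungarian) on the label confusion matrix.

The silhouette is cluster-level: `a_i` averages Euclidean distances over
unordered within-cluster pairs, `b_i` over (in, out) pairs, and
`SI = (1/C)Σ(b_i − a_i)/max(a_i, b_i)`, with singleton clusters
contributing `a_i = 0` and fully degenerate terms contributing 0. SI is
computed on the original z-connectivity features, not the embedding:
distances in embeddings of different d are not commensurable, so only the
original-space SI makes `SI − H` comparable across grid cells.

The (d, λ) grid search averages SI and H over scans and subjects per cell
(the aggregation order was unstated in the source design; averaging before
forming SI − H is the simplest unbiased choice), then takes the argmax of
SI − H with ties broken toward smaller d, then smaller λ. The default grid
is d ∈ {2, 4, …, 40} × λ ∈ {0, 2, …, 40} (420 cells).

The group template assigns each voxel its most frequent cluster across
subjects and keeps voxels whose winning frequency **strictly exceeds** 0.6
("exceeding" read as strict inequality; 12 of 20 subjects is excluded, 13
of 20 included).

## Group statistics

One-sample t-maps against zero use Benjamini–Hochberg FDR across in-mask
voxels (the named procedure behind the generic "FDR"), then remove
significant components of size ≤ min_cluster (strict "> 10 voxels" rule by
default) under a 26-connectivity neighbor rule (rmm = voxel·√3 + ε), since
no connection rule was prescribed for this filter. Network-level paired
t-tests are Bonferroni-corrected over all subregion pairs × networks
(3 × 6 = 18 per hemisphere for the default three-way parcellation);
zero-variance nonzero paired differences are flagged as degenerate with p
reported below the machine floor rather than erroring.

Two-sample maps use pooled-variance t (groups are size-matched by design),
a two-sided voxel threshold at α, and a Monte-Carlo cluster-extent
threshold in the AlphaSim style: n_sim Gaussian-noise volumes are smoothed
to the stated FWHM, thresholded two-sided at the voxel α, the maximum
suprathreshold cluster size is recorded under the rmm neighbor rule (voxels
are neighbors iff their center distance is ≤ rmm mm; rmm = 7 by default,
which at 3 mm voxels reaches two-step face neighbors), and the returned
minimum cluster size is the smallest s whose simulated corrected
p = P̂(max cluster ≥ s) is ≤ 0.05.

Two numerical choices matter here:

* **Standardization of the simulated field.** The smoothed noise volume is
  scaled by the smoothing kernel's exact root-sum-of-squares (its impulse
  response) rather than by the per-realization sample standard deviation.
  Empirical per-realization standardization shrinks the natural
  realization-to-realization fluctuation of the suprathreshold density and
  was measurably anticonservative in calibration runs (familywise
  significant-cluster rate ≈ 0.07–0.08 instead of 0.05 at a matched null);
  with kernel-exact scaling the measured null familywise rate is 0.050
  (600 replicates).
* **Smoothness must match the data.** The simulation's FWHM is a required
  modeling input. At a liberal voxel α = 0.05 with rmm = 7, suprathreshold
  voxels percolate, so max-cluster distributions are heavy-tailed and very
  sensitive to smoothness; feeding the correction a smoothness the data do
  not have (in either direction) visibly miscalibrates it. Calibration
  tests therefore simulate at the smoothness of the synthetic maps (zero).
  A known limitation inherited from the classic scheme: the Gaussian
  surrogate underestimates cluster sizes of *smoothed* t-statistic fields
  (whose spatially correlated variance estimate inflates clustering), so
  for heavily smoothed small-sample data the correction remains somewhat
  anticonservative — a documented property of AlphaSim-type corrections,
  not specific to this implementation.

## Synthetic data

The generator emulates the statistical structure connectivity-based
parcellation assumes: ROI series are iid standard Gaussian processes; each
voxel's series is its cluster's loading vector (rows of an orthonormalized
random C×R matrix, jittered per voxel with sd 0.1 and renormalized) applied
to the ROI series plus white noise. Defaults mirror the targeted study
shape: 20 subjects, T = 1200, SC = 20 half-length scans, R = 114 ROIs,
three abutting blocks of 100 voxels along the anatomical long axis,
`noise_sigma = 1.0` (noise sd equal to signal sd — a deliberately
conservative yet recoverable regime chosen once, before any evaluation).

Optional planted effects: per-epoch boundary-voxel cluster swaps with
probability `boundary_flip_prob` (plants genuine cross-scan label
instability; entropy grows monotonically with the flip probability and is
exactly 0 at zero flips and zero noise), and a group connectivity shift
realized as extra coupling between chosen voxels and a reference ROI
signal.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: hemodynamics, temporal autocorrelation,
physiological noise, spatial autocorrelation beyond the block structure,
and the anisotropic geometry of real anatomy. One consequence is visible in
the results: planted clusters are near-isotropic in connectivity space, a
regime where plain K-means is already well-suited, so at the default
conditions DEC and K-means are both perfectly stable (both entropies are 0
and the DEC-vs-K-means comparison is satisfied with ties). The stability
advantage of joint optimization on real high-dimensional connectivity
cannot be certified by this generator; the pipeline machinery for measuring
it can be.

## Problem sizes used in the shipped checks

Solver ascent/convergence: 100 random 114×300 matrices. λ→0 equivalence:
50 random instances. Exhaustive oracle: 100 instances with n ≤ 8, C = 2.
Planted recovery: 20 subjects at full study shape (300 voxels, 114 ROIs,
T = 1200, SC = 20). Statistical calibration: BH-FDR on 1000 global-null
draws of m = 2000; cluster-level familywise rate over 150 null cohorts of
20 + 20 maps on a 12³ grid with n_sim = 200; planted 0.5-shift 80-voxel
block over 20 seeds. The acceptance script runs the same computations at
slightly reduced replicate counts (printed in its output alongside each
value).

## Known limitations

* The solver guarantees a non-decreasing objective and multi-restart
  robustness, not global optimality; the exhaustive oracle certifies ~99%
  attainment only at toy sizes.
* The spectral baseline fixes one common construction (symmetric kNN
  Gaussian graph, k = 10, median-distance bandwidth, normalized Laplacian);
  spectral clustering results are known to vary with these choices.
* `rmm`-rule cluster labeling is exact but O(offsets × voxels); it is meant
  for region- and small-volume masks, not whole-brain 1 mm grids.
* No preprocessing is provided: inputs are assumed motion-corrected,
  normalized, filtered and nuisance-regressed.
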