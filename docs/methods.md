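# Methods

This note documents the model behind `phenoseg`, the defaults and why they
are what they are, the numerical choices that are not obvious from the
code, and what the synthetic test scenes do and do not show about real scan
data.

## Surface feature histograms

The per-point descriptor is a joint histogram of three angular features of
point pairs. For a source point **z**ᵢ with unit normal ξᵢ and a neighbour
**z**ⱼ with normal ξⱼ, an orthonormal frame is built from the source normal
and the displacement: u = ξᵢ, v = normalize((**z**ⱼ−**z**ᵢ) × u), w = u × v.
The features are τ₀ = ⟨v, ξⱼ⟩ ∈ [−1,1], τ₁ = ⟨u, **z**ⱼ−**z**ᵢ⟩ / d ∈
[−1,1] and τ₂ = atan2(⟨w, ξⱼ⟩, ⟨u, ξⱼ⟩) ∈ (−π,π]. τ₀ and τ₂ capture the
rotation of the neighbour's normal relative to the source frame, τ₁ the
elevation of the displacement out of the tangent plane; together they
characterize local curvature. On an ideal plane all three are exactly 0; on
a cylinder they vary systematically with the circumferential angle between
the pair.

Two conventions deserve a remark because the naive alternatives fail:

* **v must be normalized.** With a raw cross product, τ₀ and τ₂ would
  scale with the pair distance and lose their meaning as angular
  quantities; the frame must be orthonormal (this is the standard
  point-feature-histogram convention).
* **Binning uses the shifted form.** The sub-index per feature is
  ⌊(τ − τ_min)·b / (τ_max − τ_min)⌋ clamped to [0, b−1]; mapping τ
  without subtracting τ_min would produce negative indices for τ < 0 and
  could not fill b³ bins. The flat index is Σₛ subₛ·bˢ; with the default
  b = 5 the descriptor has 125 bins and the all-center triple (0,0,0)
  lands in bin 62.

### Normal estimation and orientation

Normals come from PCA over all points within r_N of the query point
(inclusive radius, point itself included): the eigenvector of the smallest
covariance eigenvalue. Neighbourhoods with fewer than `min_neighbors_normal`
(default 3) points are flagged invalid and their points dropped from the
histogram set (but reported via `point_index_map`, so cluster ids can be
re-attached to the full cloud with a −1 sentinel).

PCA leaves the normal's sign free, and the sign matters: flipping a normal
negates τ₁ and τ₂ and moves bin indices. The orientation rule is the sign
of ⟨n, **z**ᵢ − c⟩ where c is the neighbourhood centroid — "outward from
the local surface". Both vectors rotate with the cloud, so this rule is
rotation-covariant, which is what makes the computed histograms invariant
under rigid motion of the input (verified to machine precision in the
tests). Where the neighbourhood is flat the dot product vanishes
(|·| ≤ 1e−9) and the outward direction is undefined; there a fixed axis
rule applies (orient toward +z, ties toward +y, then +x). The fallback is
not rotation-covariant, but on flat neighbourhoods all three features sit
at the center of their domains, where the bin index is insensitive to a
consistent sign flip — so the invariance survives in practice. A
viewpoint-based orientation (toward the scanner) would be the natural rule
for real scan data; the scanner position is not part of this package's
input model.

### Weighted aggregation

The final descriptor of point i mixes the raw (count) single-point
histograms of its r_H-ball: x_i = Σⱼ [βⱼ·sp_j + (1−βⱼ)·sp_i] over usable
neighbours j ≠ i, with β = 0.5·(1 − d/r_H) falling linearly from 0.5 at
distance 0 to 0 at the rim, then normalized to sum 1. Two readings of this
formula are possible — normalize the single-point histograms before mixing,
or only normalize the final sum. This package normalizes only the final
histogram; the (1−β)·sp_i term is added once per neighbour, per the literal
summation. Since the result is renormalized, the differences between these
readings amount to a mild reweighting toward points with many neighbours;
the separability results were indistinguishable in exploratory runs.

Defaults r_N = 2.5 mm and r_H = 12.5 mm assume coordinates in millimetres
on a 0.5 mm uniform grid (the package's `uniform_grid_downsample` produces
such grids from denser scans; it keeps the input point nearest each voxel
centroid so output points stay on the measured surface, and anchors voxels
at absolute multiples of the spacing, which makes the operation exactly
idempotent and origin-independent). r_N must be smaller than r_H: the
normal is a local tangent-plane fit, the histogram a mesoscale shape
summary.

## Simplex transforms

Normalized histograms are compositions: nonnegative, summing to one.
Euclidean distance treats a mass shift between two near-empty bins the same
as one between two dominant bins, which is the wrong geometry for
proportions. Two embeddings repair this while keeping ordinary k-means
applicable:

* **Square root** (hc1): y = √x maps the simplex onto the positive quadrant
  of the unit sphere; ‖√x − √y‖² is exactly the Hellinger distance
  Σ(√xᵢ−√yᵢ)² (implemented in the squared form, without the conventional ½
  factor — the k-means equivalence requires this form). No zero handling
  needed.
* **Centered log-ratio** (hc2): y = clr(x) = ln(x/g(x)) with g the
  geometric mean maps the simplex interior onto the zero-sum hyperplane,
  where Euclidean distance is the Aitchison distance. Zeros are handled by
  adding ε to *every* bin and renormalizing (default ε = 1/m, configurable;
  adding everywhere rather than only to empty bins keeps the perturbation
  uniform across bins). The inverse clr is the softmax, computed with
  max-subtraction against overflow.

Both identities are exercised directly in the acceptance checks (deviation
at the 1e−12 / 1e−10 level over 1000 random 125-bin pairs).

## Clustering

The k-means core is a standard EM alternation on the transformed matrix,
with the following pinned-down details (each is a behavioural contract a
test relies on):

* E-step ties go to the lowest cluster id; the per-iteration objective
  trace (recorded after each E-step) is non-increasing.
* Empty clusters are repaired by reassigning the row farthest from its
  current centroid; because the repaired cluster's centroid becomes that
  row itself, the repair never increases the objective.
* Convergence: assignments unchanged, or relative objective change below
  1e−6, or 300 iterations.
* Restarts: default 5; best final objective wins; all randomness flows from
  one seed through named substreams, so identical config + seed gives
  bit-identical assignments.
* Initialization: `auto` enumerates every k-subset of rows as an
  initialization whenever there are no more subsets than restarts, and
  falls back to k-means++ seeding otherwise. The exhaustive mode exists
  because distance-weighted seeding provably concentrates on spread-out
  initializations, and on small instances the global optimum's basin can be
  reachable only from nearby-pair initializations — k-means++ then misses
  it at any realistic restart budget, while subset enumeration is cheap,
  deterministic, and attains the brute-force optimum on every tested
  instance. Plain `k-means++` and `random` init remain selectable.

Cluster representatives are reported on the simplex for every method: `km`
centroids already are (means of simplex points), `hc1` recomputes means of
the original histograms under the final assignments, `hc2` maps the
working-space centroid back through the inverse clr.

The number of clusters k is an input, not an inference: in phenotyping use
the organ classes sought are typically known (k = 2 for stem/leaf, 3 when
ears or berries are present). Automatic model selection is out of scope.

## Evaluation

F-measure weights each label by its frequency and credits it with its best
cluster's harmonic mean of precision and recall; F(i,j) is defined as 0
when n_ij = 0. Entropy is the cluster-size-weighted Shannon entropy
(natural log) of label mixtures within clusters, with 0·ln 0 = 0. F = 1
iff the clustering equals the label partition up to renaming; entropy = 0
iff every cluster is label-pure (both characterized against brute-force
enumeration in the tests). `sweep_k` repeats each (method, k) cell with
fresh seeds derived from a master seed and reports means and standard
deviations, the appropriate summary for a randomly initialized algorithm.

## Synthetic scenes

The generator samples surface grids of three primitives at a target pitch
(default 0.5 mm) and adds isotropic Gaussian noise (default σ = 0.045 mm,
a laser triangulation scanner's typical accuracy). Leaves are
parabolically bent rectangular patches (curvature 0.01/mm in the presets)
rather than pure planes: perfectly flat sheets concentrate all histogram
mass in a single bin and make the clustering problem trivially easy, while
mild curvature is characteristic of real leaf blades. The `barley_like`
preset (a 2 mm-radius, 120 mm stem with three 60×16 mm leaves at 120°
azimuth steps, ~18k points at 0.5 mm pitch) is the standard end-to-end
instance; its size was chosen so the whole pipeline runs in well under a
minute on one core while every point still sees ~2000 histogram-radius
neighbours, as in real grid-reduced scans.

Stem–leaf junction points are deliberately included — organ transitions are
exactly where misassignments are expected, since the local geometry there
interpolates between primitives — but organ-recovery scoring excludes a
2·r_H band around the junctions, because every histogram within that band
mixes single-point histograms from both organs and has no unambiguous
ground truth at the descriptor's own scale.

What the scenes do **not** emulate: occlusion and view-dependent sampling
density, leaf veins and serrated edges, registration artefacts between scan
strips, and outlier returns. Passing the end-to-end checks therefore shows
that the method separates the primitive geometries plants are composed of
under scanner-level noise — not that any particular real species at any
particular growth stage will reach the same scores. On the synthetic
barley scene both transform methods (hc1, hc2) reach mean F = 1.0 with
entropy 0 outside the junction band at k = 2, while the untransformed
baseline averages F ≈ 0.89 over five seeds; the same ordering the method
is designed to produce.

## Numerical details and degenerate inputs

* Pairs whose displacement is parallel to the source normal (‖d × u‖ ≤
  1e−12) have an undefined frame and are skipped.
* Radius comparisons are inclusive (≤); neighbour queries use a k-d tree.
* Histogram rows sum to 1 within 1e−9; clr outputs sum to 0 within 1e−12
  (algebraic identity, not a tolerance-tuned result).
* Points with no valid normal, no usable own histogram, or no usable
  neighbour are dropped, recorded, and reported with a −1 cluster sentinel
  when ids are re-attached to the cloud.
* Downsampling ties (two points equidistant from a voxel centroid) resolve
  to the lowest input index; label majority ties resolve to the smallest
  label id.

## Known limitations

* The axis-rule orientation fallback can flip normals inconsistently on
  *noisy, exactly flat* regions, contaminating their histograms with
  antipodal-normal bins; real leaves are curved enough for the outward rule
  to decide, but a viewpoint-aware orientation would be more robust for
  raw scanner output.
* Memory scales with the number of point pairs inside r_H (~n·2000 for
  0.5 mm grids); clouds beyond a few hundred thousand points should be
  processed in chunks or at a coarser grid.
* ε for the clr path is exposed but fixed per run; data with drastically
  varying sparsity across rows may warrant per-row zero handling, which is
  out of scope here.
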