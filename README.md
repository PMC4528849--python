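# phenoseg

Fully automated, unsupervised segmentation of plant organs from 3D
laser-scanned point clouds.

High-resolution 3D scans of plants (grapevine, wheat, barley, ...) are a
standard data source in plant phenotyping, but turning a raw point cloud
into *organs* — leaves, stems, ears, berries — usually requires manual
labeling or supervised classifiers trained on manual labels. `phenoseg`
implements a data-driven alternative that needs no labels at all: describe
every point by a histogram of its local surface geometry, treat those
histograms as points on a probability simplex, map them into a space where
Euclidean distance is meaningful for compositions, and cluster with plain
k-means. Plant organs locally resemble geometric primitives (leaf blades ≈
gently curved sheets, stems ≈ cylinders, berries ≈ spheres), so the
histograms separate organs well.

## Method

For each point **z**ᵢ of a cloud sampled on a uniform 0.5 mm grid:

1. **Normal** ξᵢ: eigenvector with the smallest eigenvalue of the covariance
   of all points within radius r_N (default 2.5 mm), oriented outward from
   the local neighbourhood centroid.
2. **Angular features** for each neighbour **z**ⱼ within r_H (default
   12.5 mm), in the Darboux frame u = ξᵢ, v = ‖(**z**ⱼ−**z**ᵢ) × u‖⁻¹
   (**z**ⱼ−**z**ᵢ) × u, w = u × v:

   τ₀ = ⟨v, ξⱼ⟩,  τ₁ = ⟨u, **z**ⱼ−**z**ᵢ⟩ / d(**z**ᵢ,**z**ⱼ),
   τ₂ = atan2(⟨w, ξⱼ⟩, ⟨u, ξⱼ⟩).

   Each feature's domain is split into b = 5 subregions; every combination
   is one bin, giving b³ = 125-bin histograms. Neighbour histograms are
   mixed with weight β = 0.5·(1 − d/r_H) and the result normalized to sum 1.
3. **Clustering** of the histogram rows x on the simplex, by k-means with
   Euclidean distance in one of three representations:
   * `km` — the normalized histograms directly (baseline);
   * `hc1` — square-root transform √x (squared Euclidean distance there is
     the Hellinger distance Σᵢ(√xᵢ−√yᵢ)²);
   * `hc2` — centered log-ratio clr(x) = (ln x₁/g(x), …, ln x_m/g(x)) after
     replacing zero bins (add ε = 1/m everywhere, renormalize); Euclidean
     distance there is the Aitchison distance of compositional data
     analysis. Cluster representatives are mapped back to the simplex
     (means of the original histograms for `hc1`, inverse clr — a softmax —
     for `hc2`).
4. **Evaluation** against reference labels by the label-weighted F-measure
   F = Σᵢ (nᵢ/n) maxⱼ F(i,j) and the cluster entropy
   Σⱼ (nⱼ/n)·(−Σᵢ pᵢⱼ ln pᵢⱼ), averaged over independently seeded repeats.

Because no annotated scan data ships with the package, a synthetic-scene
generator produces labeled clouds of plant-like primitives (bent leaf
patches, stem cylinders, berry spheres) at 0.5 mm pitch with Gaussian
scanner noise; the full pipeline is developed and scored against those.

## Worked example

```sh
phenoseg simulate --preset barley_like --seed 1 --noise 0.045 --out scene.ply
phenoseg features --in scene.ply --rn 2.5 --rh 12.5 --bins 5 --out hist.tsv
phenoseg cluster  --hist hist.tsv --method hc2 --k 2 --seed 0 --out clusters.tsv
```

or, as one pipeline run in Python:

```python
from phenoseg import (barley_like, generate_scene, compute_histograms,
                      cluster_histograms, ClusterConfig, evaluate)

spec = barley_like(seed=1)                 # stem cylinder + 3 bent leaves
pc = generate_scene(spec)                  # 18004 labeled points
hs = compute_histograms(pc)                # 18004 x 125 simplex rows
model = cluster_histograms(hs, ClusterConfig(k=2, method="hc2", seed=0))
print(evaluate(pc.labels[hs.point_index_map], model.assignments).f_measure)
```

which prints `0.9947...`: at k = 2 the clr-transformed clustering recovers
stem vs. leaf almost perfectly; the residual disagreement sits at the
stem–leaf junctions, where the local geometry genuinely interpolates
between cylinder and sheet. Excluding a 2·r_H band around the junctions,
both transform methods reach F = 1.0 and entropy 0.0 on this scene, while
the untransformed `km` baseline averages F ≈ 0.89 — the transforms, not the
clusterer, carry the improvement.

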