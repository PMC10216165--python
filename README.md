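# decparc

Functional-connectivity parcellation of a brain region by **discriminative
embedded clustering (DEC)** — joint orthonormal subspace learning and
K-means — together with the full analysis pipeline around it: connectivity
feature construction, cross-scan stability and validity metrics, parameter
grid search, group templates, and seed-based voxelwise group statistics.

## The problem

Subdividing a predefined region (for example the hippocampus) into
functionally homogeneous subregions is a clustering task on voxelwise
functional-connectivity profiles. Those profiles are high-dimensional, so
the standard recipe reduces dimensionality first (PCA) and clusters
afterwards (K-means). Because the reduction step knows nothing about the
clustering objective, the two-stage recipe easily lands in poor local
optima. DEC couples the two stages through a shared transformation matrix
and optimizes them jointly.

## The model

Let `X ∈ R^{D×n}` be the feature-centered data (D = number of target-ROI
connectivity features, n = voxels) with scatter matrix `St = X Xᵀ`. DEC
seeks an orthonormal `Q ∈ R^{D×d}`, centroids `G ∈ R^{d×C}` and a hard
indicator `F ∈ {0,1}^{n×C}` maximizing

```
Tr(Qᵀ St Q) − λ ‖Qᵀ X − G Fᵀ‖²_F      s.t.  QᵀQ = I
```

The first term is the PCA objective (variance retained in the subspace);
the second is the K-means distortion measured *inside* that subspace;
λ ≥ 0 balances them. As λ → 0 the method degenerates to PCA followed by
K-means. The solver alternates two closed-form block updates — `G` is the
matrix of embedded cluster means and `Q` collects the top-d eigenvectors of
`St − λ·X(I − F(FᵀF)⁻¹Fᵀ)Xᵀ`, then each voxel is reassigned to its nearest
embedded centroid — so the objective never decreases. Multiple restarts
(PCA + K-means initialization, K-means on random orthonormal projections,
random indicators) plus an exact single-move polish on small problems guard
against local optima.

Around the solver, the pipeline mirrors a resting-state fMRI parcellation
study: Fisher-z voxel×ROI correlation features against 114 cortical target
ROIs, C = 3 clusters, 20 random half-length scans per subject for a
stability analysis, cross-scan label entropy `H` (Kronecker-delta label
frequencies, natural log) and a cluster-level silhouette `SI`, a (d, λ)
grid search maximizing `SI − H` over d ∈ {2,…,40}, λ ∈ {0,…,40}, a
majority-voting group template (winner probability strictly > 0.6), and
one-/two-sample t-maps with BH-FDR, Bonferroni and Monte-Carlo
(AlphaSim-style) cluster-extent correction.

## Worked example

The synthetic-data module plants three contiguous clusters (~300 voxels,
114 ROIs, 1200 time points, matching the acquisition shape the pipeline
targets) so the whole pipeline runs without any data download:

```python
import numpy as np
from decparc import SyntheticSpec, generate_subject, DECConfig
from decparc.metrics import parcellate_subject
from sklearn.metrics import adjusted_rand_score

spec = SyntheticSpec(n_subjects=1, seed=0)
vts, rts, truth = generate_subject(spec, 0)
res = parcellate_subject(vts, rts,
                         DECConfig(C=3, d=10, lam=2.0, n_restarts=3, seed=0),
                         n_scans=20)
print(f"ARI vs planted labels : {adjusted_rand_score(truth, res.full_labels):.3f}")
print(f"cross-scan entropy H  : {res.consistency.H_mean:.4f}")
print(f"silhouette SI         : {res.silhouette.SI:.3f}")
print(f"voxels per cluster    : {np.bincount(res.full_labels)}")
```

prints

```
ARI vs planted labels : 1.000
cross-scan entropy H  : 0.0000
silhouette SI         : 0.244
voxels per cluster    : [100 100 100]
```

The planted three-block structure is recovered exactly (ARI = 1), the
parcellation is identical across all 20 half-length scans (H = 0, its
minimum; the maximum for C = 3 is ln 3 ≈ 1.099), and the positive
silhouette confirms that within-cluster connectivity profiles are tighter
than between-cluster ones.

The same pipeline is scriptable from the shell:

```
decparc simulate   --out ds --n-subjects 4 --seed 0
decparc parcellate --data ds --out parc --d 10 --lam 2
decparc template   --labels-dir parc --mask ds/mask.nii.gz --out tmpl
decparc compare    --data ds --out cmp        # DEC vs K-means vs spectral
```

Label maps are written as NIfTI volumes (1..C inside the mask, 0 =
background), metrics and grid-search surfaces as TSV, and every command
logs its resolved configuration and seed.

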