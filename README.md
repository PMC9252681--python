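# hybridseg

Multimodal 3D hybrid segmentation of intracranial lesions — a reusable
library and CLI for segmenting bright, lesion-like structures from 2–3
co-registered MRI volumes (e.g. T1/T1C, T2, FLAIR), aimed at researchers
who need a transparent, fully auditable classical pipeline (no training
data) plus a synthetic-phantom harness to validate it.

## Method

The pipeline runs six fixed stages:

1. **Median filtering** — cubic 3³ window per modality, edge-replicated.
2. **Gray stretching** — percentile window mapped affinely onto
   [0, L−1], L = 256 by default.
3. **Linear fusion** — voxelwise convex combination of the stretched
   channels (equal weights by default) into one scalar volume.
4. **Fast fuzzy C-means (FFCM)** — fuzzy C-means minimizing

       J_f = Σ_j Σ_i μ_j(g_i)^r ‖g_i − u_j‖²,   Σ_j μ_j(g_i) = 1,

   computed on the compressed gray **histogram**: identical gray values
   share memberships, so sums over the n = P·Q·W voxels collapse to sums
   over distinct levels weighted by their counts. Iterations then cost
   O(#levels · c) instead of O(n · c) while J_f and the center trajectory
   are provably unchanged (the test suite verifies this against a
   brute-force voxelwise FCM).
5. **Automatic thresholding** — Otsu's between-class-variance criterion
   extracts the bright, under-segmented lesion region from the clustered
   image (by default computed within the two brightest clusters).
6. **Hybrid level set** — the threshold mask seeds an embedding function φ
   (signed distance, positive inside) evolved by

       φ_t = α (U − μ) + β div(k ∇φ),   k = exp(−c |∇U|²),

   the gradient flow of the region+edge energy
   E(φ) = −α∫(U−μ)W(φ) + β∫k|∇W(φ)| under the signed-distance assumption
   |∇φ| = 1, maintained by periodic redistancing. The region force α(U−μ)
   grows the front over voxels brighter than the gray lower limit μ (set
   automatically from the threshold); the edge terms advect the front onto
   intensity boundaries and smooth it.

A seeded phantom generator renders piecewise-constant brain tissue with
ellipsoidal lesions whose modality contrasts follow the classic MR
appearance of melanocytic lesions (melanotic: T1-bright/T2-dark;
amelanotic: reversed; mixed), plus Gaussian or Rician noise and an exact
ground-truth mask — so every stage is testable without patient data.

## Worked example

```python
import hybridseg as hs

spec = hs.default_melanotic_spec(shape=(64, 64, 64), noise_sigma=5.0, seed=42)
stack, truth = hs.generate_phantom(spec)
mask, report = hs.run_pipeline(stack)
print(report.stage_names)
print([round(c, 1) for c in report.stages[3]["centers"]], report.threshold)
print(hs.evaluate(mask, truth).to_dict())
```

prints

```
['median_filter', 'gray_stretch', 'linear_fusion', 'ffcm', 'auto_threshold', 'hybrid_levelset']
[7.4, 9.4, 162.4, 187.7] 158.0
{'dice': 0.9909..., 'jaccard': 0.9819..., 'volume_error': -0.0181..., 'hausdorff': 1.0, 'hausdorff_mm': None}
```

Reading: FFCM found two background-like clusters (centers 7.4, 9.4) and two
tissue clusters (162.4 gray/white, 187.7 lesion); Otsu placed the lesion
lower limit at gray level 158; the level set refined the threshold mask to
2281 of 2323 true lesion voxels — Dice 0.991 with a maximum surface error
of one voxel. The same flow is available from the shell:

```bash
hybridseg phantom --out ph --shape 64 --sigma 5 --seed 42
hybridseg run -i ph/T1WI.nii.gz -i ph/T2WI.nii.gz -i ph/FLAIR.nii.gz --out seg
hybridseg eval --pred seg/mask.nii.gz --truth ph/truth.nii.gz
```

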