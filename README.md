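# bonemorph

Whole-bone trabecular morphometry and sliding-semilandmark geometric
morphometrics for ontogenetic microCT series — a reusable, tested
implementation of the combined internal/external workflow used to study
how a growing bone's architecture and shape change as locomotion matures.

It is aimed at biological anthropologists and bone researchers who want
the full chain as scriptable, seeded components rather than a patchwork
of interactive tools:

* **Segmentation** — windowed two-stage clustering (seeded k-means++
  initializing fuzzy C-means per overlapping subvolume, memberships
  blended across tiles), with an optional white top-hat prefilter for
  poor bone/sediment contrast.
* **Compartments** — opening/closing smoothing, an escalating
  dilate/erode cycle to close a porous cortical shell, and outer/inner
  (periosteal/endosteal) masks that split cortical from trabecular bone.
* **Trabecular metrics** — local BV/TV and the mean-intercept-length
  (MIL) fabric tensor in spheres (default ⌀ 5 mm) on a background grid
  (default 2.5 mm); degree of anisotropy DA = 1 − λ₃/λ₁; global Tb.Th
  and Tb.Sp by maximal inscribed spheres and Tb.N = 1/(Tb.Th + Tb.Sp).
* **Mesh mapping** — Delaunay tetrahedral mesh of the trabecular region
  with scalars interpolated to element centroids, written as ASCII VTK
  for ParaView.
* **Geometric morphometrics** — a 228-point template (8 fixed landmarks,
  45 curve and 175 surface semilandmarks), TPS-driven template
  projection, bending-energy-minimizing semilandmark sliding against a
  recursive Procrustes consensus, partial GPA, shape- and form-space PCA,
  and the conditional test battery (Shapiro/Levene gating ANOVA+Tukey
  vs Kruskal–Wallis+Dunn, Pearson's r against ln centroid size).
* **Pointcloud statistics** — seeded pseudolandmark correspondence,
  closest-to-mean mesh, canonical interior pointcloud (default 1.75 mm),
  rigid/affine/deformable Coherent Point Drift, barycentric scalar
  transfer, and pointwise two-tailed t maps corrected by random field
  theory or max-|t| permutation.
* **Phantoms** — seeded generators for every stage: plate/rod lattices
  and thresholded Gaussian random fields with known BV/TV, thickness,
  spacing and fabric axis; grayscale "scans" with cortical shell, blur,
  noise and sediment; ontogenetic landmark series with a planted
  allometric axis over four locomotor age classes; smooth scalar-field
  ensembles with a planted group effect.

The core quantities, in the field's notation: bone volume fraction
BV/TV = BV/TV (bone voxels over total voxels in the sampling sphere);
fabric from the MIL ellipsoid fit `uᵀMu = MIL(u)⁻²` with eigenvalues
λ₁ ≥ λ₂ ≥ λ₃ and DA = 1 − λ₃/λ₁ (0 isotropic, 1 fully anisotropic);
sliding minimizes the thin-plate-spline bending energy
`tr(YᵀBY)` of each specimen against the consensus; form space augments
Procrustes coordinates with ln CS.

## Worked example

Segment a noisy shelled phantom, separate compartments, and summarize
its trabecular architecture:

```python
import numpy as np
from bonemorph.core import Volume
from bonemorph.phantoms import (PhantomSpec, ImagingSpec,
                                make_lattice_phantom, add_cortex_and_grayscale)
from bonemorph.segmentation import ClusterConfig, mia_segment
from bonemorph.compartments import extract_masks
from bonemorph.metrics import (GridSpec, grid_samples, global_thickness,
                               global_spacing, global_number, summarize_specimen)

spec = PhantomSpec(lattice_kind="plate", voxel_size=0.05, dims=(96, 96, 96),
                   thickness=0.2, spacing=0.6, shell_thickness=0.5, rng_seed=0)
trab, truth = make_lattice_phantom(spec)
gray, _ = add_cortex_and_grayscale(trab, spec, ImagingSpec(noise_sd=18.0, rng_seed=0))

bone = mia_segment(gray, ClusterConfig(n_classes=3, subvolume_edge=64, rng_seed=0))
parts = extract_masks(bone)
samples = grid_samples(parts.trabecular, parts.inner,
                       GridSpec(node_spacing=1.0, sphere_diameter=2.0, n_mil_directions=64))
th = global_thickness(parts.trabecular)
sp = global_spacing(parts.trabecular, parts.inner)
summary = summarize_specimen(samples, th, sp, global_number(th, sp))
print(summary.to_frame().round(3).to_string(index=False))
print(f"analytic truth: BV/TV {100*truth.true_bvtv:.1f}%  "
      f"Tb.Th {truth.true_thickness} mm  Tb.Sp {truth.true_spacing} mm")
```

prints

```
   DA  DA_SD  BVTV_pct  BVTV_SD_pct   TbN  TbSp  TbTh  n_samples
0.981  0.023    22.789        4.751 1.297 0.574 0.197         83
analytic truth: BV/TV 25.0%  Tb.Th 0.2 mm  Tb.Sp 0.6 mm
```

Reading the output: the plate lattice is maximally anisotropic
(DA ≈ 0.98 with the fabric minor axis on the plate normal), Tb.Th
recovers the 0.2 mm plate thickness to well under a voxel, and Tb.Sp
the 0.6 mm gap (slightly low because spheres at the endosteal margin
clip the outermost marrow slab — the same is true of the mean local
BV/TV, 22.8% vs the 25% lattice value). All of this ran from a noisy
grayscale volume: segmentation and compartment separation happened
between the phantom and the numbers.

The same stages are available from the shell:

```bash
bonemorph run --seed 7 --outdir demo_run          # full demo battery
bonemorph segment --input scan.nrrd --output bone.nrrd --classes 3 --seed 0
bonemorph compartments --input bone.nrrd --outdir masks/
bonemorph metrics --trabecular masks/trabecular.nrrd --inner masks/inner.nrrd --outdir out/
```

`bonemorph run` writes every artifact plus a manifest (config hash,
seeds, output checksums); rerunning from the manifest reproduces all
outputs bit-exactly.

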