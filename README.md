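# moco4d

Fast motion-compensated (MoCo) reconstruction for 4D cone-beam CT.

In image-guided radiotherapy of the thorax, a 1-minute cone-beam CT scan is
sorted into N ≈ 10 respiratory phases; reconstructing each phase from only
its own projections (4D FDK) leaves severe streaking because each bin keeps
a sparse, widely spaced subset of the ~180–900 views.  `moco4d` implements
the pipeline that removes this undersampling penalty at near-interactive
speed:

1. **Respiratory binning** — an Amsterdam-Shroud-style breathing surrogate
   is extracted from the projections themselves and projections are sorted
   into phase bins anchored at end-inhale.
2. **4D FDK** — cosine-weighted, ramp-filtered, voxel-driven
   Feldkamp–Davis–Kress reconstruction per bin (full-fan circular scans).
3. **Self-supervised artifact reduction** — *pseudo-average* bins mix
   projections from different phases across breathing cycles; their FDK
   images show phase-bin streaks but time-averaged motion, so
   (pseudo-average, time-average) pairs train a residual 3D U-Net denoiser
   without any external ground truth.
4. **Deep groupwise registration** (the core) — a CNN maps all N phase
   images, concatenated along channels, to N displacement fields
   D_tem^n to an *implicit template* I_tem = (1/N) Σ_n I_n ∘ T_tem^n,
   with T_tem^n(p) = p + D_tem^n(p), trained by minimizing

       L = L_sim + λ₁ L_spatial + λ₂ L_temporal + L_con

   where L_sim is the mean negative windowed squared local normalized
   cross-correlation (LNCC, 5³ windows) between each warped phase and the
   template, L_spatial is a bending-energy penalty on second differences,
   L_temporal a diffusion penalty along the (cyclic) phase axis, and
   L_con = λ₃ · RMS(Σ_n D_tem^n) pins the template to the motion centroid
   (λ₁ = 1, λ₂ = 1e−5, λ₃ = 5e−2, Adam at 1e−3).  Two learning modes:
   *one-shot* (patient-specific; trained from scratch on the single image
   set, convergence when the loss deviates from the 20-iteration moving
   average by < 1e−5) and *population* (pre-trained on many 4D sets for a
   fixed 200 epochs, applied to new data in a single forward pass).
   All pairwise motions follow by inversion + composition:
   T_i^j = T_tem^j ∘ (T_tem^i)⁻¹.
5. **MoCo FDK** — every projection contributes to every target phase by
   warping the backprojection trajectory: voxel p is displaced to
   p + D_target^j(p) before computing its detector coordinates, where j is
   the projection's phase bin.

A deformable digital thorax phantom (analytic shapes, smooth tissue
texture, sin²-phase breathing with a known weight field) provides exact
phase volumes, inter-phase displacement fields and paired landmarks, so
the whole chain is testable end to end without any data downloads.

## Worked example

Register a 4-phase breathing phantom (8 mm amplitude) and evaluate the
recovered motion against analytic landmarks:

```python
import numpy as np
from moco4d import (GridSpec, PhaseImageSet, GroupwiseRegistration,
                    RegistrationConfig, LandmarkSet, compute_tre,
                    default_phantom, default_breathing, rasterize_phantom,
                    phantom_landmarks, bin_motion_phase)

spec = default_phantom()
breathing = default_breathing(amplitude_mm=8.0, spec=spec)
grid = GridSpec(shape=(24, 32, 32), spacing=(8.0, 8.0, 8.0))
phases = [bin_motion_phase(b, 4) for b in range(4)]
vols = [rasterize_phantom(spec, breathing, p, grid, supersample=2)
        for p in phases]
peak = max(v.data.max() for v in vols)
images = PhaseImageSet([v.copy_with(v.data / peak, kind="normalized")
                        for v in vols])

model = GroupwiseRegistration(images, RegistrationConfig(max_iter=300, seed=0))
result = model.fit(method="one-shot")
print(result.summary())

motion = result.motion_model()
li, lj = phantom_landmarks(spec, breathing, 100, phases[0], phases[2],
                           grid, seed=5)
fixed = LandmarkSet.from_voxel0(li, grid.spacing)
moving = LandmarkSet.from_voxel0(lj, grid.spacing)
before, _, _ = compute_tre(fixed, moving)
after, _, _ = compute_tre(fixed, moving, dvf=motion.field(0, 2))
print(f"landmark TRE: {before:.2f} mm before -> {after:.2f} mm after")
```

Output:

```
Groupwise registration results
==============================
phases:              4
grid:                (24, 32, 32)
iterations:          83
converged:           True
total loss:          -0.62453
  similarity:        -0.624823
  bending energy:    3.80304e-05
  temporal diffusion:1.2261e-07
  zero-mean penalty: 0.000254516
max |D| (voxels):    0.486
mean |D| (voxels):   0.096
landmark TRE: 3.45 mm before -> 0.87 mm after
```

The converged similarity of −0.62 means 62% of foreground windows reach
perfect local correlation with the implicit template; the recovered motion
cuts the landmark error from 3.45 mm (the raw breathing displacement
between end-exhale-side and end-inhale-side phases) to under a voxel.

## Command line

`moco4d {simulate, signal, bin, fdk, artifact-reduce, register, moco,
evaluate}` — each a thin wrapper over the library, reading/writing MHA or
NIfTI volumes, a JSON geometry sidecar for projections, DIR-Lab-style
landmark text files and JSON/TSV metric reports.  `moco4d simulate
--config cfg.yaml --out dir --seed 1` writes a full synthetic study.

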