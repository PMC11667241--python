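# Methods

This note records the models implemented in `moco4d`, the parameters that
matter, the numerical choices behind them, and what the synthetic study
does and does not demonstrate.

## Imaging model and geometry

Projections are line integrals of a non-negative attenuation field
(mm⁻¹) along rays from a point source to a flat detector, circular
full-fan orbit, SID 1000 mm / SDD 1500 mm by default.  Conventions:
volumes indexed `[z, y, x]`, world coordinates in mm with z the rotation
(superior–inferior) axis, gantry angle counter-clockwise from the +y
source position, grids centred on the isocenter.  Displacement fields are
voxel-unit, pull-convention (`warped(p) = image(p + D(p))`), channel order
(dx, dy, dz).

The forward projector is an exact Siddon ray/voxel traversal (numba), so
the analytic chord-length oracle through a uniform cylinder is tight to
voxel discretization.  FDK follows the classic flat-panel formulation:
detector coordinates rescaled to the virtual detector through the
isocenter, cosine pre-weighting SID/√(SID²+a²+b²), row-wise ramp
filtering, voxel-driven backprojection with the SID²/U² distance weight
and bilinear detector interpolation, scaled by Δθ/2 for the 360° orbit.
Numerical choices in the ramp stage: rows are padded to ≥2× length
(power of two) with **edge replication** — zero padding would add a step
response at truncated rows, and edge extension both suppresses circular
convolution and annihilates constant rows exactly; the frequency response
is |ω| sampled on the padded grid (Hann apodization optional); the DC bin
is identically zero.  No Parker weighting (full 360° arcs only) and no
half-fan support: the displaced-detector geometry is out of scope and is
rejected at construction.

## Breathing phantom (synthetic data)

The phantom is a set of analytic shapes — body and lung ellipsoids,
tumor sphere, diaphragm dome spheres, vessel cylinders, rib-like shell
bands — with attenuations lung 0.005 < body 0.020 < bone 0.040 mm⁻¹ and
tumor 0.026 mm⁻¹.  Soft tissue and lung parenchyma carry a smooth
multiplicative heterogeneity texture (8% amplitude, 29–43 mm wavelengths)
plus a gentle axial lung density gradient: real thorax CT is textured
everywhere, and windowed-correlation similarity degenerates on perfectly
flat tissue (see "Similarity" below).  The texture is a function of the
*reference* (material) coordinates, so it moves with the tissue and every
analytic ground-truth quantity remains exact.

Breathing is a one-parameter Lagrangian displacement
`x(φ) = x_ref + a(φ)·A·u(x_ref)` with `a(φ) = sin²(πφ)` (end-exhale at
φ=0, peak inhale at φ=0.5) and a weight field `u` directed along
(0, 0.2, −1)/‖·‖ — the diaphragm displaces inferiorly at inhale with a
20% anterior–posterior chest-wall component — with cosine falloff from
the diaphragm apex to the lung apex, a smooth falloff toward the body
surface (keeping the Eulerian inverse a contraction), and zero outside
the body.  Default amplitude A = 10 mm (8 mm in the study runs), period
4 s.  Phase volumes are rasterized by solving the inverse motion with a
fixed-point iteration (tolerance 1e−3 mm) and evaluating the analytic
shapes at the material preimage, optionally supersampled 2× per axis for
partial-volume edges.  Ground-truth displacement fields, paired lung
landmarks and breathing traces come from the same analytic motion, so
every downstream stage has an exact oracle.

Scan simulation freezes the phantom at the trace's motion phase,
quantized to 20 distinct states (bounding the number of rasterizations;
the quantization step of 0.05 cycle is below the phase-binning
resolution), and converts line integrals to noisy transmission with
photon count I₀ (Poisson, Gaussian approximation above 1000 counts;
I₀ = ∞ noiseless).

What the generator does **not** emulate: scatter, beam hardening, bowtie
filtration, detector lag, anatomic complexity (airway trees, cardiac
motion), cycle-to-cycle breathing irregularity (amplitude jitter only),
and half-fan acquisitions.  Passing tests therefore demonstrate the
pipeline's correctness and its behavior under idealized physics, not
clinical image quality.

## Respiratory surrogate and binning

The shroud image collapses each projection along the lateral detector
axis; the surrogate is the axial intensity-weighted centroid of the
column.  On a single rotation the angle-dependent anatomy baseline and
the breathing signal are separable only by frequency, so the centroid is
band-passed to the physiological breathing band (11–22 cycles/min) and
linearly detrended; a low-confidence flag is raised when out-of-band
variation dominates (e.g. no motion).  Breathing slower than ~11 or
faster than ~22 cycles/min would be attenuated — a stated design limit.
A gradient-edge-tracking variant was evaluated and rejected: with no
single dominant edge it correlated below 0.4 with the ground-truth trace,
against 0.99 for the mass centroid.

Phase binning detects end-inhale peaks (prominence ≥10% of range,
separation ≥ half the median period), assigns phase fractions linearly in
time between consecutive peaks (peaks ↦ fraction 0), and labels
`floor(fraction·N)`.  Bins partition the projections by construction.

## Artifact reduction

Pseudo-average bins are built by a deterministic round-robin rule:
pseudo-bin b takes, from cycle c, the projections with phase label
(b + c) mod N, so each pseudo bin mixes all phases whenever ≥2 cycles
exist while matching the per-bin projection counts of real phase bins.
Training pairs are (FDK of pseudo-bin, FDK of all projections), both
normalized with the target's affine parameters (0.5/99.5 percentile clip
to [0, 1]).  The denoiser is a 3-level residual 3D U-Net (base 8
channels at reduced scale, instance norm, leaky slope 0.2,
zero-initialized head so the untrained network is the identity), trained
with mean absolute error, Adam 1e−3, whole volumes, per-scan
(self-contained).  Defaults: 20–25 epochs at reduced scale.

## Groupwise registration

The network consumes the N phase images as channels and emits 3N
displacement channels.  Encoder: a stem block and four residual blocks;
decoder: three residual blocks with skip connections; kernel 3, instance
norm, leaky rectifier 0.2, widths (16, 32, 64, 96).  All convolutions run
at 1/4 to 1/16 of the input resolution and the zero-initialized head's
output is trilinearly upsampled to the input grid: respiratory
displacement fields vary over decimetre scales, so coarse prediction
costs no measurable accuracy (lung endpoint error 0.05 voxel in the
study) while keeping CPU training fast.  The identity transform is the
exact starting point.

**Loss.**  The similarity is the mean (over phases) negative LNCC between
each warped image and the implicit template, where the per-voxel LNCC
term is the squared correlation over a 5³ box window (box sums via
separable filters, replicate borders).  Three scaling decisions matter:

* *Normalization.*  The similarity is averaged over the voxel count by
  default.  With the raw sum, similarity gains grow with |Ω| while the
  regularizers are normalized means, so λ₁ = 1, λ₂ = 1e−5, λ₃ = 5e−2 and
  the 1e−5 convergence tolerance are dimensionally incoherent: in
  practice the zero-average constraint becomes a no-op, a
  similarity-neutral *common-deformation gauge mode* grows unchecked
  (observed: ~15-voxel fields, non-invertible motion models), and the
  convergence rule can never fire against an O(|Ω|) loss in float32.
  Under the mean form the published weights are meaningful and the
  optimization converges by the stated rule.  The literal summed form
  remains available (`normalized_lncc=False`) and is what the closed-form
  oracles test (similarity at identity = −|Ω|).
* *Denominator guard.*  ε = 1e−8.  At 1e−5 the squared window variance of
  low-intensity lung tissue (~4e−6 on normalized images) is below ε, LNCC
  saturates there, and the optimizer exploits the dead zone by
  manufacturing interpolation texture with large deformations.
* *Foreground mask.*  By default the per-voxel terms are restricted to a
  window-dilated foreground (any phase > 0.02 normalized intensity).
  Featureless air contributes no correlation information but offers the
  same degenerate "texture harvesting" optimum; masking removes it.  A
  no-mask mode is available.

The spatial regularizer sums squared twice-applied forward differences
per axis (stencils crossing the border dropped), normalized by 3N|Ω|; the
temporal diffusion penalizes forward differences along the phase index
with cyclic wrap (respiration is periodic; non-cyclic available); the
zero-average constraint is λ₃·√(mean per-voxel ‖Σ_n D‖²/3).  Optimizer:
Adam, learning rate 1e−3, batch 1; one-shot stops when
|loss − mean(previous 20)| < 1e−5 or at `max_iter` (3000 default; the
study runs cap at 400 and converge in 50–100 iterations); population
training runs a fixed 200 epochs over the collection.

**Motion model.**  Field inversion uses the fixed-point iteration
`D⁻¹(p) ← −D(p + D⁻¹(p))` (stop at max update < 0.01 voxel or 50
iterations; an error is raised if updates above 0.5 voxel fail to
contract for five consecutive iterations — sub-voxel plateaus return the
best iterate).  Composition is `D_c(p) = D_b(p) + D_a(p + D_b(p))` with
trilinear sampling, and every ordered phase pair gets
`D_i^j = compose(D_tem^j, invert(D_tem^i))`, diagonal identically zero.

## MoCo reconstruction

Warped backprojection deforms the grid, not the projections: for a
projection in phase bin j backprojected into target phase i, each voxel
p is displaced to p + D_i^j(p) (converted to mm) before computing
detector coordinates and the FDK distance weight.  Displacements are
sampled at voxel centres and no Jacobian intensity correction is applied
— a known approximation of this formulation.  With the identity motion
model the computation reduces *bit-for-bit* to the all-projection FDK.
The per-bin displaced coordinate grids are cached, so the cost is one
full FDK per target phase.

## Evaluation

Reconstructed CBCT intensities are only calibrated up to an affine map,
so image metrics are structure-oriented: RMSE and PSNR after aligning the
reconstruction's ROI mean to the ground truth (PSNR peak = ground-truth
maximum within the mask; exact matches report +inf), and SSIM after a
coarse-to-fine multiplicative search for the scale maximizing the masked
SSIM (101-point grid on [0.2, 5], one refinement; Gaussian-weighted 3D
windows on the ground-truth dynamic range).  TRE is the mean Euclidean
distance between paired landmarks in mm, with the estimated field
trilinearly interpolated at the fixed points (pull convention).
DIR-Lab-style landmark files (whitespace "x y z" per line, 1-based voxel
indices, spacing sidecar) are read and written losslessly; per-case voxel
spacings are user-supplied.  The reported reference table of
before-registration landmark displacements for DIR-Lab test cases 4–10
(means 9.83–14.99 mm, aggregate 9.92 mm) ships as data for validating TRE
pipelines against the public dataset, which must be obtained separately.

## Study conditions and problem sizes

The reduced-scale study uses a 64×64×48 grid at 4 mm (full-scale
224×224×96 at 2 mm available via config), a 96×72 detector at 4.5 mm,
180 projections over 360°, a 60 s trace at 4 s period (15 cycles), N = 4
phases, amplitude 8 mm, noiseless projections for the oracle runs.  The
population study trains on five phantom-family variants (jittered
anatomy, amplitudes 6–12 mm) at 24×32×32 / 8 mm and predicts a sixth
unseen subject single-pass.  The artifact-reduction stage trains 20–25
epochs on the four pseudo-average pairs.

## Known limitations

* Full-fan circular orbits only; no truncation or displaced-detector
  handling beyond edge-extended ramp filtering.
* The LNCC foreground mask assumes air is the lowest-intensity class of
  the normalized image.
* Breathing-band filtering assumes respiratory rates of 11–22
  cycles/min and roughly one gantry rotation per acquisition.
* The inverse-motion fixed point requires displacement gradients below
  one (amply satisfied by the breathing model's smooth weight field).
* Registration accuracy is reported against the same analytic motion
  family that generated the data; transfer to irregular breathing or
  sliding-motion anatomy is untested by design.
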