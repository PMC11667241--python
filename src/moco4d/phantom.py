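"""Deformable digital thorax phantom with analytic ground truth.

The phantom is a set of analytic shapes (body/lung ellipsoids, a tumor
sphere, diaphragm domes, vessel cylinders and rib-like shell bands) whose
attenuation can be evaluated exactly at arbitrary world points.  Breathing
is modelled as a Lagrangian displacement of material points,

    x(phi) = x_ref + a(phi) * A * u(x_ref),

with a(phi) = sin^2(pi * phi) (zero at end-exhale, peak inhale at phi=0.5)
and a spatially varying unit-capped weight field u dominated by the
superior-inferior direction.  Because motion and shapes are analytic, the
module can emit exact phase volumes, inter-phase displacement fields and
paired landmarks for oracle-grade testing of every downstream stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import ConeBeamGeometry, GridSpec, Volume, desk_grid
from .projections import ProjectionSet, forward_project
from .respiratory import RespiratorySignal

__all__ = [
    "Ellipsoid",
    "Sphere",
    "Cylinder",
    "PhantomSpec",
    "BreathingModel",
    "default_phantom",
    "default_breathing",
    "rasterize_phantom",
    "ground_truth_dvf",
    "phantom_landmarks",
    "breathing_trace",
    "simulate_scan",
]


# ---------------------------------------------------------------------
# Shapes
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class Ellipsoid:
    center: tuple
    semi_axes: tuple
    mu: float

    def inside(self, x, y, z):
        cx, cy, cz = self.center
        ax, ay, az = self.semi_axes
        return (((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2
                + ((z - cz) / az) ** 2) <= 1.0


@dataclass(frozen=True)
class Sphere:
    center: tuple
    radius: float
    mu: float

    def inside(self, x, y, z):
        cx, cy, cz = self.center
        return ((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2) <= self.radius**2


@dataclass(frozen=True)
class Cylinder:
    """Finite cylinder: point, unit axis, radius, half-length."""

    point: tuple
    axis: tuple
    radius: float
    half_length: float
    mu: float

    def inside(self, x, y, z):
        px, py, pz = self.point
        a = np.asarray(self.axis, dtype=float)
        a = a / np.linalg.norm(a)
        rx, ry, rz = x - px, y - py, z - pz
        t = rx * a[0] + ry * a[1] + rz * a[2]
        d2 = (rx - t * a[0]) ** 2 + (ry - t * a[1]) ** 2 + (rz - t * a[2]) ** 2
        return (d2 <= self.radius**2) & (np.abs(t) <= self.half_length)


@dataclass(frozen=True)
class PhantomSpec:
    """Analytic thorax phantom description.

    Attenuations are in mm^-1; geometry in mm.  ``diaphragm_domes`` are
    soft-tissue spheres intersected with the lungs; ``rib_*`` parameters
    carve high-attenuation bands from an ellipsoidal shell of the body.
    ``lung_gradient`` adds a gentle linear axial attenuation gradient inside
    the lungs (gravity-dependent density).  ``texture_amplitude`` modulates
    soft tissue and lung parenchyma with a smooth multiplicative
    heterogeneity pattern (wavelengths in mm): real thorax CT is textured
    everywhere, and windowed-correlation metrics degenerate on perfectly
    flat synthetic tissue.  The texture is attached to material points, so
    it moves with the breathing deformation like every other feature.
    """

    body: Ellipsoid
    lungs: tuple
    tumor: Sphere
    diaphragm_domes: tuple
    vessels: tuple
    rib_shell_scales: tuple = (0.90, 1.0)
    rib_band_period_mm: float = 32.0
    rib_band_fill: float = 0.45
    rib_mu: float = 0.04
    lung_gradient: float = 0.25
    texture_amplitude: float = 0.08
    texture_wavelengths_mm: tuple = (37.0, 43.0, 29.0)

    def __post_init__(self):
        mus = [self.body.mu, self.tumor.mu, self.rib_mu]
        mus += [l.mu for l in self.lungs] + [v.mu for v in self.vessels]
        mus += [d.mu for d in self.diaphragm_domes]
        if any(m < 0 for m in mus):
            raise ValueError("attenuations must be non-negative")
        lung_mu = max((l.mu for l in self.lungs), default=0.0)
        if (self.lungs and self.body.mu > 0
                and not (lung_mu < self.body.mu < self.rib_mu)):
            raise ValueError("require lung mu < body mu < bone mu")

    # -- analytic attenuation ------------------------------------------
    def attenuation(self, x, y, z):
        """Attenuation (mm^-1) of the *reference* phantom at world points."""
        x = np.asarray(x, dtype=float)
        mu = np.zeros(np.broadcast(x, y, z).shape, dtype=float)
        in_body = self.body.inside(x, y, z)
        texture = 1.0
        if self.texture_amplitude > 0:
            lx, ly, lz = self.texture_wavelengths_mm
            texture = 1.0 + self.texture_amplitude * (
                np.sin(2 * np.pi * np.asarray(x) / lx)
                * np.sin(2 * np.pi * np.asarray(y) / ly)
                * np.sin(2 * np.pi * np.asarray(z) / lz)
            )
            texture = np.broadcast_to(texture, mu.shape)
        mu[in_body] = self.body.mu
        if self.texture_amplitude > 0:
            mu[in_body] *= texture[in_body]

        in_any_lung = np.zeros_like(in_body)
        for lung in self.lungs:
            in_lung = lung.inside(x, y, z) & in_body
            in_any_lung |= in_lung
            if not np.any(in_lung):
                continue
            cz = lung.center[2]
            az = lung.semi_axes[2]
            zl = np.asarray(np.broadcast_to(z, mu.shape))[in_lung]
            grad = 1.0 + self.lung_gradient * (cz - zl) / az
            mu[in_lung] = lung.mu * np.clip(grad, 0.5, 1.5)
            if self.texture_amplitude > 0:
                mu[in_lung] *= texture[in_lung]

        for dome in self.diaphragm_domes:
            sel = dome.inside(x, y, z) & in_any_lung
            mu[sel] = dome.mu
        for vessel in self.vessels:
            sel = vessel.inside(x, y, z) & in_any_lung
            mu[sel] = vessel.mu
        sel = self.tumor.inside(x, y, z) & in_body
        mu[sel] = self.tumor.mu

        # rib bands: between two scaled body shells, alternating z-bands
        s_in, s_out = self.rib_shell_scales
        cx, cy, cz = self.body.center
        ax, ay, az = self.body.semi_axes
        rho2 = (((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2
                + ((z - cz) / az) ** 2)
        shell = (rho2 >= s_in**2) & (rho2 <= s_out**2) & ~in_any_lung
        zb = np.broadcast_to(z, mu.shape)
        band = ((zb - cz) / self.rib_band_period_mm) % 1.0 < self.rib_band_fill
        mu[shell & band] = self.rib_mu
        return mu

    def lung_mask_points(self, x, y, z):
        in_body = self.body.inside(x, y, z)
        m = np.zeros_like(in_body)
        for lung in self.lungs:
            m |= lung.inside(x, y, z)
        return m & in_body


@dataclass(frozen=True)
class BreathingModel:
    """One-parameter breathing surrogate with analytic weight field.

    amplitude_mm: peak superior-inferior diaphragm excursion A.
    a(phi) = sin^2(pi*phi): periodic, a(0)=a(1)=0 (end-exhale), max 1.
    The weight field u(p) points along (0, 0.2, -1)/|(0, 0.2, -1)| — the
    diaphragm displaces inferiorly at peak inhale, with a 20%
    anterior-posterior chest-wall component — scaled by a cosine falloff
    from the diaphragm apex (weight 1) to the lung apex (weight 0), a
    falloff toward the body surface, and zero outside the body.
    """

    amplitude_mm: float = 10.0
    period_s: float = 4.0
    diaphragm_apex_z: float = -55.0
    lung_apex_z: float = 70.0
    body: Ellipsoid = None
    ap_fraction: float = 0.2

    def a(self, phase_fraction):
        return np.sin(np.pi * np.asarray(phase_fraction, dtype=float)) ** 2

    def direction(self):
        d = np.array([0.0, self.ap_fraction, -1.0])
        return d / np.linalg.norm(d)

    def weight(self, x, y, z):
        """Scalar weight ||u|| at world points (1 at diaphragm apex)."""
        zd, za = self.diaphragm_apex_z, self.lung_apex_z
        t = np.clip((np.asarray(z, dtype=float) - zd) / (za - zd), 0.0, 1.0)
        w = np.cos(0.5 * np.pi * t)
        if self.body is not None:
            # smooth falloff in 3D body-normalized radius; continuous at the
            # body surface (and zero beyond), so the Eulerian inverse motion
            # remains a contraction
            cx, cy, cz = self.body.center
            ax, ay, az = self.body.semi_axes
            rho = np.sqrt(((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2
                          + ((z - cz) / az) ** 2)
            falloff = np.cos(0.5 * np.pi * np.clip((rho - 0.55) / 0.45, 0.0, 1.0))
            w = np.where(rho >= 1.0, 0.0, w * falloff)
        return w

    def u(self, x, y, z):
        """Vector weight field u(p), shape (..., 3)."""
        w = self.weight(x, y, z)
        return w[..., None] * self.direction()

    def displacement(self, points, phase_fraction):
        """Lagrangian displacement (mm) of reference points at a phase."""
        pts = np.asarray(points, dtype=float)
        s = float(self.a(phase_fraction)) * self.amplitude_mm
        return s * self.u(pts[..., 0], pts[..., 1], pts[..., 2])


def default_phantom() -> PhantomSpec:
    """Reduced-scale thorax phantom fitting a 256 x 256 x 192 mm FOV."""
    body = Ellipsoid((0.0, 0.0, 0.0), (115.0, 92.0, 92.0), 0.020)
    lungs = (
        Ellipsoid((-52.0, 0.0, 8.0), (42.0, 58.0, 66.0), 0.005),
        Ellipsoid((52.0, 0.0, 8.0), (42.0, 58.0, 66.0), 0.005),
    )
    tumor = Sphere((52.0, 12.0, -2.0), 12.0, 0.026)
    domes = (
        Sphere((-52.0, 0.0, -92.0), 48.0, 0.020),
        Sphere((52.0, 0.0, -92.0), 48.0, 0.020),
    )
    vessels = (
        Cylinder((-52.0, 8.0, 10.0), (0.2, 0.1, 1.0), 5.0, 48.0, 0.018),
        Cylinder((-46.0, -18.0, -8.0), (1.0, 0.4, 0.6), 4.0, 30.0, 0.018),
        Cylinder((52.0, -10.0, 16.0), (-0.15, 0.2, 1.0), 5.0, 46.0, 0.018),
        Cylinder((40.0, 16.0, 24.0), (1.0, -0.3, 0.5), 4.0, 28.0, 0.018),
    )
    return PhantomSpec(body=body, lungs=lungs, tumor=tumor,
                       diaphragm_domes=domes, vessels=vessels)


def phantom_family(n_subjects: int, seed: int = 0,
                   amplitude_range=(6.0, 12.0)):
    """Deterministic family of anatomy/breathing variants.

    Each subject jitters body and lung size, tumor position and radius,
    and breathing amplitude — the inter-patient variability a population
    registration model must generalize across.  Returns a list of
    (PhantomSpec, BreathingModel) pairs.
    """
    rng = np.random.default_rng(seed)
    subjects = []
    for _ in range(n_subjects):
        body_scale = rng.uniform(0.93, 1.0)
        lung_scale = rng.uniform(0.88, 1.05)
        body = Ellipsoid((0.0, 0.0, 0.0),
                         tuple(a * body_scale for a in (115.0, 92.0, 92.0)),
                         0.020)
        lungs = tuple(
            Ellipsoid((sx * 52.0 * body_scale, rng.uniform(-4, 4),
                       8.0 + rng.uniform(-6, 6)),
                      tuple(a * lung_scale for a in (42.0, 58.0, 66.0)),
                      0.005)
            for sx in (-1.0, 1.0)
        )
        right = lungs[1]
        tumor = Sphere(
            (right.center[0] + rng.uniform(-8, 8),
             right.center[1] + rng.uniform(-8, 8),
             right.center[2] + rng.uniform(-20, 0)),
            rng.uniform(9.0, 14.0), 0.026,
        )
        domes = tuple(
            Sphere((lung.center[0], lung.center[1], -92.0 * body_scale),
                   48.0, 0.020)
            for lung in lungs
        )
        vessels = tuple(
            Cylinder((lung.center[0] + rng.uniform(-10, 10),
                      lung.center[1] + rng.uniform(-14, 14),
                      lung.center[2] + rng.uniform(-8, 14)),
                     (rng.uniform(-0.3, 0.3), rng.uniform(-0.3, 0.3), 1.0),
                     rng.uniform(3.5, 5.5), 45.0, 0.018)
            for lung in lungs for _ in range(2)
        )
        spec = PhantomSpec(body=body, lungs=lungs, tumor=tumor,
                           diaphragm_domes=domes, vessels=vessels)
        breathing = default_breathing(
            amplitude_mm=rng.uniform(*amplitude_range),
            period_s=rng.uniform(3.2, 4.8), spec=spec,
        )
        subjects.append((spec, breathing))
    return subjects


def default_breathing(amplitude_mm=10.0, period_s=4.0,
                      spec: PhantomSpec = None) -> BreathingModel:
    spec = spec or default_phantom()
    if spec.lungs:
        lung_apex = spec.lungs[0].center[2] + spec.lungs[0].semi_axes[2]
    else:
        lung_apex = spec.body.center[2] + 0.8 * spec.body.semi_axes[2]
    return BreathingModel(
        amplitude_mm=amplitude_mm,
        period_s=period_s,
        diaphragm_apex_z=-50.0,
        lung_apex_z=lung_apex,
        body=spec.body,
    )


# ---------------------------------------------------------------------
# Eulerian rasterization via fixed-point inversion of the motion
# ---------------------------------------------------------------------

def _inverse_motion(breathing: BreathingModel, points, phase_fraction,
                    tol=1e-3, max_iter=40):
    """Solve x + a(phi) A u(x) = p for reference points x (fixed point)."""
    p = np.asarray(points, dtype=float)
    s = float(breathing.a(phase_fraction)) * breathing.amplitude_mm
    if s == 0.0:
        return p.copy(), 0.0
    x = p.copy()
    for _ in range(max_iter):
        disp = s * breathing.u(x[..., 0], x[..., 1], x[..., 2])
        x_new = p - disp
        delta = np.max(np.abs(x_new - x))
        x = x_new
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"fixed-point inversion did not converge: worst residual {delta:.3g} mm"
        )
    return x, delta


def rasterize_phantom(spec: PhantomSpec, breathing: BreathingModel,
                      phase_fraction: float, grid: GridSpec = None,
                      supersample: int = 1) -> Volume:
    """Voxelize the phantom at the Eulerian positions of a breathing phase.

    The voxel at world position p takes the reference attenuation at the
    material preimage x solving x + a(phi) A u(x) = p.  ``supersample``
    averages sub-voxel evaluations per axis for smoother partial-volume
    edges.
    """
    if not (0.0 <= phase_fraction < 1.0):
        raise ValueError("phase_fraction must lie in [0, 1)")
    grid = grid or desk_grid()
    _warn_if_clipped(spec, grid)
    xx, yy, zz = grid.world_coordinates()
    sx, sy, sz = grid.spacing
    acc = np.zeros(grid.shape, dtype=float)
    n = max(1, int(supersample))
    offsets = (np.arange(n) + 0.5) / n - 0.5
    for oz in offsets:
        for oy in offsets:
            for ox in offsets:
                pts = np.stack(
                    [xx + ox * sx, yy + oy * sy, zz + oz * sz], axis=-1
                )
                ref, _ = _inverse_motion(breathing, pts, phase_fraction)
                acc += spec.attenuation(ref[..., 0], ref[..., 1], ref[..., 2])
    return Volume(acc / n**3, grid, kind="attenuation")


def ground_truth_dvf(spec: PhantomSpec, breathing: BreathingModel,
                     phase_i: float, phase_j: float,
                     grid: GridSpec = None) -> np.ndarray:
    """Analytic pull-convention displacement field of phase j on the phase-i grid.

    For voxel p of the phase-i volume the returned d satisfies: the material
    point sitting at p during phase i sits at p + d during phase j.  Shape
    (3, nz, ny, nx), channels (dx, dy, dz) in voxel units.
    """
    for ph in (phase_i, phase_j):
        if not (0.0 <= ph < 1.0):
            raise ValueError("phases must lie in [0, 1)")
    grid = grid or desk_grid()
    xx, yy, zz = grid.world_coordinates()
    pts = np.stack([xx, yy, zz], axis=-1)
    if phase_i == phase_j:
        return np.zeros((3,) + tuple(grid.shape))
    ref, _ = _inverse_motion(breathing, pts, phase_i)
    pos_j = ref + breathing.displacement(ref, phase_j)
    d_world = pos_j - pts
    sx, sy, sz = grid.spacing
    return np.stack(
        [d_world[..., 0] / sx, d_world[..., 1] / sy, d_world[..., 2] / sz], axis=0
    )


def phantom_landmarks(spec: PhantomSpec, breathing: BreathingModel,
                      n_points: int, phase_i: float, phase_j: float,
                      grid: GridSpec = None, seed: int = 0):
    """Paired lung landmarks related by the Lagrangian breathing motion.

    Returns two (n_points, 3) arrays of fractional 0-based voxel indices
    (ix, iy, iz) on ``grid`` — positions of the same material points at the
    two phases.
    """
    grid = grid or desk_grid()
    rng = np.random.default_rng(seed)
    if n_points == 0:
        return np.zeros((0, 3)), np.zeros((0, 3))
    xx, yy, zz = grid.world_coordinates()
    if not np.any(spec.lung_mask_points(xx, yy, zz)):
        raise ValueError("grid contains no lung voxels")
    lo = grid.voxel_to_world(np.zeros(3))
    hi = grid.voxel_to_world(np.asarray(grid.shape)[::-1] - 1.0)
    pts = np.empty((0, 3))
    while len(pts) < n_points:
        cand = rng.uniform(lo, hi, size=(4 * n_points, 3))
        ok = spec.lung_mask_points(cand[:, 0], cand[:, 1], cand[:, 2])
        pts = np.vstack([pts, cand[ok]])
    ref = pts[:n_points]
    pos_i = ref + breathing.displacement(ref, phase_i)
    pos_j = ref + breathing.displacement(ref, phase_j)
    return grid.world_to_voxel(pos_i), grid.world_to_voxel(pos_j)


def breathing_trace(duration_s: float, period_s: float,
                    sample_rate_hz: float = 25.0, noise_sd: float = 0.0,
                    seed: int = 0) -> RespiratorySignal:
    """Sinusoid-like breathing surrogate with ground-truth phase attached.

    Amplitude is a(t/T) = sin^2(pi t / T) plus optional Gaussian jitter.
    The attached phase fraction uses the end-inhale-anchored convention.
    """
    if duration_s <= 0 or period_s <= 0 or sample_rate_hz <= 0:
        raise ValueError("duration, period and sample rate must be positive")
    n = int(round(duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    per_cycle = period_s * sample_rate_hz
    if abs(per_cycle - round(per_cycle)) < 1e-9:
        # integral samples per cycle: tile one cycle so the noiseless trace
        # is exactly periodic
        m = int(round(per_cycle))
        cycle_phase = np.arange(m) / m
        reps = n // m + 1
        motion_phase = np.tile(cycle_phase, reps)[:n]
    else:
        motion_phase = (t / period_s) % 1.0
    amp = np.sin(np.pi * motion_phase) ** 2
    if noise_sd > 0:
        amp = amp + np.random.default_rng(seed).normal(0.0, noise_sd, size=n)
    return RespiratorySignal(
        times=t, amplitude=amp, phase_fraction=(motion_phase - 0.5) % 1.0
    )


def simulate_scan(spec: PhantomSpec, breathing: BreathingModel,
                  trace: RespiratorySignal, geometry: ConeBeamGeometry,
                  n_projections: int = 180, photons_i0: float = np.inf,
                  seed: int = 0, grid: GridSpec = None,
                  n_motion_states: int = 20,
                  supersample: int = 1) -> ProjectionSet:
    """Simulate a circular full-fan scan of the breathing phantom.

    Projection k is acquired at an evenly spaced angle over 360 degrees and
    a timestamp spanning the trace; its line integrals traverse the phantom
    frozen at the trace's motion phase, quantized to ``n_motion_states``
    distinct states to bound the number of rasterizations.  Transmission
    noise draws photon counts around I0 * exp(-g) (Poisson; Gaussian
    approximation above 1000 counts), with ``photons_i0=inf`` noiseless.
    """
    if n_projections < 1:
        raise ValueError("need at least one projection")
    if not np.isinf(photons_i0) and photons_i0 <= 0:
        raise ValueError("photons_i0 must be positive (or inf for noiseless)")
    grid = grid or desk_grid()
    angles = 2 * np.pi * np.arange(n_projections) / n_projections
    duration = trace.times[-1] - trace.times[0]
    times = trace.times[0] + duration * np.arange(n_projections) / n_projections
    idx = np.searchsorted(trace.times, times).clip(0, len(trace.times) - 1)
    motion = trace.motion_phase()[idx]
    m = max(1, int(n_motion_states))
    states = (np.round(motion * m) % m).astype(int)
    data = np.empty((n_projections, geometry.n_v, geometry.n_u))
    for state in np.unique(states):
        vol = rasterize_phantom(
            spec, breathing, state / m, grid, supersample=supersample
        )
        sel = states == state
        data[sel] = forward_project(vol, geometry, angles[sel])
    if not np.isinf(photons_i0):
        rng = np.random.default_rng(seed)
        lam = photons_i0 * np.exp(-data)
        counts = np.where(
            lam > 1000.0,
            rng.normal(lam, np.sqrt(lam)),
            rng.poisson(np.minimum(lam, 1e9)).astype(float),
        )
        counts = np.maximum(counts, 0.5)
        data = -np.log(counts / photons_i0)
    geo = geometry.with_angles(angles)
    return ProjectionSet(data=data, angles=angles, timestamps=times, geometry=geo)


def _warn_if_clipped(spec: PhantomSpec, grid: GridSpec):
    lo = np.asarray(grid.voxel_to_world(np.zeros(3)))
    hi = np.asarray(grid.voxel_to_world(np.asarray(grid.shape)[::-1] - 1.0))
    c = np.asarray(spec.body.center)
    a = np.asarray(spec.body.semi_axes)
    if np.any(c - a < lo - 1e-9) or np.any(c + a > hi + 1e-9):
        warnings.warn("phantom body extends outside the grid; it will be clipped",
                      stacklevel=3)
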