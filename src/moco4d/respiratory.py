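"""Respiratory surrogate signals, Amsterdam-Shroud extraction, phase binning.

Phase convention: phase fraction 0 is anchored at end-inhale (the maxima of
the surrogate amplitude).  The breathing *motion* phase used by the phantom
(zero displacement at end-exhale) is offset by half a cycle; helpers convert
between the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "RespiratorySignal",
    "PhaseBinning",
    "extract_respiratory_signal",
    "phase_bin",
    "bin_motion_phase",
]


@dataclass
class RespiratorySignal:
    """1D breathing surrogate sampled at known times.

    ``phase_fraction`` (optional) is the ground-truth phase in [0, 1) using
    the end-inhale-anchored convention.  ``low_confidence`` flags signals
    extracted from projections without a detectable moving edge.
    """

    times: np.ndarray
    amplitude: np.ndarray
    phase_fraction: np.ndarray = None
    low_confidence: bool = False

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.amplitude.shape:
            raise ValueError("times and amplitude must be equal-length 1D arrays")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.amplitude))):
            raise ValueError("signal values must be finite")
        if self.phase_fraction is not None:
            self.phase_fraction = np.asarray(self.phase_fraction, dtype=float)

    def motion_phase(self):
        """Ground-truth breathing-motion phase (0 = end-exhale)."""
        if self.phase_fraction is None:
            raise ValueError("signal carries no ground-truth phase")
        return (self.phase_fraction + 0.5) % 1.0


@dataclass
class PhaseBinning:
    """Assignment of each projection to a respiratory bin.

    kind is "phase" for standard respiratory-phase bins, "pseudo-average"
    for artifact-reduction training bins, or "all".  ``cycle_index`` tags
    each projection with its breathing-cycle number; ``provenance`` (for
    pseudo-average bins) maps bin -> list of (cycle, source phase) pairs.
    """

    n_bins: int
    fractions: np.ndarray
    labels: np.ndarray
    kind: str = "phase"
    cycle_index: np.ndarray = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != self.fractions.shape:
            raise ValueError("labels and fractions must align")
        if self.labels.min(initial=0) < 0 or (
            len(self.labels) and self.labels.max() >= self.n_bins
        ):
            raise ValueError("labels out of range")

    def members(self, b):
        return np.flatnonzero(self.labels == b)

    def bin_sizes(self):
        return np.bincount(self.labels, minlength=self.n_bins)


def bin_motion_phase(b, n_bins):
    """Representative breathing-motion phase of bin ``b``.

    The bin centre in the end-inhale-anchored fraction is (b + 0.5)/N; the
    motion phase adds the half-cycle offset between the two conventions.
    """
    return ((b + 0.5) / n_bins + 0.5) % 1.0


def extract_respiratory_signal(projections) -> RespiratorySignal:
    """Amsterdam-Shroud breathing surrogate from a projection stack.

    Each projection is collapsed along the lateral detector axis (u) into a
    1D column; the columns are stacked over time into the shroud image.
    The per-projection surrogate is the intensity-weighted centroid of the
    column along the axial (v) axis, linearly detrended.  As the diaphragm
    descends during inhalation the lung expands downward and the
    attenuation-mass centroid shifts, tracking the breathing cycle
    robustly even when no single edge dominates.  Note the raw surrogate
    sign is anatomy-dependent; downstream phase binning anchors phase 0 at
    the detected signal maxima.
    """
    data = np.asarray(projections.data, dtype=float)
    if data.shape[0] < 2:
        raise ValueError("need at least two projections")
    shroud = data.sum(axis=2)  # (n_proj, n_v)
    weight = np.clip(shroud, 0.0, None)
    weight_sum = weight.sum(axis=1)
    low_confidence = False
    v_idx = np.arange(weight.shape[1], dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        centroid = (weight * v_idx).sum(axis=1) / weight_sum
    if np.any(weight_sum <= 0):
        low_confidence = True
        centroid = np.where(weight_sum > 0, centroid, 0.0)
    times = np.asarray(projections.timestamps, dtype=float)
    # The raw centroid mixes breathing with an anatomy baseline that varies
    # with gantry angle across all harmonics; on a single rotation the two
    # are only separable by frequency.  Keep the physiological breathing
    # band (11-22 cycles/min — normal respiratory rates) and linearly
    # detrend; slower or faster "breathing" is outside the design range.
    amplitude = _bandpass(centroid, times, lo_cpm=11.0, hi_cpm=22.0)
    removed = centroid - centroid.mean() - amplitude
    if amplitude.std() < max(removed.std(), 1e-9):
        # out-of-band (anatomy) variation dominates: no breathing detected
        low_confidence = True
    return RespiratorySignal(times, amplitude, low_confidence=low_confidence)


def _bandpass(signal, times, lo_cpm, hi_cpm):
    """Band-pass via FFT masking (uniform sampling) or harmonic regression."""
    n = len(signal)
    dt = np.diff(times)
    sig = signal - signal.mean()
    if n > 4 and np.allclose(dt, dt[0], rtol=1e-6):
        freqs = np.fft.rfftfreq(n, d=dt[0]) * 60.0  # cycles per minute
        spec = np.fft.rfft(sig)
        spec[(freqs < lo_cpm) | (freqs > hi_cpm)] = 0.0
        return np.fft.irfft(spec, n=n)
    # non-uniform sampling: project out the out-of-band harmonics of the
    # scan duration instead
    duration = times[-1] - times[0]
    t = times - times[0]
    cols = [np.ones(n), t - t.mean()]
    k_max = n // 2
    for k in range(1, k_max + 1):
        cpm = k / duration * 60.0
        if lo_cpm <= cpm <= hi_cpm:
            continue
        cols.append(np.cos(2 * np.pi * k * t / duration))
        cols.append(np.sin(2 * np.pi * k * t / duration))
    design = np.stack(cols, axis=1)
    coef, *_ = np.linalg.lstsq(design, sig, rcond=None)
    return sig - design @ coef


def phase_bin(signal: RespiratorySignal, n_bins: int) -> PhaseBinning:
    """Sort projections into respiratory-phase bins.

    End-inhale peaks of the surrogate are detected (minimum prominence, and
    minimum separation of half the median cycle); phase advances linearly in
    time between consecutive peaks, with peaks mapped to fraction 0.  The
    bin label is floor(fraction * n_bins).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    t = signal.times
    amp = signal.amplitude
    if n_bins == 1:
        frac = np.zeros_like(t)
        return PhaseBinning(1, frac, np.zeros(len(t), dtype=int),
                            cycle_index=np.zeros(len(t), dtype=int))
    prominence = 0.1 * max(np.ptp(amp), np.finfo(float).tiny)
    peaks, _ = find_peaks(amp, prominence=prominence)
    if len(peaks) >= 2:
        median_period = np.median(np.diff(t[peaks]))
        min_dist = max(1, int(round(0.5 * median_period / np.median(np.diff(t)))))
        peaks, _ = find_peaks(amp, prominence=prominence, distance=min_dist)
    if len(peaks) < 2:
        raise ValueError("cannot establish cycles: fewer than two end-inhale peaks")
    tp = t[peaks]
    period = np.median(np.diff(tp))
    frac = np.empty_like(t)
    cycle = np.empty(len(t), dtype=int)
    # before first / after last peak: extrapolate with the neighbouring period
    for i, ti in enumerate(t):
        k = np.searchsorted(tp, ti, side="right") - 1
        if k < 0:
            frac[i] = ((ti - tp[0]) / (tp[1] - tp[0])) % 1.0
            cycle[i] = 0
        elif k >= len(tp) - 1:
            last = tp[-1] - tp[-2] if len(tp) > 1 else period
            frac[i] = ((ti - tp[-1]) / last) % 1.0
            cycle[i] = len(tp) - 1
        else:
            frac[i] = (ti - tp[k]) / (tp[k + 1] - tp[k])
            cycle[i] = k
    frac = np.clip(frac, 0.0, np.nextafter(1.0, 0.0))
    labels = np.minimum((frac * n_bins).astype(int), n_bins - 1)
    return PhaseBinning(n_bins, frac, labels, cycle_index=cycle)
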