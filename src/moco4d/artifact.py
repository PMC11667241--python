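"""Self-supervised streak-artifact reduction for phase-binned CBCT.

Phase binning leaves each bin with a sparse, regularly undersampled angular
set, so 4D FDK images carry strong streaking.  High-quality targets for
supervised training do not exist per scan — instead, *pseudo-average* bins
are built that draw projections from different respiratory phases across
different breathing cycles: their reconstructions show the same streak
statistics as a real phase bin but the time-averaged motion blur of the
all-projection reconstruction.  Pairing each pseudo-average FDK image with
the time-average FDK image yields a self-contained training set, and a
small residual 3D U-Net trained on it transfers to the real phase images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._nn import Adam, Conv3d, ConvBlock, Module
from .fdk import PhaseImageSet, fdk_reconstruct
from .geometry import Volume
from .respiratory import PhaseBinning

__all__ = [
    "IntensityNormalization",
    "normalize_intensity",
    "build_pseudo_average_bins",
    "make_training_pairs",
    "DenoiserConfig",
    "DenoiserNet",
    "ArtifactReducer",
    "ArtifactReducerResults",
    "train_artifact_reduction",
    "apply_artifact_reduction",
]


# ---------------------------------------------------------------------
# Intensity normalization
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class IntensityNormalization:
    """Affine map to [0, 1] after percentile clipping; invertible."""

    lo: float
    hi: float

    def apply(self, data):
        if self.hi <= self.lo:
            return np.zeros_like(np.asarray(data, dtype=float))
        clipped = np.clip(data, self.lo, self.hi)
        return (clipped - self.lo) / (self.hi - self.lo)

    def invert(self, data):
        return np.asarray(data) * (self.hi - self.lo) + self.lo


def normalize_intensity(volume: Volume):
    """Clip to the 0.5/99.5 percentiles and map linearly to [0, 1].

    Returns (normalized Volume, IntensityNormalization).  A constant volume
    maps to all zeros with a warning.
    """
    data = np.asarray(volume.data, dtype=float)
    if data.size == 0:
        raise ValueError("empty volume")
    lo, hi = np.percentile(data, [0.5, 99.5])
    norm = IntensityNormalization(float(lo), float(hi))
    if hi <= lo:
        warnings.warn("constant volume: normalized output is all zeros",
                      stacklevel=2)
    return volume.copy_with(norm.apply(data), kind="normalized"), norm


# ---------------------------------------------------------------------
# Pseudo-average binning
# ---------------------------------------------------------------------

def build_pseudo_average_bins(binning: PhaseBinning,
                              n_bins: int = None) -> PhaseBinning:
    """Round-robin pseudo-average bins mixing phases across cycles.

    Pseudo-bin b receives, from breathing cycle c, the projections whose
    phase label is (b + c) mod N.  This deterministic rule keeps per-bin
    projection counts and angular coverage statistically matched to the
    real phase bins while ensuring every pseudo bin mixes phases whenever
    more than one cycle exists.
    """
    if binning.cycle_index is None:
        raise ValueError("binning lacks cycle indices")
    n = binning.n_bins if n_bins is None else n_bins
    if n != binning.n_bins:
        raise ValueError("pseudo bin count must equal the phase bin count")
    cycles = np.unique(binning.cycle_index)
    if len(cycles) < 2:
        raise ValueError("cannot mix phases across cycles: single cycle")
    labels = np.empty_like(binning.labels)
    provenance = {b: [] for b in range(n)}
    for c in cycles:
        sel = binning.cycle_index == c
        # pseudo-bin b takes phase (b + c) mod n, i.e. phase p goes to
        # pseudo-bin (p - c) mod n
        labels[sel] = (binning.labels[sel] - c) % n
        for p in np.unique(binning.labels[sel]):
            provenance[int((p - c) % n)].append((int(c), int(p)))
    return PhaseBinning(
        n_bins=n, fractions=binning.fractions, labels=labels,
        kind="pseudo-average", cycle_index=binning.cycle_index,
        provenance=provenance,
    )


def make_training_pairs(projections, binning: PhaseBinning, geometry=None,
                        grid=None, window="ram-lak"):
    """(pseudo-average FDK, time-average FDK) training pairs.

    The target is the all-projection reconstruction; each pseudo bin gives
    one input.  Both are normalized with the *target's* affine parameters
    so that input and target live on one intensity scale.
    Returns (pairs, IntensityNormalization).
    """
    pseudo = build_pseudo_average_bins(binning)
    target = fdk_reconstruct(projections, geometry, grid, window=window)
    target_norm, norm = normalize_intensity(target)
    pairs = []
    for b in range(pseudo.n_bins):
        vol = fdk_reconstruct(projections, geometry, grid, binning=pseudo,
                              bin_label=b, window=window)
        pairs.append((vol.copy_with(norm.apply(vol.data), kind="normalized"),
                      target_norm))
    return pairs, norm


# ---------------------------------------------------------------------
# Residual denoising U-Net
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class DenoiserConfig:
    """Training configuration for the artifact-reduction network.

    base_channels sets the first-level width of the 3-level U-Net; the loss
    is mean absolute error; training is per-scan (self-contained) on whole
    volumes at reduced scale.
    """

    base_channels: int = 8
    epochs: int = 25
    learning_rate: float = 1e-3
    leaky_slope: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.base_channels < 1:
            raise ValueError("epochs and base_channels must be positive")


class DenoiserNet(Module):
    """3-level residual 3D U-Net: output = input + learned correction.

    The final convolution is zero-initialized, so the untrained network is
    the identity — a safe starting point for a denoiser.
    """

    DIVISOR = 4

    def __init__(self, config: DenoiserConfig):
        super().__init__()
        c = config.base_channels
        s = config.leaky_slope
        rng = np.random.default_rng(config.seed)
        self.in1 = ConvBlock(1, c, rng, s)
        self.in2 = ConvBlock(c, c, rng, s)
        self.down1 = ConvBlock(c, 2 * c, rng, s)
        self.down2 = ConvBlock(2 * c, 4 * c, rng, s)
        self.up1 = ConvBlock(4 * c + 2 * c, 2 * c, rng, s)
        self.up2 = ConvBlock(2 * c + c, c, rng, s)
        self.head = Conv3d(c, 1, rng=rng, zero_init=True)

    def __call__(self, image: np.ndarray) -> ad.Tensor:
        image = np.asarray(image, dtype=np.float32)
        z, y, x = image.shape
        pads = [(-d) % self.DIVISOR for d in (z, y, x)]
        padded = np.pad(image, [(0, p) for p in pads], mode="edge")
        t = ad.Tensor(padded[None])
        h1 = self.in2(self.in1(t))
        h2 = self.down1(ad.avg_pool2(h1))
        h3 = self.down2(ad.avg_pool2(h2))
        u1 = self.up1(ad.concat([ad.upsample2(h3), h2], axis=0))
        u2 = self.up2(ad.concat([ad.upsample2(u1), h1], axis=0))
        out = t + self.head(u2)
        return out[0, :z, :y, :x]


class ArtifactReducer:
    """Streak-artifact-reduction model trained on pseudo-average pairs."""

    def __init__(self, pairs, config: DenoiserConfig = None):
        if not pairs:
            raise ValueError("need at least one training pair")
        self.pairs = [
            (np.asarray(getattr(a, "data", a), dtype=np.float32),
             np.asarray(getattr(b, "data", b), dtype=np.float32))
            for a, b in pairs
        ]
        shape = self.pairs[0][0].shape
        for a, b in self.pairs:
            if a.shape != shape or b.shape != shape:
                raise ValueError("training volumes must share one shape")
        self.config = config or DenoiserConfig()

    def fit(self, callback=None) -> "ArtifactReducerResults":
        cfg = self.config
        net = DenoiserNet(cfg)
        opt = Adam(net.parameters(), lr=cfg.learning_rate)
        trace = []
        for epoch in range(cfg.epochs):
            for inp, tgt in self.pairs:
                pred = net(inp)
                loss = (pred - ad.Tensor(tgt)).abs().mean()
                val = float(loss.item())
                if not np.isfinite(val):
                    raise FloatingPointError(
                        f"non-finite denoiser loss at epoch {epoch}: {val}"
                    )
                trace.append(val)
                loss.backward()
                opt.step()
            if callback is not None:
                callback(epoch, trace[-1])
        return ArtifactReducerResults(network=net, config=cfg,
                                      loss_trace=np.asarray(trace))


@dataclass
class ArtifactReducerResults:
    network: DenoiserNet
    config: DenoiserConfig
    loss_trace: np.ndarray

    def apply(self, images: PhaseImageSet) -> PhaseImageSet:
        """Denoise each phase volume (normalized-intensity domain)."""
        out = []
        for vol in images.volumes:
            pred = self.network(vol.data).data.astype(float)
            out.append(vol.copy_with(pred, kind="normalized"))
        return PhaseImageSet(out)

    def apply_volume(self, volume: Volume) -> Volume:
        return volume.copy_with(
            self.network(volume.data).data.astype(float), kind="normalized"
        )

    def summary(self) -> str:
        return "\n".join([
            "Artifact-reduction model",
            "========================",
            f"epochs:        {self.config.epochs}",
            f"base channels: {self.config.base_channels}",
            f"initial loss:  {self.loss_trace[0]:.6g}",
            f"final loss:    {self.loss_trace[-1]:.6g}",
        ])


def train_artifact_reduction(pairs, config: DenoiserConfig = None,
                             seed: int = None) -> ArtifactReducerResults:
    """Train the artifact-reduction network on (input, target) pairs."""
    if seed is not None:
        config = DenoiserConfig(**{
            **(config.__dict__ if config else {}), "seed": seed
        })
    return ArtifactReducer(pairs, config).fit()


def apply_artifact_reduction(model: ArtifactReducerResults,
                             images: PhaseImageSet) -> PhaseImageSet:
    """Apply a trained model to a set of phase images."""
    return model.apply(images)
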