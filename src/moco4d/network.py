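"""Groupwise-registration CNN: a 3D U-Net / residual hybrid.

The network consumes all N phase images concatenated along the channel
dimension and emits 3N channels — a 3-component displacement field to the
implicit template for every phase.  Four residual blocks encode (at 1/4 to
1/16 of the input resolution), three residual blocks decode with skip
connections, and a zero-initialized head predicts displacements at quarter
resolution which are trilinearly upsampled to the input grid, so the
untrained network realizes the identity transform exactly.  Respiratory
displacement fields vary over decimetre scales, so predicting them on a
coarse grid costs no accuracy while keeping CPU training fast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._nn import ConvBlock, Conv3d, Module, ResBlock

__all__ = ["NetworkSpec", "RegistrationNetwork", "build_network"]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyperparameters.

    widths: channels of the four encoder levels (at 1/4, 1/4, 1/8, 1/16 of
    the input resolution); the decoder mirrors the first three.
    """

    n_phases: int = 10
    widths: tuple = (16, 32, 64, 96)
    leaky_slope: float = 0.2
    kernel: int = 3

    def __post_init__(self):
        if self.n_phases < 2:
            raise ValueError("need at least two phases")
        if len(self.widths) != 4:
            raise ValueError("widths must give four encoder levels")


class RegistrationNetwork(Module):
    """Maps (N, Z, Y, X) phase images to (N, 3, Z, Y, X) displacements."""

    # overall downsampling factor: two stem pools (4) x two encoder pools (4)
    DIVISOR = 16

    def __init__(self, spec: NetworkSpec, seed: int = 0, dtype=np.float32):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(seed)
        w0, w1, w2, w3 = spec.widths
        n = spec.n_phases
        s = spec.leaky_slope
        self.stem = ConvBlock(n, w0, rng, s, dtype)
        self.enc1 = ResBlock(w0, w0, rng, s, dtype)
        self.enc2 = ResBlock(w0, w1, rng, s, dtype)
        self.enc3 = ResBlock(w1, w2, rng, s, dtype)
        self.enc4 = ResBlock(w2, w3, rng, s, dtype)
        self.dec3 = ResBlock(w3 + w2, w2, rng, s, dtype)  # bottleneck concat
        self.dec2 = ResBlock(w2 + w1, w1, rng, s, dtype)
        self.dec1 = ResBlock(w1 + w0, w0, rng, s, dtype)
        self.head = Conv3d(w0, 3 * n, rng=rng, zero_init=True, dtype=dtype)

    def __call__(self, images: np.ndarray) -> ad.Tensor:
        """Forward pass; ``images`` is a constant (N, Z, Y, X) array."""
        images = np.asarray(images)
        n, z, y, x = images.shape
        if n != self.spec.n_phases:
            raise ValueError(
                f"expected {self.spec.n_phases} phase channels, got {n}"
            )
        pads = [(-d) % self.DIVISOR for d in (z, y, x)]
        if any(pads):
            images = np.pad(
                images, [(0, 0)] + [(0, p) for p in pads], mode="edge"
            )
        t = ad.Tensor(images)
        h = self.stem(ad.avg_pool2(ad.avg_pool2(t)))  # 1/4 resolution
        e1 = self.enc1(h)                              # 1/4
        e2 = self.enc2(ad.avg_pool2(e1))               # 1/8
        e3 = self.enc3(ad.avg_pool2(e2))               # 1/16
        e4 = self.enc4(e3)                             # 1/16 (bottleneck)
        d3 = self.dec3(ad.concat([e4, e3], axis=0))    # 1/16
        d2 = self.dec2(ad.concat([ad.upsample2(d3), e2], axis=0))  # 1/8
        d1 = self.dec1(ad.concat([ad.upsample2(d2), e1], axis=0))  # 1/4
        out = ad.upsample2(ad.upsample2(self.head(d1)))
        if any(pads):
            out = out[:, :z, :y, :x]
        return out.reshape(n, 3, z, y, x)


def build_network(spec: NetworkSpec, seed: int = 0) -> RegistrationNetwork:
    """Construct a registration network with deterministic initialization."""
    return RegistrationNetwork(spec, seed=seed)
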