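"""Groupwise registration of respiratory phase images to an implicit template.

The motion model of a 4D-CBCT scan is built by jointly registering all N
phase images I^N to a common template that is never imaged: each phase n is
warped by a displacement field D_tem^n (pull convention, voxel units) and
the template I_tem is the voxelwise mean of the warped images.  The fields
are produced by a CNN (:mod:`moco4d.network`) whose parameters are trained
by minimizing

    L = L_sim + lambda1 * L_spatial + lambda2 * L_temporal + L_con,

where L_sim is the mean negative windowed squared local normalized
cross-correlation (LNCC) between each warped image and the template,
L_spatial is a bending-energy penalty on spatial second differences,
L_temporal a diffusion penalty on (cyclic) phase differences, and L_con a
zero-average-deformation constraint that pins the template to the motion
centroid.  Two learning strategies are provided:

* one-shot (patient-specific): the network is trained from scratch on the
  single image set being registered; the optimization itself yields the
  displacement fields.
* population: the network is pre-trained on a collection of 4D image sets
  for a fixed epoch budget and applied to new data in a single forward pass.

The API follows the model/results pattern: construct a
:class:`GroupwiseRegistration` from the images, call :meth:`fit`, and read
estimates and diagnostics off the returned results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad
from ._autodiff import _box1d
from ._nn import Adam
from .fdk import PhaseImageSet
from .geometry import GridSpec, Volume
from .network import NetworkSpec, RegistrationNetwork
from .transforms import DisplacementFieldSet, MotionModel, build_motion_model

__all__ = [
    "RegistrationConfig",
    "GroupwiseRegistration",
    "GroupwiseRegistrationResults",
    "PopulationRegistration",
    "PopulationRegistrationResults",
    "lncc",
    "implicit_template",
    "similarity_loss",
    "bending_energy",
    "temporal_diffusion",
    "zero_mean_penalty",
    "total_loss",
    "one_shot_register",
    "train_population",
    "predict_dvfs",
]


@dataclass(frozen=True)
class RegistrationConfig:
    """Hyperparameters of the groupwise registration objective.

    The regularization weights, LNCC window, learning rate and convergence
    rule default to the values that proved effective at clinical scale:
    lambda_spatial=1, lambda_temporal=1e-5, lambda_zero_mean=5e-2, window 5,
    Adam at 1e-3, and convergence when the loss deviates from the moving
    average of the previous 20 iterations by less than 1e-5.  ``max_iter``
    caps one-shot optimization; ``population_epochs`` fixes the pre-training
    budget.  ``normalized_lncc`` divides the similarity by the voxel count:
    this is the scaling under which the default weights and the 1e-5
    convergence tolerance are dimensionally coherent (a summed similarity
    grows with |Omega| and reduces the regularizers and the zero-average
    constraint to no-ops on any realistic grid), so it is on by default;
    the literal summed form remains available for direct evaluation.
    """

    lambda_spatial: float = 1.0
    lambda_temporal: float = 1e-5
    lambda_zero_mean: float = 5e-2
    lncc_window: int = 5
    lncc_eps: float = 1e-8
    normalized_lncc: bool = True
    learning_rate: float = 1e-3
    convergence_window: int = 20
    convergence_tol: float = 1e-5
    max_iter: int = 3000
    population_epochs: int = 200
    batch_size: int = 1
    seed: int = 0
    widths: tuple = (16, 32, 64, 96)
    cyclic_temporal: bool = True
    similarity_mask: str = "foreground"  # or "none"
    foreground_threshold: float = 0.02

    def __post_init__(self):
        if min(self.lambda_spatial, self.lambda_temporal,
               self.lambda_zero_mean) < 0:
            raise ValueError("regularization weights must be >= 0")
        if self.lncc_window < 3 or self.lncc_window % 2 == 0:
            raise ValueError("LNCC window must be odd and >= 3")


# ---------------------------------------------------------------------
# Loss terms (Tensor-valued; accept ndarrays for direct evaluation)
# ---------------------------------------------------------------------

def lncc(f, g, window: int = 5, eps: float = 1e-5, normalized: bool = False,
         weight=None):
    """Windowed squared local normalized cross-correlation.

    Sums, over every voxel p, the squared correlation of f and g within the
    window^3 neighbourhood of p (box means, replicate borders; eps guards
    the denominator).  For non-constant identical images every local term
    is 1, so the total approaches the voxel count |Omega|.  ``weight``
    (optional, same spatial shape) multiplies the per-voxel terms before
    summation — used to restrict the similarity to foreground tissue.
    Returns a Tensor; use ``.item()`` for the scalar.
    """
    f, g = ad.as_tensor(f), ad.as_tensor(g)
    w = float(window**3)
    sf = ad.box_sum(f, window)
    sg = ad.box_sum(g, window)
    sff = ad.box_sum(f * f, window)
    sgg = ad.box_sum(g * g, window)
    sfg = ad.box_sum(f * g, window)
    cross = sfg - sf * sg / w
    var_f = (sff - sf * sf / w).clamp_min(0.0)
    var_g = (sgg - sg * sg / w).clamp_min(0.0)
    terms = cross * cross / (var_f * var_g + eps)
    if weight is not None:
        terms = terms * np.asarray(weight, dtype=terms.dtype)
    total = terms.sum()
    if normalized:
        total = total / float(np.prod(f.shape[-3:]))
    return total


def _phase_arrays(images):
    if isinstance(images, PhaseImageSet):
        return images.as_array()
    return np.asarray(images)


def _warped(images, dvfs):
    arr = _phase_arrays(images)
    dvfs = ad.as_tensor(dvfs)
    return [ad.warp_tensor(arr[n], dvfs[n]) for n in range(arr.shape[0])]


def implicit_template(images, dvfs):
    """Voxelwise mean of all warped input images (Tensor)."""
    warped = _warped(images, dvfs)
    acc = warped[0]
    for wimg in warped[1:]:
        acc = acc + wimg
    return acc / float(len(warped))


def foreground_weight(images, window: int = 5, threshold: float = 0.02):
    """Binary weight over voxels near tissue in any phase image.

    Voxels whose window overlaps only featureless background (air) carry no
    correlation information; restricting the similarity to the dilated
    foreground removes a degenerate optimum in which a large common
    deformation manufactures spurious interpolation texture in air.
    """
    arr = _phase_arrays(images)
    fg = (arr.max(axis=0) > threshold).astype(arr.dtype)
    for ax in range(3):
        fg = _box1d(fg, window, ax)  # dilate by the window radius
    return (fg > 0.5).astype(arr.dtype)


def similarity_loss(images, dvfs, window: int = 5, eps: float = 1e-5,
                    normalized: bool = False, weight=None):
    """Mean negative LNCC between each warped image and the template.

    ``weight`` restricts the per-voxel correlation sum (see
    :func:`foreground_weight`); None uses every voxel.
    """
    warped = _warped(images, dvfs)
    n = len(warped)
    acc = warped[0]
    for wimg in warped[1:]:
        acc = acc + wimg
    template = acc / float(n)
    loss = None
    for wimg in warped:
        term = lncc(wimg, template, window, eps, normalized, weight)
        loss = term if loss is None else loss + term
    return -(loss / float(n))


def bending_energy(dvfs, lam: float = 1.0):
    """Spatial second-difference (bending-energy) penalty.

    dvfs: (N, 3, Z, Y, X).  Second derivatives are twice-applied forward
    differences per axis; stencils crossing the border are dropped (zero
    padding of the stencil).  Normalized by 3N|Omega|.
    """
    dvfs = ad.as_tensor(dvfs)
    n = dvfs.shape[0]
    n_vox = int(np.prod(dvfs.shape[-3:]))
    total = None
    for ax_slices in (
        (np.s_[:, :, :-2, :, :], np.s_[:, :, 1:-1, :, :], np.s_[:, :, 2:, :, :]),
        (np.s_[:, :, :, :-2, :], np.s_[:, :, :, 1:-1, :], np.s_[:, :, :, 2:, :]),
        (np.s_[:, :, :, :, :-2], np.s_[:, :, :, :, 1:-1], np.s_[:, :, :, :, 2:]),
    ):
        lo, mid, hi = ax_slices
        d2 = dvfs[lo] - 2.0 * dvfs[mid] + dvfs[hi]
        term = (d2 * d2).sum()
        total = term if total is None else total + term
    return total * (lam / (3.0 * n * n_vox))


def temporal_diffusion(dvfs, lam: float = 1.0, cyclic: bool = True):
    """Diffusion penalty on forward differences along the phase axis.

    Respiratory phases are periodic, so the difference wraps from the last
    phase back to the first by default.  Normalized by 3N|Omega|.
    """
    dvfs = ad.as_tensor(dvfs)
    n = dvfs.shape[0]
    if n < 2:
        raise ValueError("temporal diffusion needs at least two phases")
    n_vox = int(np.prod(dvfs.shape[-3:]))
    if cyclic:
        nxt = ad.concat([dvfs[1:], dvfs[:1]], axis=0)
    else:
        nxt = dvfs[1:]
        dvfs_head = dvfs[:-1]
        diff = nxt - dvfs_head
        return (diff * diff).sum() * (lam / (3.0 * n * n_vox))
    diff = nxt - dvfs
    return (diff * diff).sum() * (lam / (3.0 * n * n_vox))


def zero_mean_penalty(dvfs, lam: float = 1.0):
    """Root-mean-square of the per-voxel sum of all phase displacements."""
    dvfs = ad.as_tensor(dvfs)
    n_vox = int(np.prod(dvfs.shape[-3:]))
    s = dvfs.sum(axis=0)
    # tiny offset keeps the sqrt differentiable at exactly zero deformation
    return (((s * s).sum() / (3.0 * n_vox)) + 1e-24).sqrt() * lam


def total_loss(images, dvfs, config: RegistrationConfig, weight=None):
    """Full groupwise objective; returns (Tensor loss, dict of float parts)."""
    if weight is None and config.similarity_mask == "foreground":
        weight = foreground_weight(images, config.lncc_window,
                                   config.foreground_threshold)
    sim = similarity_loss(images, dvfs, config.lncc_window, config.lncc_eps,
                          config.normalized_lncc, weight)
    smo = bending_energy(dvfs, config.lambda_spatial)
    tmp = temporal_diffusion(dvfs, config.lambda_temporal,
                             config.cyclic_temporal)
    con = zero_mean_penalty(dvfs, config.lambda_zero_mean)
    loss = sim + smo + tmp + con
    parts = {
        "similarity": float(sim.item()),
        "bending": float(smo.item()),
        "temporal": float(tmp.item()),
        "zero_mean": float(con.item()),
        "total": float(loss.item()),
    }
    if not np.isfinite(parts["total"]):
        raise FloatingPointError(f"non-finite registration loss: {parts}")
    return loss, parts


# ---------------------------------------------------------------------
# Model / results objects
# ---------------------------------------------------------------------

def _as_image_array(images):
    """PhaseImageSet or array -> (float32 (N,Z,Y,X) array, GridSpec)."""
    if isinstance(images, PhaseImageSet):
        return images.as_array().astype(np.float32), images.grid
    arr = np.asarray(images, dtype=np.float32)
    if arr.ndim != 4:
        raise ValueError("expected (N, Z, Y, X) phase images")
    grid = GridSpec(shape=arr.shape[1:], spacing=(1.0, 1.0, 1.0))
    return arr, grid


class GroupwiseRegistration:
    """Groupwise registration model for one set of phase images.

    Parameters
    ----------
    images : PhaseImageSet or (N, Z, Y, X) array
        Normalized phase images on a common grid (N >= 2).
    config : RegistrationConfig, optional
    """

    def __init__(self, images, config: RegistrationConfig = None):
        self.images, self.grid = _as_image_array(images)
        if self.images.shape[0] < 2:
            raise ValueError("groupwise registration needs N >= 2 phases")
        self.config = config or RegistrationConfig()
        self.n_phases = self.images.shape[0]

    def _network(self, seed=None):
        spec = NetworkSpec(n_phases=self.n_phases, widths=self.config.widths)
        return RegistrationNetwork(spec, seed=self.config.seed
                                   if seed is None else seed)

    def fit(self, method: str = "one-shot",
            network: RegistrationNetwork = None,
            callback=None) -> "GroupwiseRegistrationResults":
        """Estimate the displacement fields.

        method "one-shot" trains a network from scratch on these images
        until the convergence rule fires or ``max_iter`` is reached;
        method "single-pass" runs one forward pass of a supplied
        (pre-trained) network without parameter updates.
        """
        cfg = self.config
        if method == "single-pass":
            if network is None:
                raise ValueError("single-pass fit requires a trained network")
            dvfs = network(self.images)
            return self._results(dvfs.data, [], True, 0, network)
        if method != "one-shot":
            raise ValueError(f"unknown fit method {method!r}")
        net = network or self._network()
        opt = Adam(net.parameters(), lr=cfg.learning_rate)
        weight = (foreground_weight(self.images, cfg.lncc_window,
                                    cfg.foreground_threshold)
                  if cfg.similarity_mask == "foreground" else None)
        trace = []
        converged = False
        for it in range(cfg.max_iter):
            dvfs = net(self.images)
            loss, parts = total_loss(self.images, dvfs, cfg, weight)
            trace.append(parts["total"])
            if callback is not None:
                callback(it, parts)
            w = cfg.convergence_window
            if it >= w:
                moving = float(np.mean(trace[-w - 1:-1]))
                if abs(trace[-1] - moving) < cfg.convergence_tol:
                    converged = True
                    break
            loss.backward()
            opt.step()
        final = net(self.images)
        return self._results(final.data, trace, converged, len(trace), net)

    def _results(self, fields, trace, converged, n_iter, net):
        dvfs = DisplacementFieldSet(fields.astype(np.float64), self.grid)
        return GroupwiseRegistrationResults(
            model=self, displacements=dvfs, loss_trace=np.asarray(trace),
            converged=converged, n_iter=n_iter, network=net,
        )


@dataclass
class GroupwiseRegistrationResults:
    """Estimated template displacements plus fit diagnostics."""

    model: GroupwiseRegistration
    displacements: DisplacementFieldSet
    loss_trace: np.ndarray
    converged: bool
    n_iter: int
    network: RegistrationNetwork
    _motion: MotionModel = field(default=None, repr=False)

    @property
    def template(self) -> Volume:
        data = implicit_template(self.model.images,
                                 self.displacements.fields).data
        return Volume(data, self.model.grid, kind="normalized")

    def warped_images(self) -> np.ndarray:
        arr = [w.data for w in _warped(self.model.images,
                                       self.displacements.fields)]
        return np.stack(arr, axis=0)

    def motion_model(self) -> MotionModel:
        """All pairwise inter-phase fields via inversion + composition."""
        if self._motion is None:
            self._motion = build_motion_model(self.displacements)
        return self._motion

    def loss_parts(self) -> dict:
        _, parts = total_loss(self.model.images, self.displacements.fields,
                              self.model.config)
        return parts

    def summary(self) -> str:
        parts = self.loss_parts()
        f = self.displacements.fields
        mags = np.sqrt((f**2).sum(axis=1))
        lines = [
            "Groupwise registration results",
            "==============================",
            f"phases:              {self.model.n_phases}",
            f"grid:                {tuple(self.model.grid.shape)}",
            f"iterations:          {self.n_iter}",
            f"converged:           {self.converged}",
            f"total loss:          {parts['total']:.6g}",
            f"  similarity:        {parts['similarity']:.6g}",
            f"  bending energy:    {parts['bending']:.6g}",
            f"  temporal diffusion:{parts['temporal']:.6g}",
            f"  zero-mean penalty: {parts['zero_mean']:.6g}",
            f"max |D| (voxels):    {mags.max():.3f}",
            f"mean |D| (voxels):   {mags.mean():.3f}",
        ]
        return "\n".join(lines)


class PopulationRegistration:
    """Pre-trains a registration network on a collection of 4D image sets."""

    def __init__(self, training_sets, config: RegistrationConfig = None):
        if not training_sets:
            raise ValueError("need at least one training set")
        self.config = config or RegistrationConfig()
        arrays = []
        grid0 = None
        for s in training_sets:
            arr, grid = _as_image_array(s)
            if grid0 is None:
                grid0, n0 = grid, arr.shape[0]
            elif arr.shape[0] != n0 or tuple(grid.shape) != tuple(grid0.shape):
                raise ValueError(
                    "training sets have heterogeneous grids or phase counts; "
                    "resample them to a common grid first"
                )
            arrays.append(arr)
        self.training_sets = arrays
        self.grid = grid0
        self.n_phases = arrays[0].shape[0]

    def fit(self, epochs: int = None,
            callback=None) -> "PopulationRegistrationResults":
        """Optimize the shared objective over all sets, batch size 1."""
        cfg = self.config
        epochs = cfg.population_epochs if epochs is None else epochs
        spec = NetworkSpec(n_phases=self.n_phases, widths=cfg.widths)
        net = RegistrationNetwork(spec, seed=cfg.seed)
        opt = Adam(net.parameters(), lr=cfg.learning_rate)
        weights = [
            (foreground_weight(arr, cfg.lncc_window, cfg.foreground_threshold)
             if cfg.similarity_mask == "foreground" else None)
            for arr in self.training_sets
        ]
        trace = []
        for epoch in range(epochs):
            for arr, wgt in zip(self.training_sets, weights):
                dvfs = net(arr)
                loss, parts = total_loss(arr, dvfs, cfg, wgt)
                trace.append(parts["total"])
                loss.backward()
                opt.step()
            if callback is not None:
                callback(epoch, trace[-1])
        return PopulationRegistrationResults(
            network=net, config=cfg, loss_trace=np.asarray(trace),
            n_epochs=epochs, n_sets=len(self.training_sets),
        )


@dataclass
class PopulationRegistrationResults:
    network: RegistrationNetwork
    config: RegistrationConfig
    loss_trace: np.ndarray
    n_epochs: int
    n_sets: int

    def predict(self, images) -> GroupwiseRegistrationResults:
        """Single forward pass on a new image set (no parameter updates)."""
        model = GroupwiseRegistration(images, self.config)
        return model.fit(method="single-pass", network=self.network)

    def summary(self) -> str:
        return "\n".join([
            "Population registration model",
            "=============================",
            f"training sets: {self.n_sets}",
            f"epochs:        {self.n_epochs}",
            f"iterations:    {len(self.loss_trace)}",
            f"final loss:    {self.loss_trace[-1]:.6g}" if len(self.loss_trace)
            else "final loss:    n/a",
        ])


# ---------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------

def one_shot_register(images, config: RegistrationConfig = None):
    """One-shot groupwise registration; returns (DisplacementFieldSet, net)."""
    res = GroupwiseRegistration(images, config).fit(method="one-shot")
    return res.displacements, res.network


def train_population(training_sets, config: RegistrationConfig = None):
    """Pre-train a population registration model on multiple image sets."""
    return PopulationRegistration(training_sets, config).fit()


def predict_dvfs(population_results: PopulationRegistrationResults,
                 images) -> DisplacementFieldSet:
    """Displacement fields for new images in a single pass."""
    return population_results.predict(images).displacements
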