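"""Noise reduction, normalization and augmentation.

The same augmentation family serves two purposes: enriching the training
sample (rotation, in-plane shifts, optional ZCA whitening) and perturbing
inputs at prediction time for the test-time-augmentation estimate of
aleatoric uncertainty (rotation, shrink/scale, additive noise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .patching import Volume


@dataclass
class AugmentSpec:
    """Ranges for the random geometric/intensity perturbations.

    rotation_range : degrees; angle drawn uniformly in ±rotation_range.
    shift_max : pixels; independent uniform draws per in-plane axis.
    scale_range : fractional; zoom factor drawn in 1 ± scale_range
        (covers both shrink and scale); used for test-time augmentation.
    noise_sd : additive Gaussian noise, intensity units; test-time only.
    zca_enabled / zca_epsilon : batch ZCA whitening for training batches.
    """

    rotation_range: float = 15.0
    shift_max: float = 20.0
    scale_range: float = 0.0
    noise_sd: float = 0.0
    zca_enabled: bool = False
    zca_epsilon: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rotation_range < 0 or self.shift_max < 0:
            raise ValueError("augmentation ranges must be non-negative")
        if self.scale_range < 0 or self.noise_sd < 0:
            raise ValueError("scale_range and noise_sd must be non-negative")


def tta_augment_spec(seed: int = 0) -> AugmentSpec:
    """Default test-time-augmentation spec: rotation, shrink/scale, noise.

    Shifts are excluded at test time so a patch stays spatially registered
    with the tile it came from; scale covers ±10% and noise 1% of the
    intensity range.
    """
    return AugmentSpec(
        rotation_range=15.0, shift_max=0.0, scale_range=0.10, noise_sd=0.01, seed=seed
    )


def diffusion_filter(
    volume: Volume,
    iterations: int = 5,
    conductance: float = 1.0,
    time_step: float = 0.125,
) -> Volume:
    """Edge-preserving anisotropic (Perona–Malik type) diffusion, slice-wise.

    The conduction coefficient ``g = 1 / (1 + (|∇I|/K)^2)`` suppresses
    smoothing across strong edges; ``K`` is ``conductance``.  Stability for
    the explicit 2D scheme requires ``time_step <= 0.25``.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if not 0 < time_step <= 0.25:
        raise ValueError(
            f"time_step {time_step} unstable; explicit 2D diffusion needs (0, 0.25]"
        )
    if conductance <= 0:
        raise ValueError("conductance must be positive")
    data = volume.data.astype(float).copy()
    k2 = conductance**2
    for _ in range(iterations):
        for s in range(data.shape[2]):
            img = data[:, :, s]
            # four-neighbour finite differences with replicated borders
            dn = np.roll(img, 1, axis=0) - img
            ds = np.roll(img, -1, axis=0) - img
            dw = np.roll(img, 1, axis=1) - img
            de = np.roll(img, -1, axis=1) - img
            dn[0, :] = ds[-1, :] = dw[:, 0] = de[:, -1] = 0.0
            flux = sum(d / (1.0 + d * d / k2) for d in (dn, ds, dw, de))
            data[:, :, s] = img + time_step * flux
    return Volume(data=data, spacing=volume.spacing, affine=volume.affine)


def normalize(volume: Volume) -> Volume:
    """Min–max rescale of the whole volume to [0, 1]."""
    lo = float(volume.data.min())
    hi = float(volume.data.max())
    if hi - lo == 0:
        raise ValueError("constant volume: min-max normalization undefined")
    data = (volume.data - lo) / (hi - lo)
    return Volume(data=data, spacing=volume.spacing, affine=volume.affine)


def augment(
    patch: np.ndarray, spec: AugmentSpec, draw: np.random.Generator
) -> np.ndarray:
    """Apply one random draw of the augmentation family to a (h, w, d) patch.

    Rotation, scaling and shifts act in-plane (identically on every depth
    slice) through a single bilinear affine resampling with the patch
    minimum as fill value; Gaussian noise is added last.  Identical ``draw``
    state gives identical output.
    """
    patch = np.asarray(patch, dtype=float)
    if patch.ndim != 3:
        raise ValueError(f"patch must be (h, w, d), got shape {patch.shape}")
    theta = np.deg2rad(draw.uniform(-spec.rotation_range, spec.rotation_range))
    shift_r = draw.uniform(-spec.shift_max, spec.shift_max)
    shift_c = draw.uniform(-spec.shift_max, spec.shift_max)
    zoom = draw.uniform(1.0 - spec.scale_range, 1.0 + spec.scale_range)

    h, w, _ = patch.shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    # output -> input mapping: rotate about the centre, scale, then shift
    matrix = rot / zoom
    offset = center - matrix @ (center + np.array([shift_r, shift_c]))
    fill = float(patch.min())
    out = np.empty_like(patch)
    for s in range(patch.shape[2]):
        out[:, :, s] = ndimage.affine_transform(
            patch[:, :, s], matrix, offset=offset, order=1, mode="constant", cval=fill
        )
    if spec.noise_sd > 0:
        out = out + draw.normal(0.0, spec.noise_sd, size=out.shape)
    return out


def zca_whiten(batch: np.ndarray, epsilon: float = 1e-8) -> np.ndarray:
    """ZCA (zero-phase, symmetric) whitening of a batch of patches.

    Each patch is flattened to a vector; the batch is mean-centered, rotated
    into the eigenbasis of its empirical covariance, rescaled by
    ``(λ + ε)^(-1/2)`` and rotated back, so the output stays in image space
    with empirical covariance approximately the identity.  The batch mean is
    re-added, so an already-white batch passes through unchanged.
    """
    batch = np.asarray(batch, dtype=float)
    n = batch.shape[0]
    if n < 2:
        raise ValueError("ZCA whitening needs a batch of at least 2 patches")
    shape = batch.shape[1:]
    X = batch.reshape(n, -1)
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = Xc.T @ Xc / (n - 1)
    lam, U = np.linalg.eigh(cov)
    lam = np.clip(lam, 0.0, None)
    W = (U * (1.0 / np.sqrt(lam + epsilon))) @ U.T
    out = Xc @ W + mean
    return out.reshape((n,) + shape)


def zca_matrix(batch: np.ndarray, epsilon: float = 1e-8) -> np.ndarray:
    """The symmetric whitening matrix ``U diag((λ+ε)^(-1/2)) Uᵀ`` itself."""
    batch = np.asarray(batch, dtype=float)
    n = batch.shape[0]
    if n < 2:
        raise ValueError("ZCA whitening needs a batch of at least 2 patches")
    X = batch.reshape(n, -1)
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (n - 1)
    lam, U = np.linalg.eigh(cov)
    lam = np.clip(lam, 0.0, None)
    return (U * (1.0 / np.sqrt(lam + epsilon))) @ U.T
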