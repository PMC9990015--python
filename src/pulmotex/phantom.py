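"""Synthetic CT-like lung phantoms with six separable texture classes.

The generator stands in for a patient cohort: it builds a body-shaped volume
containing two ellipsoidal lungs and paints configurable sub-regions of the
lung with texture motifs that echo the six radiological patterns the
classifier must separate:

* ``healthy`` (0) - dark, lightly noisy parenchyma;
* ``ground_glass`` (1) - hazy raised attenuation with smooth variation;
* ``ground_glass_reticulation`` (2) - haze plus a fine line lattice;
* ``honeycomb`` (3) - clustered dark cysts with bright walls;
* ``emphysema`` (4) - abnormally dark blobs on parenchyma;
* ``unhealthy`` (5) - dense, bright consolidation.

Intensities are arbitrary units in [0, 1]; the pipeline needs relative
texture contrast, not calibrated HU.  Everything is deterministic for a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage

from .patching import (
    CLASS_NAMES,
    N_CLASSES,
    SENTINEL,
    LabelMap,
    Patch,
    PatchSet,
    Volume,
)

MIN_EXTENT = 8  # smallest supported patch edge

# Composition intensities (arbitrary units).
_AIR = 0.05
_BODY = 0.55


@dataclass
class PhantomSpec:
    """Recipe for one phantom volume.

    ``class_regions`` is an ordered list of ``(class_id, region)`` pairs
    applied on top of an all-healthy lung; later regions override earlier
    ones.  Region descriptors are dicts with a ``type`` key:

    ``{"type": "all"}``
        the whole lung mask;
    ``{"type": "box", "rows": (r0, r1), "cols": (c0, c1), "slices": (s0, s1),
    "side": "left"|"right"|None}``
        half-open voxel box intersected with the mask (optionally one lung);
    ``{"type": "ellipsoid", "center": (r, c, s), "radii": (a, b, c)}``
        ellipsoid intersected with the mask;
    ``{"type": "fraction", "fraction": f}``
        the first ``round(f * n_mask)`` lung voxels in raster order — handy
        for phantoms with an exact disease burden.
    """

    shape: tuple[int, int, int] = (160, 160, 9)
    spacing: tuple[float, float, float] = (1.0, 1.0, 3.0)
    class_regions: list[tuple[int, dict[str, Any]]] = field(default_factory=list)
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if any(e < MIN_EXTENT for e in self.shape[:2]) or self.shape[2] < 3:
            raise ValueError(
                f"phantom shape {self.shape} below minimum {(MIN_EXTENT, MIN_EXTENT, 3)}"
            )
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        for class_id, _ in self.class_regions:
            if class_id not in range(N_CLASSES):
                raise ValueError(
                    f"unknown class_id {class_id}; expected 0..{N_CLASSES - 1}"
                )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class Phantom:
    """A generated volume with its lung mask and voxel-level ground truth."""

    volume: Volume
    mask: np.ndarray
    truth: LabelMap
    spec: PhantomSpec

    def __post_init__(self) -> None:
        on_mask = self.truth.labels[self.mask.astype(bool)]
        if (on_mask == SENTINEL).any() or (
            self.truth.labels[~self.mask.astype(bool)] != SENTINEL
        ).any():
            raise ValueError("truth must be defined exactly on mask voxels")


def _lung_masks(shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Left/right lung ellipsoids inside the body."""
    H, W, D = shape
    rr, cc, ss = np.ogrid[:H, :W, :D]
    lungs = []
    for c_col in (0.30 * W, 0.70 * W):
        e = (
            ((rr - 0.5 * H) / (0.42 * H)) ** 2
            + ((cc - c_col) / (0.21 * W)) ** 2
            + ((ss - 0.5 * (D - 1)) / (0.85 * D)) ** 2
        )
        lungs.append(e <= 1.0)
    return lungs[0], lungs[1]


def _region_mask(
    region: dict[str, Any], mask: np.ndarray, shape: tuple[int, int, int]
) -> np.ndarray:
    kind = region.get("type")
    H, W, D = shape
    if kind == "all":
        return mask.copy()
    if kind == "box":
        r0, r1 = region.get("rows", (0, H))
        c0, c1 = region.get("cols", (0, W))
        s0, s1 = region.get("slices", (0, D))
        sel = np.zeros(shape, dtype=bool)
        sel[r0:r1, c0:c1, s0:s1] = True
        side = region.get("side")
        if side == "left":
            sel[:, W // 2:, :] = False
        elif side == "right":
            sel[:, : W // 2, :] = False
        return sel & mask
    if kind == "ellipsoid":
        r, c, s = region["center"]
        a, b, cz = region["radii"]
        rr, cc, ss = np.ogrid[:H, :W, :D]
        sel = ((rr - r) / a) ** 2 + ((cc - c) / b) ** 2 + ((ss - s) / cz) ** 2 <= 1.0
        return sel & mask
    if kind == "fraction":
        f = float(region["fraction"])
        if not 0.0 < f <= 1.0:
            raise ValueError(f"fraction must be in (0, 1], got {f}")
        flat = np.flatnonzero(mask.ravel())
        n = int(round(f * flat.size))
        sel = np.zeros(mask.size, dtype=bool)
        sel[flat[:n]] = True
        return sel.reshape(mask.shape)
    raise ValueError(f"unknown region type {kind!r}")


def _lattice(shape, period: int, thickness: int = 1) -> np.ndarray:
    """In-plane grid of lines (rows and columns), constant across slices."""
    H, W, D = shape
    rows = (np.arange(H) % period) < thickness
    cols = (np.arange(W) % period) < thickness
    plane = rows[:, None] | cols[None, :]
    return np.broadcast_to(plane[:, :, None], shape)


def _disk_lattice(shape, period: int, radius: float, jitter_rows: bool = True) -> np.ndarray:
    """In-plane lattice of disks (cyst lumens / emphysematous blobs)."""
    H, W, D = shape
    r = np.arange(H)[:, None]
    c = np.arange(W)[None, :]
    # distance to the nearest lattice node, with alternate rows offset
    ri = r % period
    shift = (period // 2) * (((r // period) % 2) if jitter_rows else 0)
    ci = (c + shift) % period
    dr = np.minimum(ri, period - ri)
    dc = np.minimum(ci, period - ci)
    plane = dr**2 + dc**2 <= radius**2
    return np.broadcast_to(plane[:, :, None], shape)


def _class_textures(
    shape: tuple[int, int, int], rng: np.random.Generator
) -> np.ndarray:
    """One full-volume intensity field per class, stacked as (6, H, W, D)."""
    fields = np.empty((N_CLASSES,) + shape)
    # healthy: dark parenchyma
    fields[0] = 0.20
    # ground glass: hazy raised attenuation, smooth spatial variation
    haze = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=4.0)
    haze /= max(np.abs(haze).max(), 1e-12)
    fields[1] = 0.42 + 0.05 * haze
    # ground glass reticulation: haze plus a fine bright line lattice
    fields[2] = 0.42 + 0.22 * _lattice(shape, period=6)
    # honeycomb: bright cyst walls around clustered dark lumens
    fields[3] = np.where(_disk_lattice(shape, period=7, radius=2.2), 0.05, 0.65)
    # emphysema: abnormally dark blobs on parenchyma
    fields[4] = np.where(_disk_lattice(shape, period=9, radius=3.2), 0.02, 0.16)
    # unhealthy: dense consolidation
    fields[5] = 0.78
    return fields


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Build a phantom volume, lung mask and ground-truth label map.

    Deterministic for a fixed ``spec.seed``; raises if a region does not
    intersect the lung mask.
    """
    rng = np.random.default_rng(spec.seed)
    left, right = _lung_masks(spec.shape)
    mask = left | right

    truth = np.full(spec.shape, SENTINEL, dtype=np.int16)
    truth[mask] = 0  # healthy unless a region overrides
    for class_id, region in spec.class_regions:
        sel = _region_mask(region, mask, spec.shape)
        if not sel.any():
            raise ValueError(
                f"region {region!r} for class {class_id} lies outside the lung mask"
            )
        truth[sel] = class_id

    fields = _class_textures(spec.shape, rng)
    data = np.full(spec.shape, _AIR)
    body = _body_mask(spec.shape)
    data[body] = _BODY
    for class_id in range(N_CLASSES):
        sel = truth == class_id
        if sel.any():
            data[sel] = fields[class_id][sel]
    data = data + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    np.clip(data, 0.0, 1.0, out=data)

    volume = Volume(data=data, spacing=spec.spacing)
    return Phantom(
        volume=volume,
        mask=mask,
        truth=LabelMap(labels=truth, spacing=spec.spacing, affine=volume.affine),
        spec=spec,
    )


def _body_mask(shape: tuple[int, int, int]) -> np.ndarray:
    H, W, D = shape
    rr, cc, _ = np.ogrid[:H, :W, :D]
    e = ((rr - 0.5 * H) / (0.48 * H)) ** 2 + ((cc - 0.5 * W) / (0.48 * W)) ** 2
    return np.broadcast_to(e <= 1.0, shape)


def default_phantom_spec(
    noise_sd: float = 0.03, seed: int = 0, shape: tuple[int, int, int] = (160, 160, 9)
) -> PhantomSpec:
    """Six-class study phantom: each lung split into three row bands.

    Left lung hosts healthy / ground glass / reticulation, right lung hosts
    honeycomb / emphysema / unhealthy, so all six textures occupy compact
    patch-sized regions.
    """
    H = shape[0]
    b0, b1, b2, b3 = int(0.05 * H), int(0.37 * H), int(0.63 * H), int(0.95 * H)
    regions: list[tuple[int, dict[str, Any]]] = [
        (0, {"type": "box", "rows": (b0, b1), "side": "left"}),
        (1, {"type": "box", "rows": (b1, b2), "side": "left"}),
        (2, {"type": "box", "rows": (b2, b3), "side": "left"}),
        (3, {"type": "box", "rows": (b0, b1), "side": "right"}),
        (4, {"type": "box", "rows": (b1, b2), "side": "right"}),
        (5, {"type": "box", "rows": (b2, b3), "side": "right"}),
    ]
    return PhantomSpec(shape=shape, class_regions=regions, noise_sd=noise_sd, seed=seed)


def preprocess_phantom(
    phantom: Phantom,
    iterations: int = 5,
    conductance: float = 1.0,
    time_step: float = 0.125,
) -> Phantom:
    """Apply the pipeline's preprocessing (diffusion + min-max) to a phantom.

    Training patches must be drawn from a volume that went through the same
    noise reduction and normalization the mapping pipeline applies, otherwise
    the classifier sees a shifted intensity distribution at deployment.
    """
    from .preprocess import diffusion_filter, normalize

    volume = phantom.volume
    if iterations > 0:
        volume = diffusion_filter(volume, iterations=iterations,
                                  conductance=conductance, time_step=time_step)
    volume = normalize(volume)
    return Phantom(volume=volume, mask=phantom.mask, truth=phantom.truth,
                   spec=phantom.spec)


def majority_label(truth_patch: np.ndarray) -> int:
    """Majority ground-truth class inside a patch; ties break to the lowest id.

    Sentinel (off-mask) voxels are ignored; returns the sentinel if the patch
    holds no lung voxel.
    """
    vals = truth_patch[truth_patch != SENTINEL]
    if vals.size == 0:
        return SENTINEL
    counts = np.bincount(vals, minlength=N_CLASSES)
    return int(np.argmax(counts))  # argmax takes the lowest index on ties


def sample_labeled_patches(
    phantom: Phantom,
    size: tuple[int, int, int],
    n_per_class: int,
    seed: int = 0,
    classes: tuple[int, ...] | None = None,
    min_mask_fraction: float = 0.5,
    min_purity: float = 0.0,
    max_tries_factor: int = 2000,
) -> PatchSet:
    """Draw a balanced, labelled patch sample from a phantom.

    Patches are drawn at random positions (overlap allowed — these are
    training samples, not a tiling); a patch's label is the majority truth
    class among its lung voxels and must match the requested class.  By
    default samples are majority-lung (``min_mask_fraction=0.5``) but may
    straddle texture boundaries, like the tiles the mapping stage produces;
    raise ``min_purity`` to restrict to homogeneous single-texture samples
    (useful when measuring texture statistics).

    Raises ``ValueError`` naming any requested class absent from the phantom.
    """
    if classes is None:
        classes = tuple(range(N_CLASSES))
    present = set(np.unique(phantom.truth.labels)) - {SENTINEL}
    missing = [c for c in classes if c not in present]
    if missing:
        names = ", ".join(f"{c} ({CLASS_NAMES[c]})" for c in missing)
        raise ValueError(f"phantom lacks requested class(es): {names}")

    rng = np.random.default_rng(seed)
    h, w, d = size
    H, W, D = phantom.volume.shape
    if h > H or w > W or d > D:
        raise ValueError(f"patch size {size} exceeds phantom shape {(H, W, D)}")
    truth = phantom.truth.labels
    mask = phantom.mask

    patches: list[Patch] = []
    labels: list[int] = []
    fractions: list[float] = []
    for target in classes:
        centers = np.argwhere(truth == target)
        got = 0
        tries = 0
        limit = n_per_class * max_tries_factor
        while got < n_per_class:
            tries += 1
            if tries > limit:
                raise ValueError(
                    f"could not sample {n_per_class} patches of class {target} "
                    f"({CLASS_NAMES[target]}); region too small for size {size}"
                )
            r, c, s = centers[rng.integers(len(centers))]
            r0 = int(np.clip(r - h // 2, 0, H - h))
            c0 = int(np.clip(c - w // 2, 0, W - w))
            s0 = int(np.clip(s - d // 2, 0, D - d))
            tp = truth[r0:r0 + h, c0:c0 + w, s0:s0 + d]
            frac = float(mask[r0:r0 + h, c0:c0 + w, s0:s0 + d].mean())
            if frac < min_mask_fraction or majority_label(tp) != target:
                continue
            lung_vox = tp[tp != SENTINEL]
            if (lung_vox == target).mean() < min_purity:
                continue
            patches.append(
                Patch(
                    data=phantom.volume.data[
                        r0:r0 + h, c0:c0 + w, s0:s0 + d
                    ].copy(),
                    grid_index=(-1, -1, -1),
                    voxel_origin=(r0, c0, s0),
                )
            )
            labels.append(target)
            fractions.append(frac)
            got += 1
    return PatchSet(
        patches=patches,
        source_shape=phantom.volume.shape,
        mask_fraction=np.asarray(fractions),
        labels=np.asarray(labels),
    )
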