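"""3D patch extraction and label/uncertainty map rebuild.

The lung region of a CT volume is tiled into non-overlapping 3D patches
(default sizes 64x64x3, 32x32x3, 16x16x3, 8x8x3), each patch is classified
into one of six texture classes, and the per-patch labels are broadcast back
onto the voxel grid to build the anatomical label map and the disease-ratio
profile of the patient.

Conventions
-----------
* Voxel indices are 0-based ``(row, col, slice)``; arrays are ``(H, W, D)``.
* Tiles are emitted in raster order: slice-major, then row, then column.
* Tiles that would overrun the volume are shifted inward so the last tile
  abuts the boundary; where two shifted tiles overlap, the later tile in
  raster order wins during rebuild.
* Voxels outside the lung mask, or inside tiles discarded for containing
  almost no lung, carry the sentinel label ``-1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical class order used throughout the package.
CLASS_NAMES = (
    "healthy",
    "ground_glass",
    "ground_glass_reticulation",
    "honeycomb",
    "emphysema",
    "unhealthy",
)
N_CLASSES = len(CLASS_NAMES)

#: Label value for voxels outside the lung mask / not covered by any patch.
SENTINEL = -1

#: Patch footprints exercised by default (height, width, depth).
DEFAULT_PATCH_SIZES = ((64, 64, 3), (32, 32, 3), (16, 16, 3), (8, 8, 3))


def _default_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    return aff


@dataclass
class Volume:
    """A 3D intensity grid with voxel spacing and spatial reference."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class Patch:
    """One tile of a volume plus its bookkeeping coordinates."""

    data: np.ndarray
    grid_index: tuple[int, int, int]
    voxel_origin: tuple[int, int, int]

    @property
    def size(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class PatchSet:
    """Raster-ordered patches extracted from one volume.

    ``labels`` is populated for labelled (training) sets only.
    """

    patches: list[Patch]
    source_shape: tuple[int, int, int]
    mask_fraction: np.ndarray = field(default_factory=lambda: np.zeros(0))
    labels: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.patches)

    def __iter__(self):
        return iter(self.patches)

    def stack(self) -> np.ndarray:
        """All patch intensities as one array (n, h, w, d)."""
        return np.stack([p.data for p in self.patches]) if self.patches else np.zeros((0,))


@dataclass
class LabelMap:
    """Per-voxel class ids (0..5) on lung voxels, sentinel elsewhere."""

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        valid = (self.labels == SENTINEL) | (
            (self.labels >= 0) & (self.labels < N_CLASSES)
        )
        if not valid.all():
            bad = np.unique(self.labels[~valid])
            raise ValueError(f"label map contains invalid class ids {bad.tolist()}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)


@dataclass
class DiseaseProfile:
    """Fraction of labelled lung voxels assigned to each texture class."""

    ratios: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.ratios.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"disease ratios must sum to 1, got {total}")

    def as_vector(self) -> np.ndarray:
        return np.array([self.ratios[name] for name in CLASS_NAMES])


def _tile_starts(extent: int, size: int) -> list[int]:
    """Start offsets of non-overlapping tiles along one axis.

    The final tile is shifted inward so it ends exactly at the boundary.
    """
    if size > extent:
        raise ValueError(f"patch size {size} exceeds volume extent {extent}")
    starts = list(range(0, extent - size + 1, size))
    if starts[-1] + size < extent:
        starts.append(extent - size)
    return starts


def extract_patches(
    volume: Volume,
    mask: np.ndarray,
    size: tuple[int, int, int],
    min_mask_fraction: float = 0.05,
) -> PatchSet:
    """Tile the masked region of ``volume`` into non-overlapping patches.

    Parameters
    ----------
    volume
        Source intensity volume.
    mask
        Binary lung mask, same shape as the volume.
    size
        Patch extent ``(h, w, d)``; the stride equals the patch size.
    min_mask_fraction
        Tiles whose fraction of lung voxels falls below this are discarded.

    Returns
    -------
    PatchSet
        Kept tiles in raster order (slice-major, then row, then column) with
        their grid indices and per-tile lung fraction.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != volume.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match volume shape {volume.shape}"
        )
    h, w, d = size
    if not mask.any():
        return PatchSet(patches=[], source_shape=volume.shape,
                        mask_fraction=np.zeros(0))
    H, W, D = volume.shape
    row_starts = _tile_starts(H, h)
    col_starts = _tile_starts(W, w)
    slc_starts = _tile_starts(D, d)

    patches: list[Patch] = []
    fractions: list[float] = []
    for k, s0 in enumerate(slc_starts):
        for i, r0 in enumerate(row_starts):
            for j, c0 in enumerate(col_starts):
                tile_mask = mask[r0:r0 + h, c0:c0 + w, s0:s0 + d]
                frac = float(tile_mask.mean())
                if frac < min_mask_fraction:
                    continue
                patches.append(
                    Patch(
                        data=volume.data[r0:r0 + h, c0:c0 + w, s0:s0 + d].copy(),
                        grid_index=(i, j, k),
                        voxel_origin=(r0, c0, s0),
                    )
                )
                fractions.append(frac)
    return PatchSet(
        patches=patches,
        source_shape=volume.shape,
        mask_fraction=np.asarray(fractions),
    )


def rebuild_label_map(
    patchset: PatchSet,
    labels: np.ndarray,
    mask: np.ndarray,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    affine: np.ndarray | None = None,
) -> LabelMap:
    """Broadcast per-patch class labels back onto the voxel grid.

    Lung voxels covered by a patch receive that patch's label; where two
    inward-shifted tiles overlap the later patch in raster order wins.
    Everything else is the sentinel.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != len(patchset):
        raise ValueError(
            f"got {labels.shape[0]} labels for {len(patchset)} patches"
        )
    mask = np.asarray(mask).astype(bool)
    if mask.shape != patchset.source_shape:
        raise ValueError("mask shape does not match patch source shape")
    out = np.full(patchset.source_shape, SENTINEL, dtype=np.int16)
    for patch, label in zip(patchset.patches, labels):
        r0, c0, s0 = patch.voxel_origin
        h, w, d = patch.size
        region = out[r0:r0 + h, c0:c0 + w, s0:s0 + d]
        region[mask[r0:r0 + h, c0:c0 + w, s0:s0 + d]] = label
    return LabelMap(labels=out, spacing=spacing, affine=affine)


def disease_profile(labelmap: LabelMap, mask: np.ndarray) -> DiseaseProfile:
    """Fraction of labelled lung voxels per class (the patient's profile)."""
    mask = np.asarray(mask).astype(bool)
    lab = labelmap.labels[mask]
    lab = lab[lab != SENTINEL]
    if lab.size == 0:
        raise ValueError("no labelled lung voxels; cannot compute disease profile")
    counts = np.bincount(lab, minlength=N_CLASSES).astype(float)
    ratios = counts / counts.sum()
    return DiseaseProfile(ratios={n: float(r) for n, r in zip(CLASS_NAMES, ratios)})


def rebuild_uncertainty_map(
    patchset: PatchSet,
    values: np.ndarray,
    mask: np.ndarray,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Broadcast one scalar uncertainty per patch onto the voxel grid.

    Uncovered voxels are NaN.  For display the paper-style red-scale rendering
    clamps values to [0, 0.30]; the returned array is unclamped.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] != len(patchset):
        raise ValueError(
            f"got {values.shape[0]} values for {len(patchset)} patches"
        )
    mask = np.asarray(mask).astype(bool)
    out = np.full(patchset.source_shape, np.nan)
    for patch, val in zip(patchset.patches, values):
        r0, c0, s0 = patch.voxel_origin
        h, w, d = patch.size
        region = out[r0:r0 + h, c0:c0 + w, s0:s0 + d]
        region[mask[r0:r0 + h, c0:c0 + w, s0:s0 + d]] = val
    return out


def expected_tile_count(shape: tuple[int, int, int], size: tuple[int, int, int]) -> int:
    """Number of tiles a full-mask volume produces: prod(ceil(extent/size))."""
    return int(np.prod([int(np.ceil(e / s)) for e, s in zip(shape, size)]))
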