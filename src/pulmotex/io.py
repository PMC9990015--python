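"""Reading and writing volumes: NIfTI-1 in/out, DICOM series in, masks.

Arrays are ``(rows, cols, slices)``; the NIfTI affine is preserved on a
write→read round trip.  DICOM series are read slice-by-slice and sorted by
slice position regardless of file order on disk.
"""

from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from scipy import ndimage

from .patching import LabelMap, Volume


def read_volume(path: str | os.PathLike) -> Volume:
    """Read a 3D NIfTI file or a directory holding one DICOM series."""
    path = Path(path)
    if path.is_dir():
        return _read_dicom_series(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI volume, got {data.ndim}D at {path}")
    zooms = img.header.get_zooms()[:3]
    return Volume(data=data, spacing=tuple(float(z) for z in zooms),
                  affine=np.asarray(img.affine))


def write_volume(volume: Volume, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(volume.data.astype(np.float64), volume.affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def write_labelmap(labelmap: LabelMap, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(labelmap.labels.astype(np.int16), labelmap.affine)
    img.header.set_zooms(labelmap.spacing)
    nib.save(img, str(path))


def read_labelmap(path: str | os.PathLike) -> LabelMap:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj).astype(np.int16)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D label map, got {data.ndim}D at {path}")
    zooms = img.header.get_zooms()[:3]
    return LabelMap(labels=data, spacing=tuple(float(z) for z in zooms),
                    affine=np.asarray(img.affine))


def write_scalar_map(
    values: np.ndarray, affine: np.ndarray, spacing, path: str | os.PathLike
) -> None:
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float64), affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def read_mask(path: str | os.PathLike) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D mask, got {data.ndim}D at {path}")
    return data > 0


def write_mask(mask: np.ndarray, affine: np.ndarray, spacing,
               path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def _read_dicom_series(directory: Path) -> Volume:
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() in (".dcm", ""))
    slices = []
    for f in files:
        if f.is_dir():
            continue
        try:
            ds = pydicom.dcmread(str(f))
        except (pydicom.errors.InvalidDicomError, IsADirectoryError):
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise ValueError(f"no DICOM slices found in {directory}")
    # sort by slice position along the normal (fall back to InstanceNumber)
    def position(ds):
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    slices.sort(key=position)
    pixel_spacings = {tuple(map(float, getattr(s, "PixelSpacing", (1, 1))))
                      for s in slices}
    if len(pixel_spacings) != 1:
        raise ValueError(f"inconsistent DICOM pixel spacing: {pixel_spacings}")
    row_sp, col_sp = pixel_spacings.pop()
    if len(slices) > 1:
        gaps = np.diff([position(s) for s in slices])
        if gaps.size and (np.abs(gaps - gaps[0]) > 1e-3).any():
            raise ValueError("inconsistent DICOM slice spacing")
        slice_sp = float(abs(gaps[0])) if gaps.size else 1.0
    else:
        slice_sp = float(getattr(slices[0], "SliceThickness", 1.0))
    data = np.stack(
        [s.pixel_array.astype(float) * float(getattr(s, "RescaleSlope", 1.0))
         + float(getattr(s, "RescaleIntercept", 0.0)) for s in slices],
        axis=2,
    )
    return Volume(data=data, spacing=(row_sp, col_sp, slice_sp))


def otsu_lung_mask(volume: Volume) -> np.ndarray:
    """Threshold fallback lung mask for phantoms and simple scans.

    Lungs are the dark structures enclosed by the bright body: voxels below
    the Otsu threshold that do not touch the volume border (which removes
    the surrounding air).
    """
    from skimage.filters import threshold_otsu

    dark = volume.data < threshold_otsu(volume.data)
    # erode first so a lung touching the body edge cannot leak into the
    # outside air through a voxel-wide bridge; one dilation restores size
    eroded = ndimage.binary_erosion(dark)
    labelled, n = ndimage.label(eroded)
    border = set()
    for axis in range(3):
        for idx in (0, -1):
            border |= set(np.unique(np.take(labelled, idx, axis=axis)))
    keep = np.isin(labelled, [i for i in range(1, n + 1) if i not in border])
    return ndimage.binary_dilation(keep) & dark
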