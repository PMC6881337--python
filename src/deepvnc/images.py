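"""Hounsfield-unit rasters, brain masks, lossless I/O and mask conditioning.

Images are 2-D HU rasters carried by :class:`HUImage`; binary brain masks by
:class:`BrainMask`. Two on-disk formats are supported: NIfTI (``.nii`` /
``.nii.gz``, via nibabel, for volumes) and a compressed array archive
(``.npz``) holding per-slice tensors under the keys ``pixels``, ``mask``,
``subject_id`` and ``slice_id``. Both round-trip pixel values losslessly.

Pixel coordinates are (row, col), 0-based; slice indexing is 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import nibabel as nib
from scipy.ndimage import binary_erosion
from skimage.morphology import disk

logger = logging.getLogger(__name__)

#: 12-bit CT convention: air floor to the maximum encodable attenuation.
DEFAULT_HU_RANGE = (-1024.0, 3071.0)


@dataclass
class HUImage:
    """A 2-D raster of Hounsfield-unit values with identity metadata.

    Parameters
    ----------
    pixels : ndarray
        2-D float array of HU values; must be finite.
    slice_id : str
        Opaque slice identifier.
    subject_id : str
        Opaque patient/scene identifier (the grouping key for data splits).
    """

    pixels: np.ndarray
    slice_id: str = "0"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError(f"HUImage requires a non-empty 2-D array, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("HUImage pixels must be finite (no NaN/Inf)")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "HUImage":
        """Return a copy carrying ``pixels`` but the same identifiers."""
        return HUImage(pixels=pixels, slice_id=self.slice_id, subject_id=self.subject_id)


@dataclass
class BrainMask:
    """Binary raster marking intracranial parenchyma."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError(f"BrainMask requires a non-empty 2-D array, got shape {self.pixels.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def n_true(self) -> int:
        return int(self.pixels.sum())


def clamp_hu(pixels: np.ndarray, hu_range: tuple[float, float] = DEFAULT_HU_RANGE) -> np.ndarray:
    """Clip HU values into ``hu_range``, logging a warning if any were outside."""
    lo, hi = hu_range
    n_out = int(np.count_nonzero((pixels < lo) | (pixels > hi)))
    if n_out:
        logger.warning("%d pixel(s) outside HU range [%g, %g]; clamped", n_out, lo, hi)
    return np.clip(pixels, lo, hi)


def _ids_from_path(path: Path) -> tuple[str, str]:
    stem = path.name
    for suffix in (".nii.gz", ".nii", ".npz"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    return stem, "0"


def read_image(
    path,
    slice_index: int | None = None,
    hu_range: tuple[float, float] = DEFAULT_HU_RANGE,
) -> HUImage:
    """Read a 2-D HU raster from a NIfTI file or an array archive.

    For a 3-D NIfTI volume ``slice_index`` selects an axial slice (last axis,
    0-based). Out-of-range values are clamped into ``hu_range`` with a logged
    warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    subject_id, slice_id = _ids_from_path(path)
    if path.name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim == 3:
            if slice_index is None:
                if data.shape[2] != 1:
                    raise ValueError("3-D volume requires slice_index")
                slice_index = 0
            if not 0 <= slice_index < data.shape[2]:
                raise IndexError(f"slice_index {slice_index} out of range for {data.shape[2]} slices")
            data = data[:, :, slice_index]
            slice_id = str(slice_index)
        elif data.ndim != 2:
            raise ValueError(f"unsupported NIfTI dimensionality {data.ndim}")
    elif path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as archive:
            data = np.asarray(archive["pixels"], dtype=float)
            if "subject_id" in archive:
                subject_id = str(archive["subject_id"])
            if "slice_id" in archive:
                slice_id = str(archive["slice_id"])
        if data.ndim == 3:
            if slice_index is None:
                raise ValueError("3-D archive payload requires slice_index")
            if not 0 <= slice_index < data.shape[2]:
                raise IndexError(f"slice_index {slice_index} out of range")
            data = data[:, :, slice_index]
            slice_id = str(slice_index)
        elif data.ndim != 2:
            raise ValueError(f"archive payload must be 2-D or 3-D, got {data.ndim}-D")
    else:
        raise ValueError(f"unsupported image format: {path.name}")
    return HUImage(pixels=clamp_hu(data, hu_range), slice_id=slice_id, subject_id=subject_id)


def write_image(image: HUImage, path, mask: BrainMask | None = None) -> None:
    """Write an HU raster losslessly (float64 NIfTI, or npz archive).

    For the archive format an optional companion mask is stored under the
    ``mask`` key; NIfTI output holds pixels only.
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    if path.name.endswith((".nii", ".nii.gz")):
        nifti = nib.Nifti1Image(image.pixels.astype(np.float64), affine=np.eye(4))
        nifti.header.set_data_dtype(np.float64)
        nib.save(nifti, str(path))
    elif path.suffix == ".npz":
        payload = {
            "pixels": image.pixels.astype(np.float64),
            "subject_id": np.str_(image.subject_id),
            "slice_id": np.str_(image.slice_id),
        }
        if mask is not None:
            payload["mask"] = mask.pixels
        np.savez_compressed(path, **payload)
    else:
        raise ValueError(f"unsupported image format: {path.name}")


def read_mask(path) -> BrainMask:
    """Read the companion mask stored in an array archive."""
    path = Path(path)
    with np.load(path, allow_pickle=False) as archive:
        if "mask" not in archive:
            raise KeyError(f"no mask stored in {path}")
        return BrainMask(pixels=archive["mask"])


def erode_mask(mask: BrainMask, diameter: int = 5) -> BrainMask:
    """Erode a brain mask with a disk-shaped structuring element.

    The element of diameter ``d`` (odd) is the set of integer offsets within
    Euclidean distance ``(d-1)/2`` of the center; diameter 5 gives the 13-pixel
    disk used to pull evaluation masks away from skull-stripping boundaries.
    Pixels outside the raster count as background, so the border is eroded too.
    """
    if diameter < 1 or diameter % 2 == 0:
        raise ValueError(f"diameter must be a positive odd integer, got {diameter}")
    if diameter == 1:
        return BrainMask(pixels=mask.pixels.copy())
    footprint = disk(diameter // 2)
    return BrainMask(pixels=binary_erosion(mask.pixels, structure=footprint, border_value=0))


def crop_to_mask(
    image: HUImage, mask: BrainMask, margin: int = 0
) -> tuple[HUImage, BrainMask]:
    """Crop image and mask to the mask's tight bounding box plus ``margin``.

    The bounding box is expanded by ``margin`` pixels on every side and clipped
    to the raster bounds; pixel values are preserved.
    """
    if mask.shape != image.shape:
        raise ValueError("mask shape must equal image shape")
    if margin < 0:
        raise ValueError("margin must be non-negative")
    rows, cols = np.nonzero(mask.pixels)
    if rows.size == 0:
        raise ValueError("cannot crop to an empty mask")
    r0 = max(int(rows.min()) - margin, 0)
    r1 = min(int(rows.max()) + margin + 1, image.height)
    c0 = max(int(cols.min()) - margin, 0)
    c1 = min(int(cols.max()) + margin + 1, image.width)
    return (
        image.with_pixels(image.pixels[r0:r1, c0:c1].copy()),
        BrainMask(pixels=mask.pixels[r0:r1, c0:c1].copy()),
    )
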