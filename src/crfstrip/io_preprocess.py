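"""NIfTI I/O, canonical working space, and training augmentations.

All processing happens in a fixed *canonical space*: a 1 mm isotropic,
``(256, 256, 256)`` RAS grid in which the world-space centre of the input
volume sits at voxel ``(128, 128, 128)`` and intensities are min-max
normalised to ``[0, 1]``.  Mapping into this space uses only the affine
stored in the file — no registration to a template.

Resampling is trilinear for images and nearest-neighbour for label masks,
so label sets are preserved exactly.  The canonical affine always has unit
scales and RAS orientation regardless of the input orientation (the input's
own affine carries its orientation into the resampling), which makes the
canonical -> native round trip exactly invertible up to interpolation.

Augmentation draws exactly ONE of four transforms per call — intensity
scaling in [0.9, 1.1], intensity shift in [-0.1, 0.1], rotation up to 15
degrees about a random grid axis, or translation up to 10 mm per axis —
matching the training protocol the package's defaults encode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

CANONICAL_SIZE = 256

__all__ = [
    "RawVolume", "CanonicalVolume", "AugmentSpec",
    "load_volume", "save_volume", "save_mask",
    "to_canonical", "from_canonical", "augment", "augment_arrays",
]


@dataclass
class RawVolume:
    """A volume exactly as stored on disk: voxel grid + voxel-to-world affine."""

    voxels: np.ndarray
    affine: np.ndarray
    meta: str = ""

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D grid, got {self.voxels.ndim}D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is degenerate (non-invertible)")


@dataclass
class CanonicalVolume:
    """A volume resampled to the canonical grid, intensities in [0, 1]."""

    voxels: np.ndarray
    affine: np.ndarray
    source_affine: np.ndarray

    @property
    def shape(self):
        return self.voxels.shape


@dataclass
class AugmentSpec:
    intensity_scale_range: tuple = (0.9, 1.1)
    intensity_shift_range: tuple = (-0.1, 0.1)
    max_rotation_deg: float = 15.0
    max_translation_mm: float = 10.0
    seed: int = 0


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_volume(path) -> RawVolume:
    """Read a NIfTI file verbatim (no resampling).

    4D files with a singleton trailing axis are squeezed to 3D with a
    logged note; any other non-3D layout is rejected.
    """
    try:
        img = nib.load(str(path))
    except FileNotFoundError:
        raise
    except Exception as e:  # corrupt header etc.
        raise ValueError(f"not a readable NIfTI file: {path} ({e})") from e
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        logger.info("squeezing singleton 4th axis of %s", path)
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(
            f"expected a 3D volume, got shape {data.shape} in {path}")
    return RawVolume(voxels=data, affine=img.affine, meta=str(path))


def save_volume(vol, path):
    """Write a RawVolume/CanonicalVolume as NIfTI, preserving its affine."""
    nib.save(nib.Nifti1Image(np.asarray(vol.voxels, dtype=np.float32),
                             vol.affine), str(path))


def save_mask(mask: np.ndarray, affine: np.ndarray, path):
    """Write a binary mask as unsigned 8-bit NIfTI."""
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine),
             str(path))


# ---------------------------------------------------------------------------
# Canonical space
# ---------------------------------------------------------------------------

def _canonical_affine(raw: RawVolume, size: int) -> np.ndarray:
    """Unit-scale RAS affine placing the input's centre at the grid centre."""
    centre_vox = np.array([s // 2 for s in raw.voxels.shape], dtype=np.float64)
    centre_world = raw.affine @ np.append(centre_vox, 1.0)
    can = np.eye(4)
    can[:3, 3] = centre_world[:3] - size // 2
    return can


def to_canonical(raw: RawVolume, size: int = CANONICAL_SIZE) -> CanonicalVolume:
    """Resample to the 1 mm canonical grid and min-max normalise to [0, 1].

    The geometric centre of the input grid lands at voxel
    ``(size//2,)*3``; the grid is implicitly padded (with 0) or cropped to
    ``(size, size, size)`` by the resampling.
    """
    if float(raw.voxels.max()) - float(raw.voxels.min()) < 1e-12:
        raise ValueError("constant image: zero dynamic range, "
                         "cannot normalise intensities")
    can_aff = _canonical_affine(raw, size)
    m = np.linalg.inv(raw.affine) @ can_aff
    data = ndimage.affine_transform(
        raw.voxels.astype(np.float64), m[:3, :3], m[:3, 3],
        output_shape=(size,) * 3, order=1, mode="constant", cval=0.0)
    lo, hi = float(data.min()), float(data.max())
    if hi - lo < 1e-12:
        raise ValueError("constant image: zero dynamic range, "
                         "cannot normalise intensities")
    data = (data - lo) / (hi - lo)
    return CanonicalVolume(voxels=data, affine=can_aff,
                           source_affine=raw.affine.copy())


def from_canonical(mask: np.ndarray, raw: RawVolume,
                   size: int = CANONICAL_SIZE) -> np.ndarray:
    """Inverse-resample a canonical-space label grid to the native grid
    (nearest-neighbour)."""
    mask = np.asarray(mask)
    if mask.shape != (size,) * 3:
        raise ValueError(f"mask shape {mask.shape} != {(size,) * 3}")
    can_aff = _canonical_affine(raw, size)
    a = np.linalg.inv(can_aff) @ raw.affine
    out = ndimage.affine_transform(
        mask.astype(np.float64), a[:3, :3], a[:3, 3],
        output_shape=raw.voxels.shape, order=0, mode="constant", cval=0.0)
    return out.astype(mask.dtype)


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

_ROT_PLANES = ((0, 1), (0, 2), (1, 2))


def augment_arrays(image: np.ndarray, mask: np.ndarray, spec: AugmentSpec,
                   seed: int):
    """Apply exactly one randomly chosen augmentation to an (image, mask)
    pair on a shared grid.  Deterministic per seed."""
    if image.shape != mask.shape:
        raise ValueError("image and mask must share the grid")
    rng = np.random.default_rng(seed)
    branch = int(rng.integers(4))
    img = np.asarray(image, dtype=np.float64)
    msk = np.asarray(mask)
    if branch == 0:      # intensity scale
        f = rng.uniform(*spec.intensity_scale_range)
        return np.clip(img * f, 0.0, 1.0), msk.copy()
    if branch == 1:      # intensity shift
        s = rng.uniform(*spec.intensity_shift_range)
        return np.clip(img + s, 0.0, 1.0), msk.copy()
    if branch == 2:      # rotation about a random grid plane
        plane = _ROT_PLANES[rng.integers(len(_ROT_PLANES))]
        angle = rng.uniform(-spec.max_rotation_deg, spec.max_rotation_deg)
        img2 = ndimage.rotate(img, angle, axes=plane, reshape=False,
                              order=1, mode="constant", cval=0.0)
        msk2 = ndimage.rotate(msk.astype(np.float64), angle, axes=plane,
                              reshape=False, order=0, mode="constant",
                              cval=0.0).astype(msk.dtype)
        return np.clip(img2, 0.0, 1.0), msk2
    # translation (mm == voxels on the 1 mm canonical grid)
    t = rng.uniform(-spec.max_translation_mm, spec.max_translation_mm, 3)
    img2 = ndimage.shift(img, t, order=1, mode="constant", cval=0.0)
    msk2 = ndimage.shift(msk.astype(np.float64), t, order=0,
                         mode="constant", cval=0.0).astype(msk.dtype)
    return np.clip(img2, 0.0, 1.0), msk2


def augment(volume: CanonicalVolume, mask: np.ndarray, spec: AugmentSpec,
            seed: int):
    """Augment a canonical volume and its mask together."""
    if volume.voxels.shape != mask.shape:
        raise ValueError("volume and mask must share the canonical grid")
    img2, msk2 = augment_arrays(volume.voxels, mask, spec, seed)
    return CanonicalVolume(voxels=img2, affine=volume.affine.copy(),
                           source_affine=volume.source_affine.copy()), msk2
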