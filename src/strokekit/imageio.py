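"""Volume containers, NIfTI I/O and DWI preprocessing.

The preprocessing contract mirrors a typical acute-stroke DWI pipeline:
volumes are padded with blank slices to a fixed slice count so every
patient presents the same input size, intensities are re-scaled by
z-score normalization, and 2D training slices are augmented with
rotation / horizontal flip / shift-scale-rotate transforms applied
identically to image and mask.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from skimage.transform import AffineTransform as _SkAffine
from skimage.transform import warp as _sk_warp

__all__ = [
    "DwiVolume",
    "SegMap",
    "AugmentParams",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "pad_slices",
    "zscore_normalize",
    "augment",
]


def _default_affine(spacing_mm: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


@dataclass
class DwiVolume:
    """A patient's 3D diffusion-weighted image grid.

    Axes are (x, y, slice); ``spacing_mm`` gives the voxel size along each
    axis and ``affine`` maps 0-based voxel indices to world millimetres.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    affine: np.ndarray = None  # type: ignore[assignment]
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing components must be positive")
        if self.affine is None:
            self.affine = _default_affine(self.spacing_mm)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def replace(self, **kw) -> "DwiVolume":
        return dataclasses.replace(self, **kw)


@dataclass
class SegMap:
    """Binary 3D lesion mask on the same grid as its DwiVolume."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    affine: np.ndarray = None  # type: ignore[assignment]
    patient_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"expected 3D mask, got {arr.ndim}D")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be in {0, 1}")
        self.data = arr.astype(np.uint8)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing components must be positive")
        if self.affine is None:
            self.affine = _default_affine(self.spacing_mm)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def n_voxels(self) -> int:
        return int(self.data.sum())

    def same_grid(self, other) -> bool:
        return (
            self.data.shape == other.data.shape
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.affine, other.affine)
        )

    def replace(self, **kw) -> "SegMap":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_volume(path, patient_id: str = "") -> DwiVolume:
    """Read a 3D NIfTI-1 volume.

    Raises ``ValueError`` naming the path on malformed input and on
    anything that is not a plain 3D volume.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # noqa: BLE001 - rewrap with path context
        raise ValueError(f"cannot read NIfTI file {path!s}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    elif data.ndim != 3:
        raise ValueError(f"expected 3D volume in {path!s}, got {data.ndim}D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DwiVolume(
        data=np.asarray(data, dtype=np.float64),
        spacing_mm=spacing,
        affine=np.asarray(img.affine, dtype=np.float64),
        patient_id=patient_id,
    )


def write_volume(volume: DwiVolume, path) -> None:
    img = nib.Nifti1Image(volume.data.astype(np.float64), volume.affine)
    img.header.set_zooms(volume.spacing_mm)
    nib.save(img, str(path))


def read_mask(path, patient_id: str = "") -> SegMap:
    vol = read_volume(path, patient_id=patient_id)
    data = (vol.data > 0.5).astype(np.uint8)
    return SegMap(data=data, spacing_mm=vol.spacing_mm, affine=vol.affine,
                  patient_id=patient_id)


def write_mask(mask: SegMap, path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    img.header.set_zooms(mask.spacing_mm)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def pad_slices(volume, target: int = 32):
    """Replenish a volume (or mask) with blank slices up to ``target``.

    Blank slices are appended after the last acquired slice. Volumes with
    more slices than ``target`` are rejected rather than cropped.
    """
    n = volume.data.shape[2]
    if n > target:
        raise ValueError(
            f"volume exceeds padding target ({n} slices > {target})"
        )
    if n == target:
        return volume
    pad = np.zeros(volume.data.shape[:2] + (target - n,), dtype=volume.data.dtype)
    return volume.replace(data=np.concatenate([volume.data, pad], axis=2))


def zscore_normalize(volume: DwiVolume) -> DwiVolume:
    """Re-scale intensities to zero mean / unit SD over the nonzero support.

    The statistics are computed over nonzero voxels only, so appended blank
    padding slices neither shift the statistics nor acquire nonzero values:
    exact zeros stay exactly zero.
    """
    support = volume.data != 0
    vals = volume.data[support]
    if vals.size < 2:
        raise ValueError("zero variance: not enough nonzero voxels to normalize")
    mu = vals.mean()
    sd = vals.std()
    if sd < 1e-12:
        raise ValueError("zero variance: constant volume cannot be z-scored")
    out = np.zeros_like(volume.data)
    out[support] = (vals - mu) / sd
    return volume.replace(data=out)


@dataclass
class AugmentParams:
    """2D augmentation policy: rotation, horizontal flip, shift-scale-rotate.

    ``rotate_deg`` bounds the standalone rotation draw; ``hflip_prob`` is the
    probability of a horizontal flip; shift/scale/rotate bounds parameterize a
    single combined affine draw (shift as a fraction of the slice size, scale
    as 1 +/- ``scale_delta``).
    """

    rotate_deg: float = 15.0
    hflip_prob: float = 0.5
    shift_frac: float = 0.0625
    scale_delta: float = 0.1
    ssr_rotate_deg: float = 15.0

    @staticmethod
    def identity() -> "AugmentParams":
        return AugmentParams(rotate_deg=0.0, hflip_prob=0.0, shift_frac=0.0,
                             scale_delta=0.0, ssr_rotate_deg=0.0)


def _warp_pair(image, mask, tform):
    img_out = _sk_warp(image, tform.inverse, order=1, mode="constant", cval=0.0,
                       preserve_range=True)
    msk_out = _sk_warp(mask.astype(float), tform.inverse, order=0,
                       mode="constant", cval=0.0, preserve_range=True)
    return img_out, (msk_out > 0.5).astype(mask.dtype)


def augment(image_slice, mask_slice, params: AugmentParams, seed: int):
    """Apply one random draw of the augmentation policy to a slice pair.

    The identical geometric transform is applied to the image (bilinear) and
    to the mask (nearest neighbour, so the mask stays binary). The draw is a
    deterministic function of ``seed``.
    """
    image_slice = np.asarray(image_slice, dtype=np.float64)
    mask_slice = np.asarray(mask_slice)
    if image_slice.shape != mask_slice.shape:
        raise ValueError(
            f"image/mask shape mismatch: {image_slice.shape} vs {mask_slice.shape}"
        )
    if image_slice.ndim != 2:
        raise ValueError("augment operates on single 2D slices")
    rng = np.random.default_rng(seed)

    img, msk = image_slice, mask_slice
    # horizontal flip (axis 0 = x, the left-right image axis)
    if rng.random() < params.hflip_prob:
        img = img[::-1, :].copy()
        msk = msk[::-1, :].copy()
    # standalone rotation about the slice centre
    angle = rng.uniform(-params.rotate_deg, params.rotate_deg)
    # combined shift-scale-rotate draw
    h, w = img.shape
    shift = rng.uniform(-params.shift_frac, params.shift_frac, size=2) * (h, w)
    scale = 1.0 + rng.uniform(-params.scale_delta, params.scale_delta)
    ssr_angle = rng.uniform(-params.ssr_rotate_deg, params.ssr_rotate_deg)

    total_angle = np.deg2rad(angle + ssr_angle)
    if total_angle == 0.0 and scale == 1.0 and not np.any(shift):
        return img, msk
    centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    tform = (
        _SkAffine(translation=-centre)
        + _SkAffine(rotation=total_angle, scale=scale)
        + _SkAffine(translation=centre + shift)
    )
    return _warp_pair(img, msk, tform)
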