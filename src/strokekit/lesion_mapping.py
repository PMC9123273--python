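"""Atlas-based lesion mapping.

A segmented lesion is carried between native and standard space through
composed world-to-world affine transforms; labeled atlases are resampled
onto the native grid with nearest-neighbour interpolation, and three
lesion-distribution indices are reported per region: the lesion voxel
count in the region, the percentage of the lesion in the region, and the
percentage of the region occupied by the lesion.

The built-in registration estimates a 12-parameter affine by minimizing
the mean-squared intensity difference, initialized from the centers of
mass (and image principal axes); a hook accepts a precomputed 4x4 matrix
from an external tool instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .imageio import DwiVolume, SegMap
from .metrics import lesion_volume_ml

__all__ = [
    "AtlasDefinition",
    "AffineTransform",
    "RegionRow",
    "LesionReport",
    "register_affine",
    "load_transform",
    "save_transform",
    "compose",
    "transform_atlas",
    "transform_mask",
    "lesion_indices",
    "render_report",
]


@dataclass
class AtlasDefinition:
    """Integer-labeled volume (0 = outside brain) plus a region table.

    ``region_table`` maps region id -> (name, territory flag in
    {"anterior", "posterior"}).
    """

    labels: np.ndarray
    region_table: dict[int, tuple[str, str]]
    spacing_mm: tuple[float, float, float]
    affine: np.ndarray = None  # type: ignore[assignment]
    name: str = "atlas"

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if self.affine is None:
            aff = np.eye(4)
            aff[0, 0], aff[1, 1], aff[2, 2] = self.spacing_mm
            self.affine = aff
        self.affine = np.asarray(self.affine, dtype=np.float64)
        present = set(int(v) for v in np.unique(self.labels)) - {0}
        missing = present - set(self.region_table)
        if missing:
            raise ValueError(f"labels missing from region table: {sorted(missing)}")

    @property
    def region_ids(self) -> list[int]:
        return sorted(self.region_table)

    def territory_mask(self, territory: str) -> np.ndarray:
        ids = [rid for rid, (_, terr) in self.region_table.items()
               if terr == territory]
        return np.isin(self.labels, ids)

    def brain_mask(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class AffineTransform:
    """World-to-world 4x4 affine with provenance metadata.

    ``matrix`` maps homogeneous world coordinates of the *moving* image
    onto world coordinates of the *fixed* image.
    """

    matrix: np.ndarray
    moving_id: str = ""
    fixed_id: str = ""

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (4, 4):
            raise ValueError("transform must be a 4x4 matrix")
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("transform must be invertible")

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix),
                               moving_id=self.fixed_id, fixed_id=self.moving_id)

    @staticmethod
    def identity() -> "AffineTransform":
        return AffineTransform(np.eye(4))


def compose(t1: AffineTransform, t2: AffineTransform) -> AffineTransform:
    """Composition applying ``t1`` first, then ``t2`` (matrix product t2 @ t1)."""
    return AffineTransform(t2.matrix @ t1.matrix,
                           moving_id=t1.moving_id, fixed_id=t2.fixed_id)


def save_transform(t: AffineTransform, path) -> None:
    np.savetxt(path, t.matrix, fmt="%.12g",
               header=f"world-to-world affine: {t.moving_id} -> {t.fixed_id}")


def load_transform(path, moving_id: str = "", fixed_id: str = "") -> AffineTransform:
    """External-tool hook: read a row-major 4x4 world-to-world matrix file."""
    mat = np.loadtxt(path)
    return AffineTransform(mat.reshape(4, 4), moving_id=moving_id, fixed_id=fixed_id)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def _resample(data, moving_affine, fixed_affine, fixed_shape,
              world_transform, order):
    """Pull-back resampling of ``data`` onto the fixed grid.

    For each fixed voxel index i: world_f = A_f i, world_m = T^-1 world_f,
    i_m = A_m^-1 world_m.
    """
    m = np.linalg.inv(moving_affine) @ np.linalg.inv(world_transform) @ fixed_affine
    return ndimage.affine_transform(
        data, m[:3, :3], offset=m[:3, 3], output_shape=tuple(fixed_shape),
        order=order, mode="constant", cval=0.0, prefilter=(order > 1),
    )


def resample_volume(moving: DwiVolume, t: AffineTransform,
                    target: DwiVolume) -> DwiVolume:
    """Resample a moving intensity volume onto the target grid (trilinear)."""
    out = _resample(moving.data, moving.affine, target.affine,
                    target.shape, t.matrix, order=1)
    return DwiVolume(out, target.spacing_mm, target.affine, moving.patient_id)


def transform_mask(mask: SegMap, t: AffineTransform, target) -> SegMap:
    """Carry a binary mask through ``t`` onto the target grid (nearest)."""
    out = _resample(mask.data.astype(np.float64), mask.affine, target.affine,
                    target.shape if hasattr(target, "shape") else target.data.shape,
                    t.matrix, order=0)
    return SegMap((out > 0.5).astype(np.uint8), target.spacing_mm,
                  target.affine, mask.patient_id)


def transform_atlas(atlas: AtlasDefinition, t: AffineTransform,
                    target: DwiVolume) -> AtlasDefinition:
    """Resample atlas labels onto the target grid with nearest neighbour.

    ``t`` maps atlas-space world coordinates onto native (target) world
    coordinates. The label set can only shrink; no labels are invented.
    """
    out = _resample(atlas.labels.astype(np.float64), atlas.affine,
                    target.affine, target.shape, t.matrix, order=0)
    out = np.rint(out).astype(atlas.labels.dtype)
    if not np.any(out > 0):
        raise ValueError("atlas does not intersect target grid")
    return AtlasDefinition(out, dict(atlas.region_table), target.spacing_mm,
                           target.affine, name=atlas.name)


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------

def _center_of_mass_world(vol: DwiVolume) -> np.ndarray:
    w = np.clip(vol.data, 0, None)
    if w.sum() <= 0:
        raise ValueError("cannot register an empty volume")
    com_vox = np.array(ndimage.center_of_mass(w))
    return (vol.affine @ np.append(com_vox, 1.0))[:3]


def _principal_axes_world(vol: DwiVolume):
    """Intensity-weighted second moments in world coordinates."""
    w = np.clip(vol.data, 0, None)
    idx = np.argwhere(w > 0)
    wts = w[w > 0]
    pts = (vol.affine[:3, :3] @ idx.T).T + vol.affine[:3, 3]
    mu = np.average(pts, axis=0, weights=wts)
    d = pts - mu
    cov = (d * wts[:, None]).T @ d / wts.sum()
    return mu, cov


def _params_to_matrix(x: np.ndarray) -> np.ndarray:
    t = np.eye(4)
    t[:3, :3] = np.eye(3) + x[:9].reshape(3, 3)
    t[:3, 3] = x[9:]
    return t


def register_affine(moving: DwiVolume, fixed: DwiVolume,
                    method: str = "builtin",
                    matrix_file=None,
                    smooth_sigma_mm: float = 1.0,
                    maxiter: int = 6000) -> AffineTransform:
    """Estimate the world-to-world affine mapping ``moving`` onto ``fixed``.

    The built-in method initializes translation from the centers of mass
    (with a principal-axes sanity fallback when moments are degenerate) and
    then minimizes the mean-squared intensity difference over the fixed
    brain support with Powell's method over 12 affine parameters. Both
    volumes are lightly smoothed in-plane first so that voxel noise does
    not trap the optimizer.

    ``method='external'`` reads a precomputed 4x4 world-to-world matrix
    from ``matrix_file`` instead.
    """
    if method == "external":
        if matrix_file is None:
            raise ValueError("external method requires matrix_file")
        return load_transform(matrix_file, moving.patient_id, fixed.patient_id)
    if method != "builtin":
        raise ValueError(f"unknown registration method: {method}")

    def smooth(v: DwiVolume) -> np.ndarray:
        sig = [smooth_sigma_mm / s for s in v.spacing_mm[:2]] + [0.0]
        return ndimage.gaussian_filter(v.data, sigma=sig)

    mov_s = smooth(moving)
    fix_s = smooth(fixed)
    mov = moving.replace(data=mov_s)

    # center-of-mass translation init; principal axes only as a check that
    # the moment matrix is non-degenerate (phantoms need no rotation init)
    t0 = np.zeros(12)
    try:
        com_m = _center_of_mass_world(moving.replace(data=mov_s))
        com_f = _center_of_mass_world(fixed.replace(data=fix_s))
        t0[9:] = com_f - com_m
        _, cov = _principal_axes_world(moving.replace(data=mov_s))
        if np.linalg.cond(cov) > 1e8:
            import warnings

            warnings.warn("singular moment matrix; center-of-mass init only",
                          RuntimeWarning, stacklevel=2)
    except ValueError:
        pass

    support = fix_s > (0.05 * fix_s.max())
    fix_vals = fix_s[support]
    scale = np.array([0.05] * 9 + [5.0, 5.0, 5.0])

    def cost(xs: np.ndarray) -> float:
        mat = _params_to_matrix(xs * scale + np.concatenate([np.zeros(9), t0[9:]]))
        res = _resample(mov.data, mov.affine, fixed.affine, fixed.shape,
                        mat, order=1)
        return float(np.mean((res[support] - fix_vals) ** 2))

    res = optimize.minimize(
        cost, np.zeros(12), method="Powell",
        options={"maxfev": maxiter, "xtol": 1e-4, "ftol": 1e-8},
    )
    base = float(np.mean(fix_vals ** 2))
    if not np.isfinite(res.fun) or res.fun > base:
        raise RuntimeError(f"registration diverged (final cost {res.fun:.4g})")
    mat = _params_to_matrix(res.x * scale + np.concatenate([np.zeros(9), t0[9:]]))
    return AffineTransform(mat, moving.patient_id, fixed.patient_id)


# ---------------------------------------------------------------------------
# Lesion-distribution indices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionRow:
    region_id: int
    name: str
    territory: str
    voxels_in_region: int
    pct_of_lesion: float
    pct_of_region: float


@dataclass
class LesionReport:
    """Per-region lesion-distribution indices for one atlas.

    For every region: the lesion voxel count inside it, the percentage of
    the lesion falling in it, and the percentage of the region occupied by
    the lesion. Voxels on atlas background (label 0) are reported in
    ``voxels_outside`` so counts always conserve.
    """

    atlas_name: str
    rows: list[RegionRow]
    voxels_outside: int
    total_lesion_voxels: int
    lesion_volume_ml: float

    def to_dict(self) -> dict:
        return {
            "atlas": self.atlas_name,
            "total_lesion_voxels": self.total_lesion_voxels,
            "lesion_volume_ml": self.lesion_volume_ml,
            "voxels_outside_atlas": self.voxels_outside,
            "regions": [vars(r) for r in self.rows],
        }


def lesion_indices(segmap: SegMap, atlas_native: AtlasDefinition) -> LesionReport:
    """Compute the three per-region indices on a shared native grid."""
    if segmap.data.shape != atlas_native.labels.shape:
        raise ValueError(
            f"grid mismatch: {segmap.data.shape} vs {atlas_native.labels.shape}")
    lesion = segmap.data.astype(bool)
    total = int(lesion.sum())
    if total == 0:
        raise ValueError("no lesion to map")
    rows = []
    counted = 0
    for rid in atlas_native.region_ids:
        region = atlas_native.labels == rid
        n_region = int(region.sum())
        n_in = int(np.sum(lesion & region))
        counted += n_in
        name, terr = atlas_native.region_table[rid]
        rows.append(RegionRow(
            region_id=rid, name=name, territory=terr, voxels_in_region=n_in,
            pct_of_lesion=round(100.0 * n_in / total, 2),
            pct_of_region=round(100.0 * n_in / n_region, 2) if n_region else 0.0,
        ))
    outside = total - counted
    return LesionReport(
        atlas_name=atlas_native.name, rows=rows, voxels_outside=outside,
        total_lesion_voxels=total,
        lesion_volume_ml=lesion_volume_ml(total, segmap.spacing_mm),
    )


def render_report(reports: list[LesionReport], format: str = "text") -> str:
    """Render per-atlas reports; text view sorts by count and hides zero rows,
    JSON retains everything."""
    if format == "json":
        return json.dumps([r.to_dict() for r in reports], indent=2)
    if format != "text":
        raise ValueError(f"unknown format: {format}")
    lines = []
    for rep in reports:
        lines.append(f"=== Atlas: {rep.atlas_name} ===")
        lines.append(f"total lesion voxels: {rep.total_lesion_voxels}"
                     f" ({rep.lesion_volume_ml:.2f} ml)")
        if rep.voxels_outside:
            lines.append(f"voxels outside atlas: {rep.voxels_outside}")
        lines.append(f"{'region':<16}{'territory':<12}{'voxels':>8}"
                     f"{'% of lesion':>13}{'% of region':>13}")
        for row in sorted(rep.rows, key=lambda r: -r.voxels_in_region):
            if row.voxels_in_region == 0:
                continue
            lines.append(f"{row.name:<16}{row.territory:<12}"
                         f"{row.voxels_in_region:>8}"
                         f"{row.pct_of_lesion:>12.2f}%{row.pct_of_region:>12.2f}%")
        lines.append("")
    return "\n".join(lines)
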