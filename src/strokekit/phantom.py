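"""Synthetic DWI phantoms with known ground truth.

Acute ischemic lesions are bright in diffusion-weighted images, so the
phantom places hyperintense ellipsoidal components of controlled in-plane
diameter, multiplicity, and vascular territory inside a brain-shaped
ellipsoid on a noisy background, using anisotropic spacing (fine in-plane,
thick slices) typical of clinical DWI. A two-territory labeled atlas
phantom stands in for real anatomical atlases, and a known affine
native-to-standard transform makes registration testable.

Labeling rules mirror clinical convention: a *lacune* is an isolated
(single-component) lesion whose maximal in-plane extent does not exceed a
diameter threshold (default 20 mm); multiple scattered small lesions are
never lacunes. The territory label is anterior or posterior when at least
95% of lesion voxels fall in that territory's regions, otherwise "both".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

from .imageio import DwiVolume, SegMap, write_mask, write_volume
from .lesion_mapping import AffineTransform, AtlasDefinition, resample_volume

__all__ = [
    "LesionSpec",
    "PhantomConfig",
    "PatientCase",
    "generate_atlas_phantom",
    "generate_case",
    "derive_labels",
    "feret_diameter_mm",
    "simulate_cohort",
    "write_cases",
    "make_standard_space_pair",
    "BRAIN_MEAN",
]

BRAIN_MEAN = 100.0  # background brain intensity, arbitrary DWI units

SIZE_LABELS = ("lacune", "non_lacune")
TERRITORY_LABELS = ("anterior", "posterior", "both")


@dataclass(frozen=True)
class LesionSpec:
    """Prescription for the lesion(s) inserted into one phantom case.

    ``diameter_mm`` is the maximal in-plane extent of the primary
    component; ``intensity_contrast`` is the lesion-minus-background mean
    difference in units of the background noise SD.
    """

    diameter_mm: float
    n_components: int = 1
    territory: str = "anterior"
    intensity_contrast: float = 5.0
    center_jitter_mm: float = 2.0

    def __post_init__(self):
        if self.diameter_mm <= 0:
            raise ValueError("diameter_mm must be positive")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.territory not in TERRITORY_LABELS:
            raise ValueError(f"territory must be one of {TERRITORY_LABELS}")
        if self.territory == "both" and self.n_components < 2:
            raise ValueError("territory='both' requires n_components >= 2")
        if self.intensity_contrast <= 0:
            raise ValueError("intensity_contrast must be positive")
        if self.center_jitter_mm < 0:
            raise ValueError("center_jitter_mm must be non-negative")


@dataclass(frozen=True)
class PhantomConfig:
    """Grid geometry and noise level of the phantom generator.

    Defaults keep clinical DWI anisotropy (fine in-plane, 7 mm slices) on a
    grid small enough for CPU training.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 8)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 7.0)
    n_slices_target: int = 8
    background_noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if any(d < 8 for d in self.grid_shape[:2]) or self.grid_shape[2] < 1:
            raise ValueError("grid dims too small (in-plane dims must be >= 8)")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing components must be positive")
        if self.background_noise_sd <= 0:
            raise ValueError("background_noise_sd must be positive")

    def grid_affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.spacing_mm
        # center the world origin in the volume
        aff[:3, 3] = -(np.array(self.grid_shape) - 1) / 2.0 * self.spacing_mm
        return aff


@dataclass
class PatientCase:
    """A generated phantom: volume, ground-truth mask, labels, provenance."""

    volume: DwiVolume
    truth_mask: SegMap
    size_label: str
    territory_label: str
    spec: LesionSpec
    seed: int
    patient_id: str = ""

    def __post_init__(self):
        if self.truth_mask.data.shape != self.volume.data.shape:
            raise ValueError("truth mask grid must equal volume grid")


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _coord_grids_mm(config: PhantomConfig):
    nx, ny, nz = config.grid_shape
    sx, sy, sz = config.spacing_mm
    x = (np.arange(nx) - (nx - 1) / 2.0) * sx
    y = (np.arange(ny) - (ny - 1) / 2.0) * sy
    z = (np.arange(nz) - (nz - 1) / 2.0) * sz
    return np.meshgrid(x, y, z, indexing="ij")


def _brain_ellipsoid(config: PhantomConfig) -> np.ndarray:
    gx, gy, gz = _coord_grids_mm(config)
    nx, ny, nz = config.grid_shape
    sx, sy, sz = config.spacing_mm
    ax = 0.42 * nx * sx
    ay = 0.46 * ny * sy
    az = 0.55 * nz * sz
    return (gx / ax) ** 2 + (gy / ay) ** 2 + (gz / az) ** 2 <= 1.0


def feret_diameter_mm(mask_data: np.ndarray, spacing_mm) -> float:
    """Max in-plane Feret (caliper) diameter over slices, in millimetres.

    Computed per transverse slice from voxel centers (convex hull for
    speed) plus one in-plane voxel to account for voxel extent, then
    maximized over slices. Through-plane extent is deliberately ignored:
    with thick slices it is not the clinically quoted diameter.
    """
    sx, sy = float(spacing_mm[0]), float(spacing_mm[1])
    s_inplane = 0.5 * (sx + sy)
    best = 0.0
    for k in range(mask_data.shape[2]):
        pts = np.argwhere(mask_data[:, :, k])
        if pts.size == 0:
            continue
        coords = pts * np.array([sx, sy])
        if len(coords) == 1:
            d = 0.0
        else:
            if len(coords) > 10:
                try:
                    coords = coords[ConvexHull(coords).vertices]
                except Exception:  # collinear points
                    pass
            d = float(pdist(coords).max())
        best = max(best, d + s_inplane)
    return best


# ---------------------------------------------------------------------------
# Atlas phantom
# ---------------------------------------------------------------------------

def generate_atlas_phantom(config: PhantomConfig, n_regions: int) -> AtlasDefinition:
    """Tile a brain-shaped ellipsoid into labeled regions.

    Label 0 is outside the brain. The anterior half of the brain (low y)
    holds regions 1..ceil(n/2) flagged "anterior"; the rest are
    "posterior". Regions are contiguous x-bands of near-equal voxel count
    within each half, so the construction is deterministic.
    """
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    brain = _brain_ellipsoid(config)
    if n_regions > int(brain.sum()):
        raise ValueError("atlas too fine for grid")
    _, gy, _ = _coord_grids_mm(config)
    anterior_half = brain & (gy < 0)
    posterior_half = brain & (gy >= 0)
    n_ant = math.ceil(n_regions / 2)
    n_post = n_regions - n_ant

    labels = np.zeros(config.grid_shape, dtype=np.int32)
    table: dict[int, tuple[str, str]] = {}

    def tile(half_mask, n_bands, first_id, territory, prefix):
        idx = np.argwhere(half_mask)
        order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0]))  # bands along x
        idx = idx[order]
        chunks = np.array_split(idx, n_bands)
        for b, chunk in enumerate(chunks):
            if len(chunk) == 0:
                raise ValueError("atlas too fine for grid")
            rid = first_id + b
            labels[tuple(chunk.T)] = rid
            table[rid] = (f"{prefix}{b + 1}", territory)

    tile(anterior_half, n_ant, 1, "anterior", "A")
    if n_post:
        tile(posterior_half, n_post, n_ant + 1, "posterior", "P")
    return AtlasDefinition(labels, table, config.spacing_mm,
                           config.grid_affine(), name="phantom_atlas")


# ---------------------------------------------------------------------------
# Case generation
# ---------------------------------------------------------------------------

def _lesion_axes_mm(config: PhantomConfig, diameter_mm: float):
    """In-plane and through-plane semi-axes of a lesion ellipsoid.

    The in-plane semi-axis is diameter/2. The through-plane semi-axis is
    floored so small lesions still occupy their central slice despite thick
    slices, and capped at 9 mm: with 7 mm slices, clinical lesions do not
    extend through-plane as far as in-plane.
    """
    a = diameter_mm / 2.0
    c = max(0.55 * config.spacing_mm[2], min(a, 9.0))
    return a, c


def _ellipsoid_support(config: PhantomConfig, center_vox, diameter_mm: float):
    """Voxels whose centers fall strictly inside the lesion ellipsoid."""
    a, c = _lesion_axes_mm(config, diameter_mm)
    sx, sy, sz = config.spacing_mm
    nx, ny, nz = config.grid_shape
    cx, cy, cz = center_vox
    x = (np.arange(nx) - cx) * sx
    y = (np.arange(ny) - cy) * sy
    z = (np.arange(nz) - cz) * sz
    gx, gy, gz = np.meshgrid(x, y, z, indexing="ij")
    return (gx / a) ** 2 + (gy / a) ** 2 + (gz / c) ** 2 < 1.0


def _place_component(config, allowed: np.ndarray, diameter_mm: float,
                     jitter_mm: float, rng: np.random.Generator):
    """Find a center whose full ellipsoid fits inside ``allowed``."""
    # structure = the lesion support for an integer center, built on its own
    # odd-sized local grid so erosion semantics are exact
    a, c = _lesion_axes_mm(config, diameter_mm)
    sx, sy, sz = config.spacing_mm
    hx, hy, hz = (int(np.ceil(a / sx)), int(np.ceil(a / sy)),
                  int(np.ceil(c / sz)))
    lx = np.arange(-hx, hx + 1) * sx
    ly = np.arange(-hy, hy + 1) * sy
    lz = np.arange(-hz, hz + 1) * sz
    gx, gy, gz = np.meshgrid(lx, ly, lz, indexing="ij")
    structure = (gx / a) ** 2 + (gy / a) ** 2 + (gz / c) ** 2 < 1.0
    if any(s > g for s, g in zip(structure.shape, allowed.shape)):
        raise ValueError("requested diameter larger than the territory extent")
    fits = ndimage.binary_erosion(allowed, structure=structure, border_value=0)
    candidates = np.argwhere(fits)
    if len(candidates) == 0:
        raise ValueError("requested diameter larger than the territory extent")
    base = candidates[rng.integers(len(candidates))].astype(float)
    # sub-voxel in-plane jitter, capped so containment is preserved
    center = base.copy()
    max_j = min(jitter_mm, 0.49 * min(sx, sy))
    if max_j > 0:
        center[0] += rng.uniform(-max_j, max_j) / sx
        center[1] += rng.uniform(-max_j, max_j) / sy
    support = _ellipsoid_support(config, center, diameter_mm)
    if not np.all(allowed[support]):  # jitter pushed an edge voxel out
        support = _ellipsoid_support(config, base, diameter_mm)
    return support


def generate_case(config: PhantomConfig, atlas: AtlasDefinition,
                  spec: LesionSpec, patient_id: str = "",
                  lacune_threshold_mm: float = 20.0) -> PatientCase:
    """Generate one phantom patient with the prescribed lesion(s).

    Deterministic in (config, spec): the generator seeds its own RNG from
    ``config.seed``. Lesion voxels are brighter than the brain background
    by ``intensity_contrast`` background-SDs, and every lesion voxel lies
    inside the requested territory's atlas regions.
    """
    if atlas.labels.shape != tuple(config.grid_shape):
        raise ValueError("atlas grid must equal config grid")
    rng = np.random.default_rng(config.seed)
    brain = atlas.brain_mask()

    if spec.territory == "both":
        terr_masks = [atlas.territory_mask("anterior"),
                      atlas.territory_mask("posterior")]
    else:
        terr_masks = [atlas.territory_mask(spec.territory)]

    lesion = np.zeros(config.grid_shape, dtype=bool)
    secondary = max(0.8 * spec.diameter_mm, 1.6 * min(config.spacing_mm[:2]))
    diameters = [spec.diameter_mm] + [secondary] * (spec.n_components - 1)
    for i, d in enumerate(diameters):
        terr = terr_masks[i % len(terr_masks)]
        # keep components disjoint (2-voxel moat around existing lesion)
        allowed = terr & ~ndimage.binary_dilation(lesion, iterations=2)
        support = _place_component(config, allowed, d,
                                   spec.center_jitter_mm, rng)
        lesion |= support

    if spec.n_components == 1:  # single component: check the diameter contract
        got = feret_diameter_mm(lesion.astype(np.uint8), config.spacing_mm)
        s_in = 0.5 * (config.spacing_mm[0] + config.spacing_mm[1])
        if abs(got - spec.diameter_mm) > s_in + 1e-9:
            raise RuntimeError(
                f"lesion diameter {got:.2f} mm misses spec {spec.diameter_mm} mm")

    data = np.zeros(config.grid_shape)
    data[brain] = BRAIN_MEAN + rng.normal(
        0.0, config.background_noise_sd, size=int(brain.sum()))
    data[lesion] += spec.intensity_contrast * config.background_noise_sd
    data = np.clip(data, 0.1, None)  # keep brain support strictly nonzero
    data[~brain] = 0.0

    affine = config.grid_affine()
    volume = DwiVolume(data, config.spacing_mm, affine, patient_id)
    mask = SegMap(lesion.astype(np.uint8), config.spacing_mm, affine, patient_id)
    size_label, territory_label = derive_labels(
        mask, config.spacing_mm, atlas, lacune_threshold_mm)
    return PatientCase(volume=volume, truth_mask=mask, size_label=size_label,
                       territory_label=territory_label, spec=spec,
                       seed=config.seed, patient_id=patient_id)


def derive_labels(mask: SegMap, spacing_mm, atlas: AtlasDefinition,
                  lacune_threshold_mm: float = 20.0) -> tuple[str, str]:
    """Apply the size and territory labeling rules to a lesion mask.

    Lacune: exactly one 26-connected component whose maximal in-plane
    Feret diameter is at most the threshold; multiple scattered lesions
    are never lacunes. Territory: anterior/posterior when >= 95% of lesion
    voxels fall in that territory's regions, otherwise both.
    """
    data = mask.data.astype(bool)
    if not data.any():
        raise ValueError("no lesion")
    _, n_comp = ndimage.label(data, structure=np.ones((3, 3, 3)))
    if n_comp == 1 and feret_diameter_mm(data, spacing_mm) <= lacune_threshold_mm:
        size_label = "lacune"
    else:
        size_label = "non_lacune"

    total = data.sum()
    frac_ant = np.sum(data & atlas.territory_mask("anterior")) / total
    frac_post = np.sum(data & atlas.territory_mask("posterior")) / total
    if frac_ant >= 0.95:
        territory_label = "anterior"
    elif frac_post >= 0.95:
        territory_label = "posterior"
    else:
        territory_label = "both"
    return size_label, territory_label


# ---------------------------------------------------------------------------
# Cohorts and standard-space pairs
# ---------------------------------------------------------------------------

def simulate_cohort(n_cases: int, config: PhantomConfig,
                    atlas: AtlasDefinition, seed: int,
                    contrast: float = 5.0,
                    both_fraction: float = 0.0) -> list[PatientCase]:
    """Generate a balanced cohort of phantom patients.

    Half the cases are lacunes (single component, 6-16 mm), half
    non-lacunes (60% single territorial 22-26 mm — the phantom brain caps
    the diameter — and 40% multiple scattered embolic-like lesions of
    7-11 mm); territories alternate anterior/posterior, with an optional
    fraction of both-territory cases. Case ``k`` uses config seed
    ``seed*100000 + k`` so cohorts are reproducible and cases distinct.
    """
    rng = np.random.default_rng(seed)
    cases = []
    n_both = int(round(both_fraction * n_cases))
    for k in range(n_cases):
        lacune = k % 2 == 0
        if k < n_both:
            territory, n_comp = "both", 2
            diameter = float(rng.uniform(8, 14))
            lacune = False
        else:
            territory = "anterior" if (k // 2) % 2 == 0 else "posterior"
            if lacune:
                diameter, n_comp = float(rng.uniform(6, 16)), 1
            elif rng.random() < 0.6:
                diameter, n_comp = float(rng.uniform(22, 26)), 1
            else:
                diameter, n_comp = float(rng.uniform(7, 11)), int(rng.integers(2, 4))
        spec = LesionSpec(diameter_mm=diameter, n_components=n_comp,
                          territory=territory, intensity_contrast=contrast)
        case_cfg = replace(config, seed=seed * 100000 + k)
        cases.append(generate_case(case_cfg, atlas, spec,
                                   patient_id=f"case{k:03d}"))
    return cases


def write_cases(cases: list[PatientCase], out_dir) -> pd.DataFrame:
    """Write NIfTI pairs plus a tab-separated manifest; returns the manifest."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, case in enumerate(cases):
        cid = case.patient_id or f"case{i:03d}"
        write_volume(case.volume, out / f"{cid}_dwi.nii.gz")
        write_mask(case.truth_mask, out / f"{cid}_mask.nii.gz")
        rows.append({
            "case_id": cid, "seed": case.seed,
            "diameter_mm": case.spec.diameter_mm,
            "n_components": case.spec.n_components,
            "territory": case.spec.territory,
            "size_label": case.size_label,
            "territory_label": case.territory_label,
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return manifest


def make_standard_space_pair(volume: DwiVolume,
                             translation_mm=(5.0, -3.0, 7.0),
                             rotation_deg: float = 0.0):
    """Create a 'standard space' copy of a native volume with a known affine.

    Returns (standard_volume, true_transform) where the transform maps
    native world coordinates onto standard world coordinates (in-plane
    rotation about the world origin followed by translation).
    """
    th = np.deg2rad(rotation_deg)
    mat = np.eye(4)
    mat[:2, :2] = [[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]]
    mat[:3, 3] = translation_mm
    t = AffineTransform(mat, moving_id=volume.patient_id, fixed_id="standard")
    standard = resample_volume(volume, t, volume)
    standard = standard.replace(patient_id="standard")
    return standard, t
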