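"""Synthetic pelvic CT phantoms with a rectal hydrogel spacer.

The generator emulates the planning-CT anatomy of a prostate case injected
with a hydrogel spacer: an elliptical body with a fat ring, prostate and
seminal vesicles (their union is the CTV), rectum with gas lumen, bladder,
femoral heads, penile bulb, left/right neurovascular bundles (NVB), and a
crescent-shaped spacer interposed between the prostate's posterior surface
and the rectal anterior wall. The NVBs sit posterolateral to the prostate at
spacer depth so that the lateral (+x / -x) treatment beams traverse spacer
and NVB in the same corridor — the geometric condition under which spacer
material errors project onto the NVB dose.

The spacer is generated at soft-tissue intensity (mean 31 HU, the standard
non-contrast hydrogel) and :func:`iodinate_spacer` re-renders it as the
iodinated product: normally distributed HU with mean 120, followed by 3D
Gaussian smoothing confined to the spacer region.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core import ImageGrid, ROISet, require_aligned


def _default_tissue_hu() -> dict[str, float]:
    # representative CT numbers; configurable per phantom
    return {
        "air": -1000.0,
        "body": 20.0,
        "fat": -100.0,
        "prostate": 40.0,
        "seminal_vesicles": 40.0,
        "rectum_wall": 40.0,
        "rectum_lumen": -700.0,
        "bladder": 10.0,
        "bone": 700.0,
        "nvb": 40.0,
        "penile_bulb": 40.0,
        "spacer": 31.0,
    }


def _default_noise_sd() -> dict[str, float]:
    return {
        "air": 5.0,
        "body": 10.0,
        "fat": 10.0,
        "prostate": 10.0,
        "seminal_vesicles": 10.0,
        "rectum_wall": 10.0,
        "rectum_lumen": 15.0,
        "bladder": 10.0,
        "bone": 30.0,
        "nvb": 10.0,
        "penile_bulb": 10.0,
        "spacer": 10.0,
    }


@dataclass
class PhantomParams:
    """Geometry, CT-number and noise settings of one synthetic pelvis.

    Positions are millimetre offsets from the prostate centre (which sits at
    the grid centre); sizes are in mm. Defaults give a desk-scale 240 x 240
    x 160 mm field of view at 2-mm voxels — smaller than a clinical scan
    but large enough to contain the full pelvic geometry.
    """

    shape: tuple[int, int, int] = (120, 120, 80)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)

    prostate_semiaxes: tuple[float, float, float] = (22.0, 20.0, 20.0)
    sv_semiaxes: tuple[float, float, float] = (16.0, 8.0, 10.0)
    sv_offset: tuple[float, float, float] = (0.0, 5.0, 26.0)
    rectum_outer_radius: float = 12.0
    rectum_wall: float = 4.0
    rectum_y: float = 43.0
    rectum_halflength: float = 60.0
    spacer_thickness: float = 10.0
    spacer_arc_deg: float = 120.0
    nvb_radius: float = 5.0
    nvb_offset: tuple[float, float] = (24.0, 14.0)  # (|x|, y) from prostate centre
    nvb_halflength: float = 25.0
    femur_radius: float = 15.0
    femur_x: float = 70.0
    femur_halflength: float = 70.0
    bulb_semiaxes: tuple[float, float, float] = (10.0, 8.0, 8.0)
    bulb_offset: tuple[float, float, float] = (0.0, -5.0, -32.0)
    body_semiaxes: tuple[float, float] = (110.0, 95.0)
    fat_ring_fraction: float = 0.15

    tissue_hu: dict[str, float] = field(default_factory=_default_tissue_hu)
    noise_sd: dict[str, float] = field(default_factory=_default_noise_sd)

    iodinated_hu_mean: float = 120.0
    iodinated_hu_sd: float = 15.0
    smooth_sigma_voxels: float = 1.0

    seed: int = 0

    def validate(self) -> None:
        if self.spacer_thickness <= 0:
            raise ValueError("spacer_thickness must be > 0")
        sizes = (
            *self.prostate_semiaxes, *self.sv_semiaxes, self.rectum_outer_radius,
            self.rectum_wall, self.nvb_radius, self.femur_radius, *self.bulb_semiaxes,
            *self.body_semiaxes,
        )
        if any(s <= 0 for s in sizes):
            raise ValueError("all geometric sizes must be > 0")
        if self.rectum_wall >= self.rectum_outer_radius:
            raise ValueError("rectum wall thickness must be smaller than its outer radius")
        if not (0 < self.spacer_arc_deg <= 180):
            raise ValueError("spacer_arc_deg must lie in (0, 180]")

    @classmethod
    def fine(cls, **overrides) -> "PhantomParams":
        """1-mm-voxel variant of the default phantom (same physical geometry).

        Useful when a structure needs many voxels, e.g. >= 10^4 spacer voxels
        for tight HU-mean checks.
        """
        return cls(shape=(240, 240, 160), spacing=(1.0, 1.0, 1.0), **overrides)

    @classmethod
    def reduced(cls, **overrides) -> "PhantomParams":
        """3-mm-voxel, slightly cropped variant for fast cohort studies."""
        return cls(shape=(72, 72, 56), spacing=(3.0, 3.0, 3.0), **overrides)


def _ellipsoid(dx, dy, dz, semi) -> np.ndarray:
    a, b, c = semi
    return (dx / a) ** 2 + (dy / b) ** 2 + (dz / c) ** 2 <= 1.0


def generate_phantom(params: PhantomParams | None = None) -> tuple[ImageGrid, ROISet]:
    """Build one pelvic HU phantom and its ROI set.

    Deterministic for a fixed ``params.seed``. The spacer ROI is carved to be
    disjoint from CTV, rectum, bladder and NVBs; if the requested geometry
    leaves no spacer at all (e.g. rectum pushed through the spacer gap) a
    ValueError is raised.
    """
    params = params or PhantomParams()
    params.validate()
    shape, spacing = params.shape, params.spacing
    grid_tmp = ImageGrid(np.zeros(shape), spacing)
    # world coordinates relative to the prostate centre (grid centre)
    centre = grid_tmp.index_to_world((np.asarray(shape) - 1) / 2.0)
    x = grid_tmp.axis_coordinates(0) - centre[0]
    y = grid_tmp.axis_coordinates(1) - centre[1]
    z = grid_tmp.axis_coordinates(2) - centre[2]
    X, Y, Z = x[:, None, None], y[None, :, None], z[None, None, :]

    bx, by = params.body_semiaxes
    body_rho = np.sqrt((X / bx) ** 2 + (Y / by) ** 2) + 0.0 * Z
    body = body_rho <= 1.0
    fat = (body_rho <= 1.0) & (body_rho > 1.0 - params.fat_ring_fraction)

    prostate = _ellipsoid(X, Y, Z, params.prostate_semiaxes)
    sv = _ellipsoid(X - params.sv_offset[0], Y - params.sv_offset[1],
                    Z - params.sv_offset[2], params.sv_semiaxes)
    ctv = prostate | sv

    r_rect = np.sqrt(X**2 + (Y - params.rectum_y) ** 2) + 0.0 * Z
    in_len = np.abs(Z + 0.0 * X + 0.0 * Y) <= params.rectum_halflength
    rectum = (r_rect <= params.rectum_outer_radius) & in_len
    lumen = (r_rect <= params.rectum_outer_radius - params.rectum_wall) & in_len

    bladder = _ellipsoid(X, Y + 30.0, Z - 25.0, (24.0, 16.0, 18.0)) & ~ctv

    nx_off, ny_off = params.nvb_offset
    nvb_l = (np.sqrt((X + nx_off) ** 2 + (Y - ny_off) ** 2) <= params.nvb_radius) & (
        np.abs(Z + 0.0 * X + 0.0 * Y) <= params.nvb_halflength) & ~ctv
    nvb_r = (np.sqrt((X - nx_off) ** 2 + (Y - ny_off) ** 2) <= params.nvb_radius) & (
        np.abs(Z + 0.0 * X + 0.0 * Y) <= params.nvb_halflength) & ~ctv

    femur_l = (np.sqrt((X + params.femur_x) ** 2 + Y**2) <= params.femur_radius) & (
        np.abs(Z + 0.0 * X + 0.0 * Y) <= params.femur_halflength)
    femur_r = (np.sqrt((X - params.femur_x) ** 2 + Y**2) <= params.femur_radius) & (
        np.abs(Z + 0.0 * X + 0.0 * Y) <= params.femur_halflength)

    bulb = _ellipsoid(X - params.bulb_offset[0], Y - params.bulb_offset[1],
                      Z - params.bulb_offset[2], params.bulb_semiaxes) & ~ctv

    # spacer: posterior crescent shell on the prostate, one thickness deep
    a, b, c = params.prostate_semiaxes
    rho = np.sqrt((X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2)
    rnorm = np.sqrt(X**2 + Y**2 + Z**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_post = np.where(rnorm > 0, Y / np.maximum(rnorm, 1e-9), 0.0)
    wedge = cos_post >= np.cos(np.deg2rad(params.spacer_arc_deg / 2.0))
    shell = (rho > 1.0) & (rho <= 1.0 + params.spacer_thickness / b)
    spacer = shell & wedge & ~(ctv | rectum | lumen | bladder | nvb_l | nvb_r) & body
    if not spacer.any():
        raise ValueError("spacer geometry fully overlapped by neighbouring structures")

    # corridor check: lateral beams must cross spacer and NVB at shared (y,z)
    sp_fp = spacer.any(axis=0)
    if not ((nvb_l | nvb_r).any(axis=0) & sp_fp).any():
        raise ValueError("NVB does not overlap the lateral-beam corridor through the spacer")

    hu_of = params.tissue_hu
    sd_of = params.noise_sd
    mean_map = np.full(shape, hu_of["air"])
    sd_map = np.full(shape, sd_of["air"])
    # later assignments override earlier ones
    paint = [
        (body, "body"), (fat, "fat"),
        (femur_l, "bone"), (femur_r, "bone"),
        (bladder, "bladder"),
        (rectum, "rectum_wall"), (lumen, "rectum_lumen"),
        (bulb, "penile_bulb"),
        (prostate, "prostate"), (sv, "seminal_vesicles"),
        (nvb_l, "nvb"), (nvb_r, "nvb"),
        (spacer, "spacer"),
    ]
    for mask, tissue in paint:
        mean_map[mask] = hu_of[tissue]
        sd_map[mask] = sd_of[tissue]

    rng = np.random.default_rng(params.seed)
    hu = mean_map + sd_map * rng.standard_normal(shape)
    grid = ImageGrid(hu, spacing, unit="HU")

    rois = ROISet(grid, {
        "prostate": prostate, "seminal_vesicles": sv, "ctv": ctv,
        "rectum": rectum, "bladder": bladder,
        "nvb_left": nvb_l, "nvb_right": nvb_r,
        "femur_left": femur_l, "femur_right": femur_r,
        "penile_bulb": bulb, "spacer": spacer, "body": body,
    })
    rois.validate_canonical()
    return grid, rois


def iodinate_spacer(
    hu: ImageGrid,
    spacer_mask: np.ndarray,
    mean_hu: float = 120.0,
    sd_hu: float = 15.0,
    smooth_sigma: float = 1.0,
    seed: int = 0,
) -> ImageGrid:
    """Re-render the spacer as iodinated hydrogel on a copy of the HU grid.

    In-mask voxels are replaced by Normal(mean_hu, sd_hu) draws; a 3D
    Gaussian smoothing of ``smooth_sigma`` voxels is then applied to the
    spacer region using mask-normalized convolution (so the in-mask mean is
    preserved and no anatomy leaks in). A single one-voxel rim outside the
    mask is blended; all other voxels are untouched.
    """
    spacer_mask = np.asarray(spacer_mask, dtype=bool)
    if spacer_mask.shape != hu.shape:
        raise ValueError("spacer mask shape does not match grid")
    if not spacer_mask.any():
        raise ValueError("spacer mask is empty")
    if sd_hu < 0:
        raise ValueError("sd_hu must be >= 0")
    rng = np.random.default_rng(seed)
    out = hu.values.copy()
    draws = mean_hu + sd_hu * rng.standard_normal(int(spacer_mask.sum()))
    if smooth_sigma <= 0:
        out[spacer_mask] = draws
        return hu.like(out, unit="HU")

    w = spacer_mask.astype(np.float64)
    vals = np.zeros_like(w)
    vals[spacer_mask] = draws
    num = ndimage.gaussian_filter(vals, smooth_sigma)
    den = ndimage.gaussian_filter(w, smooth_sigma)
    with np.errstate(invalid="ignore", divide="ignore"):
        smoothed = np.where(den > 1e-6, num / np.maximum(den, 1e-12), 0.0)
    out[spacer_mask] = smoothed[spacer_mask]
    rim = ndimage.binary_dilation(spacer_mask) & ~spacer_mask
    # blend rim toward the smoothed spacer value by its smoothed mask weight
    alpha = np.clip(den[rim], 0.0, 1.0)
    out[rim] = (1.0 - alpha) * out[rim] + alpha * smoothed[rim]
    return hu.like(out, unit="HU")


@dataclass
class PhantomCase:
    """One realized cohort member."""

    case_id: str
    params: PhantomParams
    hu: ImageGrid
    rois: ROISet


def case_seed(master_seed: int, index: int) -> int:
    """Fixed per-case child-seed arithmetic, auditable from the manifest."""
    return master_seed * 1000 + index


def jitter_params(
    base: PhantomParams,
    index: int,
    master_seed: int,
    size_jitter: float = 0.10,
    position_jitter_mm: float = 3.0,
) -> PhantomParams:
    """Per-case geometry perturbation: sizes +-10%, positions +-3 mm."""
    seed = case_seed(master_seed, index)
    rng = np.random.default_rng(seed + 500_000)

    def s(v):  # size scale
        return v * (1.0 + size_jitter * rng.uniform(-1, 1))

    def pos(v):
        return v + position_jitter_mm * rng.uniform(-1, 1)

    return dataclasses.replace(
        base,
        prostate_semiaxes=tuple(s(v) for v in base.prostate_semiaxes),
        sv_semiaxes=tuple(s(v) for v in base.sv_semiaxes),
        sv_offset=tuple(pos(v) for v in base.sv_offset),
        rectum_outer_radius=s(base.rectum_outer_radius),
        rectum_y=pos(base.rectum_y),
        spacer_thickness=s(base.spacer_thickness),
        nvb_offset=tuple(pos(v) for v in base.nvb_offset),
        bulb_offset=tuple(pos(v) for v in base.bulb_offset),
        seed=seed,
    )


def generate_cohort(
    n_cases: int,
    base_params: PhantomParams | None = None,
    master_seed: int = 1,
    size_jitter: float = 0.10,
    position_jitter_mm: float = 3.0,
) -> list[PhantomCase]:
    """Realize a cohort of phantoms with jittered geometry and derived seeds."""
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    base = base_params or PhantomParams()
    cases = []
    for i in range(n_cases):
        params = jitter_params(base, i, master_seed, size_jitter, position_jitter_mm)
        hu, rois = generate_phantom(params)
        cases.append(PhantomCase(case_id=f"case{i:03d}", params=params, hu=hu, rois=rois))
    return cases


def cohort_manifest(cases: list[PhantomCase], path: str | Path | None = None) -> dict:
    """JSON-able manifest of per-case parameters (and optionally write it)."""
    manifest = {
        c.case_id: {
            "seed": c.params.seed,
            "params": {
                k: v for k, v in dataclasses.asdict(c.params).items()
                if not isinstance(v, dict)
            },
            "spacer_voxels": int(c.rois["spacer"].sum()),
        }
        for c in cases
    }
    if path is not None:
        Path(path).write_text(json.dumps(manifest, indent=1, default=list))
    return manifest
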