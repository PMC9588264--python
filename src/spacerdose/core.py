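"""Shared domain types and volume I/O.

All volumes live on axis-aligned voxel grids. The axis convention is fixed:
x runs patient-left to patient-right, y anterior to posterior, z inferior to
superior (an LPS-like frame), so the two lateral treatment beams travel along
the +x and -x directions. Indices are 0-based and voxel-centered: the world
coordinate of voxel ``(i, j, k)`` is ``origin + index * spacing``. Lengths are
millimetres throughout; dose is carried in cGy.

Volumes interchange as NIfTI (via nibabel) with a small JSON sidecar holding
the unit tag, because NIfTI has no dose-unit field.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import nibabel as nib
import numpy as np

#: Unit tags an ImageGrid may carry.
VALID_UNITS = ("HU", "SPR", "cGy", "gamma", "unitless")

#: Canonical ROI names used by the phantom generator and the pipeline.
CANONICAL_ROIS = (
    "prostate",
    "seminal_vesicles",
    "ctv",
    "rectum",
    "bladder",
    "nvb_left",
    "nvb_right",
    "femur_left",
    "femur_right",
    "penile_bulb",
    "spacer",
    "body",
)


class AlignmentError(ValueError):
    """Two grids/masks that must share a voxel lattice do not."""


@dataclass
class ImageGrid:
    """A 3D scalar volume with voxel spacing and world origin.

    Parameters
    ----------
    values
        3D array of voxel values (float).
    spacing
        Voxel size ``(dx, dy, dz)`` in mm; all components must be positive.
    origin
        World coordinate of voxel ``(0, 0, 0)`` in mm.
    unit
        One of :data:`VALID_UNITS`.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    unit: str = "unitless"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of (possibly fractional) voxel indices."""
        return np.asarray(self.origin) + np.asarray(index, dtype=float) * np.asarray(self.spacing)

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        """Continuous voxel indices of world coordinates (mm)."""
        return (np.asarray(world, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def axis_coordinates(self, axis: int) -> np.ndarray:
        """Voxel-center world coordinates along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]

    def like(self, values: np.ndarray, unit: str | None = None) -> "ImageGrid":
        """A new grid sharing this grid's geometry."""
        return ImageGrid(values, self.spacing, self.origin, unit or self.unit)


def assert_aligned(a: ImageGrid, b: ImageGrid) -> bool:
    """True iff two grids share shape, spacing (1e-6 mm) and origin (1e-3 mm)."""
    if a.shape != b.shape:
        return False
    if any(abs(sa - sb) > 1e-6 for sa, sb in zip(a.spacing, b.spacing)):
        return False
    if any(abs(oa - ob) > 1e-3 for oa, ob in zip(a.origin, b.origin)):
        return False
    return True


def require_aligned(a: ImageGrid, b: ImageGrid, what: str = "grids") -> None:
    if not assert_aligned(a, b):
        raise AlignmentError(
            f"{what} are not aligned: shapes {a.shape} vs {b.shape}, "
            f"spacings {a.spacing} vs {b.spacing}, origins {a.origin} vs {b.origin}"
        )


@dataclass
class ROISet:
    """Named boolean masks sharing one reference grid's voxel lattice."""

    grid: ImageGrid
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, mask in list(self.masks.items()):
            self.masks[name] = self._check(name, mask)

    def _check(self, name: str, mask: np.ndarray) -> np.ndarray:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.grid.shape:
            raise AlignmentError(
                f"mask {name!r} shape {mask.shape} does not match grid {self.grid.shape}"
            )
        if not mask.any():
            raise ValueError(f"mask {name!r} is empty")
        return mask

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def __iter__(self) -> Iterator[str]:
        return iter(self.masks)

    def add(self, name: str, mask: np.ndarray) -> None:
        self.masks[name] = self._check(name, mask)

    def names(self) -> list[str]:
        return list(self.masks)

    def validate_canonical(self) -> None:
        """Check cross-structure invariants for the canonical pelvic ROI set.

        The clinical target volume is defined as prostate plus seminal
        vesicles, and the spacer must never intersect it.
        """
        if all(n in self for n in ("ctv", "prostate", "seminal_vesicles")):
            union = self["prostate"] | self["seminal_vesicles"]
            if not np.array_equal(self["ctv"], union):
                raise ValueError("ctv mask must equal prostate union seminal_vesicles")
        if "ctv" in self and "spacer" in self and (self["ctv"] & self["spacer"]).any():
            raise ValueError("spacer mask intersects the CTV")


@dataclass(frozen=True)
class Ray:
    """A straight sampling ray: entry point (mm), unit direction, step (mm)."""

    entry: tuple[float, float, float]
    direction: tuple[float, float, float]
    step: float = 1.0

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        norm = float(np.linalg.norm(d))
        if not np.isclose(norm, 1.0, atol=1e-9):
            raise ValueError(f"direction must be a unit vector, |d| = {norm}")
        if self.step <= 0:
            raise ValueError("step length must be > 0")


# -- I/O ------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_volume(grid: ImageGrid, path: str | Path, extra_sidecar: Mapping | None = None) -> Path:
    """Write a grid as NIfTI plus a JSON sidecar holding the unit tag."""
    path = Path(path)
    affine = np.diag(list(grid.spacing) + [1.0])
    affine[:3, 3] = grid.origin
    img = nib.Nifti1Image(grid.values.astype(np.float32), affine)
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))
    sidecar = {"unit": grid.unit}
    if extra_sidecar:
        sidecar.update(extra_sidecar)
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_volume(path: str | Path) -> ImageGrid:
    """Read a NIfTI volume written by :func:`write_volume`.

    The unit tag comes from the JSON sidecar when present, otherwise
    ``unitless``. Non-positive spacings in the header raise.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"volume file not found: {path}")
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(s <= 0 for s in spacing):
        raise ValueError(f"non-positive voxel spacing in header of {path}: {spacing}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    unit = "unitless"
    sc = _sidecar_path(path)
    if sc.exists():
        unit = json.loads(sc.read_text()).get("unit", "unitless")
    values = np.asanyarray(img.dataobj, dtype=np.float64)
    return ImageGrid(values, spacing, origin, unit)


def write_mask(mask: np.ndarray, grid: ImageGrid, path: str | Path) -> Path:
    """Write a boolean mask as uint8 (0/1) NIfTI on a grid's geometry."""
    path = Path(path)
    affine = np.diag(list(grid.spacing) + [1.0])
    affine[:3, 3] = grid.origin
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine)
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))
    return path


def read_mask(path: str | Path, grid: ImageGrid) -> np.ndarray:
    """Read a uint8 mask NIfTI and check it matches a grid's lattice."""
    vol = read_volume(path)
    require_aligned(vol, grid, "mask and grid")
    return vol.values > 0.5


def mask_volume_cc(mask: np.ndarray, grid: ImageGrid) -> float:
    """Absolute volume of a mask in cm^3 on a grid's lattice."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.shape:
        raise AlignmentError(
            f"mask shape {mask.shape} does not match grid shape {grid.shape}"
        )
    return float(mask.sum()) * grid.voxel_volume_mm3 / 1000.0
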