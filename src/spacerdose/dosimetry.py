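"""DVH construction, dosimetric indices, and constraint reporting.

Conventions: Dx is the minimum dose received by the hottest x% of a
structure (exact order statistics on raw voxel doses, not binned); Vd is the
volume — relative or absolute — receiving at least dose d; the equivalent
uniform dose is the generalized power mean

    EUD_a = ( sum_i n_i d_i^a )^(1/a)

over DVH bins with fractional volumes n_i, with a < 0 for targets (cold
spots dominate) and a > 0 for serial organs at risk (hot spots dominate).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .core import ImageGrid, ROISet, mask_volume_cc


@dataclass
class DVHCurve:
    """Differential and cumulative dose-volume histogram of one structure."""

    edges_cGy: np.ndarray        # uniform bin edges, len n_bins + 1
    differential: np.ndarray     # fraction of structure per bin, sums to 1
    volume_cc: float

    def __post_init__(self) -> None:
        self.edges_cGy = np.asarray(self.edges_cGy, dtype=float)
        self.differential = np.asarray(self.differential, dtype=float)
        if self.differential.size != self.edges_cGy.size - 1:
            raise ValueError("differential length must be len(edges) - 1")
        if np.any(self.differential < 0):
            raise ValueError("differential fractions must be >= 0")
        total = self.differential.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"differential fractions sum to {total}, expected 1")

    @property
    def bin_centers_cGy(self) -> np.ndarray:
        return 0.5 * (self.edges_cGy[:-1] + self.edges_cGy[1:])

    def cumulative(self, dose_cGy) -> np.ndarray | float:
        """V(d): fraction of the structure receiving at least d (V(0) = 1).

        A bin counts toward V(d) when its lower edge is >= d, so the binned
        curve agrees with the exact sort-based curve to within one bin.
        """
        d = np.atleast_1d(np.asarray(dose_cGy, dtype=float))
        out = np.array([self.differential[self.edges_cGy[:-1] >= di].sum() for di in d])
        out[d <= self.edges_cGy[0]] = 1.0
        return float(out[0]) if np.isscalar(dose_cGy) else out


def dvh(dose: ImageGrid, mask: np.ndarray, bin_width_cGy: float = 10.0) -> DVHCurve:
    """Differential DVH of in-mask voxel doses with uniform bins."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dose.shape:
        raise ValueError("mask shape does not match dose grid")
    if not mask.any():
        raise ValueError("empty structure mask")
    doses = dose.values[mask]
    # extend one bin beyond the maximum so the hottest voxels occupy a bin
    # whose lower edge is at or above every dose they exceed
    top = max(float(doses.max()), bin_width_cGy) + bin_width_cGy
    edges = np.arange(0.0, top + bin_width_cGy, bin_width_cGy)
    counts, _ = np.histogram(doses, bins=edges)
    return DVHCurve(edges, counts / counts.sum(), mask_volume_cc(mask, dose))


def d_at_percent(doses: np.ndarray | ImageGrid, x: float, mask: np.ndarray | None = None) -> float:
    """Dx: minimum dose (cGy) covering the hottest x% of the structure."""
    if not (0 < x <= 100):
        raise ValueError("x must lie in (0, 100]")
    if isinstance(doses, ImageGrid):
        if mask is None:
            raise ValueError("a mask is required with an ImageGrid input")
        doses = doses.values[np.asarray(mask, dtype=bool)]
    doses = np.asarray(doses, dtype=float).ravel()
    if doses.size == 0:
        raise ValueError("empty structure")
    srt = np.sort(doses)[::-1]  # hottest first
    k = int(np.ceil(x / 100.0 * srt.size)) - 1
    return float(srt[k])


def mean_dose(doses: np.ndarray | ImageGrid, mask: np.ndarray | None = None) -> float:
    if isinstance(doses, ImageGrid):
        if mask is None:
            raise ValueError("a mask is required with an ImageGrid input")
        doses = doses.values[np.asarray(mask, dtype=bool)]
    doses = np.asarray(doses, dtype=float).ravel()
    if doses.size == 0:
        raise ValueError("empty structure")
    return float(doses.mean())


def eud(curve: DVHCurve | np.ndarray, a: float, zero_floor_cGy: float = 0.1) -> float:
    """Equivalent uniform dose of a DVH (or raw voxel doses) with exponent a.

    For a < 0 the power mean is singular at zero dose, so zero-dose bins are
    floored at ``zero_floor_cGy`` (0.1 cGy) before exponentiation; targets
    receiving near-prescription doses are unaffected by the floor.
    """
    if a == 0:
        raise ValueError("a = 0 is not defined for this power-mean EUD")
    if isinstance(curve, DVHCurve):
        d = curve.bin_centers_cGy.copy()
        n = curve.differential
    else:
        d = np.asarray(curve, dtype=float).ravel().copy()
        if d.size == 0:
            raise ValueError("empty structure")
        n = np.full(d.size, 1.0 / d.size)
    if np.any(d < 0):
        raise ValueError("doses must be >= 0")
    if a < 0:
        d = np.maximum(d, zero_floor_cGy)
    nz = n > 0
    return float((n[nz] * d[nz] ** a).sum() ** (1.0 / a))


#: Structure-specific EUD exponents: a = -10 for targets, a = 8 for the
#: serial OARs compared in the study.
EUD_EXPONENTS: dict[str, float] = {
    "prostate": -10.0,
    "seminal_vesicles": -10.0,
    "ctv": -10.0,
    "rectum": 8.0,
    "bladder": 8.0,
    "nvb": 8.0,
    "nvb_left": 8.0,
    "nvb_right": 8.0,
}


def dose_indices(dose: ImageGrid, mask: np.ndarray, roi_name: str | None = None) -> dict[str, float]:
    """The study's index set for one structure: D02..D98, Dmean, and EUD."""
    doses = dose.values[np.asarray(mask, dtype=bool)]
    out = {f"D{x:02d}": d_at_percent(doses, x) for x in (2, 5, 20, 50, 95, 98)}
    out["Dmean"] = mean_dose(doses)
    a = EUD_EXPONENTS.get(roi_name or "", None)
    if a is not None:
        out["EUD"] = eud(doses, a)
    return out


# -- institutional constraints -------------------------------------------

def load_constraints(path=None) -> list[dict]:
    """Load the constraint table (bundled institutional defaults if no path)."""
    if path is None:
        text = resources.files("spacerdose.data").joinpath("constraints.yaml").read_text()
    else:
        text = open(path).read()
    rules = yaml.safe_load(text)
    for r in rules:
        if "roi" not in r or "type" not in r:
            raise ValueError(f"malformed constraint rule: {r}")
        if r["type"] not in ("V_rel", "V_abs", "mean", "D_cc"):
            raise ValueError(f"unknown constraint type {r['type']!r} in rule {r}")
    return rules


def _evaluate_rule(dose: ImageGrid, rois: ROISet, rule: dict) -> dict:
    roi = rule["roi"]
    row = {"roi": roi, "type": rule["type"], "verdict": "skip", "value": np.nan}
    if roi not in rois:
        return row
    mask = rois[roi]
    doses = dose.values[mask]
    kind = rule["type"]
    if kind == "V_rel":
        d_cGy = rule["dose_gy"] * 100.0
        value = 100.0 * float((doses >= d_cGy).mean())
        limit, unit = rule["limit_pct"], "%"
        row.update(rule=f"V{rule['dose_gy']:g}Gy < {limit}%")
    elif kind == "V_abs":
        d_cGy = rule["dose_gy"] * 100.0
        vox_cc = dose.voxel_volume_mm3 / 1000.0
        value = float((doses >= d_cGy).sum()) * vox_cc
        limit, unit = rule["limit_cc"], "cc"
        row.update(rule=f"V{rule['dose_gy']:g}Gy < {limit} cm3")
    elif kind == "mean":
        value = float(doses.mean()) / 100.0
        limit, unit = rule["limit_gy"], "Gy"
        row.update(rule=f"mean < {limit} Gy")
    else:  # D_cc: min dose of the hottest `volume_cc` of the structure
        vox_cc = dose.voxel_volume_mm3 / 1000.0
        n = max(1, int(np.ceil(rule["volume_cc"] / vox_cc)))
        value = float(np.sort(doses)[::-1][min(n, doses.size) - 1]) / 100.0
        limit, unit = rule["limit_gy"], "Gy"
        row.update(rule=f"D{rule['volume_cc']:g}cm3 < {limit} Gy")
    row.update(value=value, limit=limit, unit=unit,
               verdict="pass" if value < limit else "fail")
    return row


def constraint_report(
    doses: dict[str, ImageGrid] | ImageGrid,
    rois: ROISet,
    rules: list[dict] | None = None,
) -> pd.DataFrame:
    """Evaluate the OAR/body constraint table per scenario dose grid.

    Accepts either one dose grid or a mapping scenario -> grid. Missing ROIs
    yield 'skip' rows rather than errors.
    """
    rules = rules if rules is not None else load_constraints()
    if isinstance(doses, ImageGrid):
        doses = {"": doses}
    rows = []
    for scenario, dose in doses.items():
        for rule in rules:
            row = _evaluate_rule(dose, rois, rule)
            row["scenario"] = scenario
            rows.append(row)
    cols = ["scenario", "roi", "rule", "value", "limit", "unit", "verdict", "type"]
    return pd.DataFrame(rows).reindex(columns=cols)
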