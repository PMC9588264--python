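"""Material physics: compositions, proton stopping-power ratios, effective Z,
HU-to-SPR calibration, and the three spacer-material scenarios.

The study design compares proton dose under three ways of assigning the
spacer's stopping power:

* **NM** (no material override): the spacer keeps the stopping power implied
  by its CT number through the HU->SPR calibration curve. An iodinated spacer
  reads ~120 HU, so the curve treats it as a dense tissue — the error
  mechanism the analysis quantifies.
* **WM** (water override): spacer SPR forced to exactly 1.0.
* **TM** (true material override): spacer SPR computed from its elemental
  composition via Bethe theory — the ground truth.

The hydrogel spacer is 88% water, 0.7% trilysine, 10.1% PEG and 1.2% iodine
by weight at 1.03 g/cm^3; its theoretical SPR at 198.3 MeV is ~1.02-1.03,
well below the ~1.11 the calibration curve assigns to 120 HU.

Mean excitation energies use the Bragg additivity rule over electron
fractions with the ICRU condensed-compound constituent I-values (H 19.2,
C 81, N 82, O 106 eV, ...). The water reference stopping number is computed
by the same rule (giving I_w ~= 75.3 eV), so the SPR of water itself is
exactly 1 by construction and density scaling at fixed composition is exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .core import ImageGrid, ROISet

#: symbol -> (Z, atomic weight, mean excitation energy eV).
#: I-values follow the ICRU additivity convention for constituents of
#: condensed compounds (hence C 81 and O 106 rather than the elemental
#: 78 / 95 used for pure substances).
ELEMENTS: dict[str, tuple[int, float, float]] = {
    "H": (1, 1.008, 19.2),
    "C": (6, 12.011, 81.0),
    "N": (7, 14.007, 82.0),
    "O": (8, 15.999, 106.0),
    "F": (9, 18.998, 112.0),
    "Na": (11, 22.990, 149.0),
    "Mg": (12, 24.305, 156.0),
    "P": (15, 30.974, 173.0),
    "S": (16, 32.06, 180.0),
    "Cl": (17, 35.45, 174.0),
    "K": (19, 39.098, 190.0),
    "Ca": (20, 40.078, 191.0),
    "Fe": (26, 55.845, 286.0),
    "I": (53, 126.904, 491.0),
}

#: Molecular formulas for the named components a spacer recipe may use.
#: Trilysine is three lysines joined by two peptide bonds (3 x C6H14N2O2
#: minus 2 x H2O); PEG is represented by its ethylene-oxide repeat unit.
COMPONENT_FORMULAS: dict[str, dict[str, int]] = {
    "water": {"H": 2, "O": 1},
    "trilysine": {"C": 18, "H": 38, "N": 6, "O": 4},
    "peg": {"C": 2, "H": 4, "O": 1},
}

PROTON_REST_ENERGY_MEV = 938.272
ELECTRON_REST_ENERGY_EV = 0.51099895e6


@dataclass(frozen=True)
class MaterialSpec:
    """Elemental weight fractions plus mass density."""

    name: str
    weight_fractions: Mapping[str, float]
    density: float  # g/cm^3

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"density must be > 0, got {self.density}")
        if not self.weight_fractions:
            raise ValueError("empty composition")
        total = 0.0
        for sym, w in self.weight_fractions.items():
            if sym not in ELEMENTS:
                raise ValueError(f"unknown element symbol {sym!r}")
            if w < 0:
                raise ValueError(f"negative weight fraction for {sym}")
            total += w
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"weight fractions sum to {total}, expected 1")

    # electrons per gram, relative quantities -----------------------------
    @property
    def z_over_a(self) -> float:
        """Mean Z/A (mol electrons per gram of material)."""
        return sum(w * ELEMENTS[s][0] / ELEMENTS[s][1] for s, w in self.weight_fractions.items())

    def electron_fractions(self) -> dict[str, float]:
        """Fraction of the material's electrons contributed by each element."""
        za = self.z_over_a
        return {
            s: w * ELEMENTS[s][0] / ELEMENTS[s][1] / za
            for s, w in self.weight_fractions.items()
        }

    @property
    def mean_excitation_energy_eV(self) -> float:
        """Bragg-additivity log-mean I over electron fractions."""
        ef = self.electron_fractions()
        return float(np.exp(sum(f * np.log(ELEMENTS[s][2]) for s, f in ef.items())))


def _formula_weight_fractions(formula: Mapping[str, int]) -> dict[str, float]:
    mass = sum(ELEMENTS[s][1] * n for s, n in formula.items())
    return {s: ELEMENTS[s][1] * n / mass for s, n in formula.items()}


WATER = MaterialSpec("water", _formula_weight_fractions(COMPONENT_FORMULAS["water"]), 1.0)


def material_from_components(
    components: Mapping[str, float], density: float, name: str = "custom"
) -> MaterialSpec:
    """Build a MaterialSpec from named components or raw element symbols.

    ``components`` maps component names (``water``, ``trilysine``, ``PEG``,
    case-insensitive) or element symbols to weight fractions, which must sum
    to 1 within 1e-4 (then renormalized exactly).

    >>> spacer = material_from_components(
    ...     {"water": 0.88, "trilysine": 0.007, "PEG": 0.101, "I": 0.012}, 1.03)
    """
    total = float(sum(components.values()))
    if abs(total - 1.0) > 1e-4:
        raise ValueError(f"component fractions sum to {total}, expected 1 (+-1e-4)")
    elem: dict[str, float] = {}
    for comp, w in components.items():
        key = comp.lower()
        if key in COMPONENT_FORMULAS:
            sub = _formula_weight_fractions(COMPONENT_FORMULAS[key])
        elif comp in ELEMENTS:
            sub = {comp: 1.0}
        else:
            raise ValueError(
                f"unknown component {comp!r}; expected one of "
                f"{sorted(COMPONENT_FORMULAS)} or an element symbol"
            )
        for s, f in sub.items():
            elem[s] = elem.get(s, 0.0) + (w / total) * f
    # renormalize to absorb float round-off
    s_total = sum(elem.values())
    elem = {s: f / s_total for s, f in elem.items()}
    return MaterialSpec(name, elem, density)


def spacer_material(density: float = 1.03) -> MaterialSpec:
    """The iodinated hydrogel spacer's true composition."""
    return material_from_components(
        {"water": 0.88, "trilysine": 0.007, "PEG": 0.101, "I": 0.012},
        density,
        name="iodinated_hydrogel_spacer",
    )


def _stopping_number(i_eV: float, beta2: float) -> float:
    """Bethe stopping number L = ln(2 m_e c^2 beta^2 / (I (1-beta^2))) - beta^2."""
    return float(np.log(2.0 * ELECTRON_REST_ENERGY_EV * beta2 / (i_eV * (1.0 - beta2))) - beta2)


def compute_spr(material: MaterialSpec, energy_MeV: float = 198.3) -> float:
    """Proton stopping-power ratio of a material relative to water.

    SPR = (relative electron density) x L_material / L_water with the Bethe
    stopping number L evaluated at the proton's beta^2 and each medium's
    Bragg-additivity mean excitation energy. Valid for 1-300 MeV protons.
    """
    if not (1.0 <= energy_MeV <= 300.0):
        raise ValueError(f"energy {energy_MeV} MeV outside supported band [1, 300]")
    if material.z_over_a <= 0:
        raise ValueError("material has zero electron density")
    gamma = 1.0 + energy_MeV / PROTON_REST_ENERGY_MEV
    beta2 = 1.0 - 1.0 / gamma**2
    rel_e_density = material.density * material.z_over_a / (WATER.density * WATER.z_over_a)
    l_mat = _stopping_number(material.mean_excitation_energy_eV, beta2)
    l_wat = _stopping_number(WATER.mean_excitation_energy_eV, beta2)
    return rel_e_density * l_mat / l_wat


def effective_z(material: MaterialSpec, exponent: float = 3.5) -> float:
    """Power-law effective atomic number over electron fractions.

    Z_eff = (sum_i f_i Z_i^m)^(1/m) with f_i the electron fractions. The
    default exponent m = 3.5 is the photoelectric-regime convention.
    """
    if exponent <= 0:
        raise ValueError("exponent must be > 0")
    ef = material.electron_fractions()
    return float(sum(f * ELEMENTS[s][0] ** exponent for s, f in ef.items()) ** (1.0 / exponent))


# -- HU -> SPR calibration ------------------------------------------------

#: Representative soft-tissue/bone calibration knots. Institutional curves
#: are scanner-specific and not public; only the qualitative property
#: SPR(120 HU) > SPR_TM > 1.0 matters to the scenario comparison.
DEFAULT_HU_CURVE_KNOTS: tuple[tuple[float, float], ...] = (
    (-1000.0, 0.001),
    (-100.0, 0.93),
    (0.0, 1.00),
    (100.0, 1.10),
    (1600.0, 1.85),
)


@dataclass(frozen=True)
class HUCurve:
    """Piecewise-linear HU -> SPR calibration, clamped outside the knots."""

    knots: tuple[tuple[float, float], ...] = DEFAULT_HU_CURVE_KNOTS

    def __post_init__(self) -> None:
        if len(self.knots) < 2:
            raise ValueError("calibration curve needs at least 2 knots")
        hu = np.array([k[0] for k in self.knots])
        spr = np.array([k[1] for k in self.knots])
        if not np.all(np.diff(hu) > 0):
            raise ValueError("HU knots must be strictly increasing")
        if not np.all(np.diff(spr) >= 0):
            raise ValueError("SPR knots must be non-decreasing")
        if abs(self(0.0) - 1.0) > 1e-6:
            raise ValueError("curve must map 0 HU (water) to SPR 1.0")

    def __call__(self, hu):
        hu_k = np.array([k[0] for k in self.knots])
        spr_k = np.array([k[1] for k in self.knots])
        out = np.interp(np.asarray(hu, dtype=float), hu_k, spr_k)
        return float(out) if np.isscalar(hu) else out


def hu_to_spr(hu, curve: HUCurve | None = None):
    """Map HU values (scalar, array, or ImageGrid) through a calibration curve."""
    curve = curve or HUCurve()
    if isinstance(hu, ImageGrid):
        return hu.like(curve(hu.values), unit="SPR")
    return curve(hu)


# -- scenarios ------------------------------------------------------------

SCENARIOS = ("NM", "WM", "TM")


@dataclass(frozen=True)
class Scenario:
    """Spacer-material scenario: NM, WM, or TM (with the true composition)."""

    kind: str
    spacer: MaterialSpec | None = None

    def __post_init__(self) -> None:
        if self.kind not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}, got {self.kind!r}")
        if self.kind == "TM" and self.spacer is None:
            object.__setattr__(self, "spacer", spacer_material())


def build_spr_grid(
    hu: ImageGrid,
    rois: ROISet,
    scenario: Scenario | str,
    curve: HUCurve | None = None,
    energy_MeV: float = 198.3,
) -> ImageGrid:
    """SPR grid for one scenario: calibration curve everywhere, with the
    spacer region overridden according to the scenario.

    NM leaves the spacer on the curve (so iodinated HU reads as dense
    tissue); WM forces spacer SPR to 1.0; TM assigns the composition-derived
    theoretical SPR.
    """
    if isinstance(scenario, str):
        scenario = Scenario(scenario)
    if "spacer" not in rois:
        raise ValueError("ROISet must contain a 'spacer' mask")
    curve = curve or HUCurve()
    spr = curve(hu.values)
    mask = rois["spacer"]
    if scenario.kind == "WM":
        spr[mask] = 1.0
    elif scenario.kind == "TM":
        spr[mask] = compute_spr(scenario.spacer, energy_MeV)
    return hu.like(spr, unit="SPR")
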