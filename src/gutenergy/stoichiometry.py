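"""Chemical-oxygen-demand (COD) stoichiometry for dietary energy accounting.

COD counts the electron equivalents in organic matter as the grams of O2
needed to oxidize it fully, with organic nitrogen leaving as ammonia (humans
do not use ammonia as an electron donor, so it is excluded from the demand).
That makes grams of COD a common currency for tracking energy flow between
the diet, the host, the gut microbes, and feces: for a compound CcHhOoNn the
theoretical oxygen demand (ThOD) follows from the combustion balance

    CcHhOoNn + (c + (h - 3n)/4 - o/2) O2  ->  c CO2 + n NH3 + ((h - 3n)/2) H2O

so ThOD per gram is ``M_O2 * (c + (h - 3n)/4 - o/2) / M`` for molar mass M.

The module converts macronutrient intakes (g/day) into a five-class COD
vector -- available sugar+starch, resistant starch (RS), non-starch
polysaccharide (NSP, fiber), protein, fat -- and back to kcal through a
diet-specific kcal-per-gCOD ratio.  Per-class gCOD/g factors are recomputed
from :func:`thod_per_gram` on representative compounds at load time rather
than hard-coded.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources
from typing import Mapping

import yaml

__all__ = [
    "ATOMIC_MASS",
    "O2_MOLAR_MASS",
    "InvalidFormulaError",
    "InvalidProfileError",
    "ConfigurationError",
    "ElementalFormula",
    "MacronutrientProfile",
    "CODVector",
    "CODCoefficients",
    "compound_library",
    "default_coefficients",
    "thod_per_gram",
    "intake_to_cod",
    "kcal_per_gcod",
    "cod_to_kcal",
    "scfa_mass_to_cod",
    "scfa_cod_factors",
    "SCFA_COMPOUNDS",
]

ATOMIC_MASS: Mapping[str, float] = {"C": 12.011, "H": 1.008, "O": 15.999, "N": 14.007}
O2_MOLAR_MASS = 2.0 * ATOMIC_MASS["O"]

#: compound-library entry backing each short-chain fatty acid
SCFA_COMPOUNDS = {
    "acetate": "acetic-acid",
    "propionate": "propionic-acid",
    "n_butyrate": "n-butyric-acid",
    "iso_butyrate": "iso-butyric-acid",
}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class InvalidFormulaError(ValueError):
    """Raised for negative atom counts, bad molar mass, or unparsable formulas."""


class InvalidProfileError(ValueError):
    """Raised when a macronutrient profile violates its invariants."""


class ConfigurationError(ValueError):
    """Raised for invalid conversion settings (e.g. non-positive kcal/gCOD)."""


@dataclass(frozen=True)
class ElementalFormula:
    """Elemental composition of a compound restricted to C, H, O, N.

    ``molar_mass`` may be given (e.g. a tabulated value); it must then lie
    within 0.5 g/mol of the mass implied by the atom counts.  If omitted it
    is computed from standard atomic weights.
    """

    n_c: int
    n_h: int
    n_o: int = 0
    n_n: int = 0
    molar_mass: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        for label, n in (("C", self.n_c), ("H", self.n_h), ("O", self.n_o), ("N", self.n_n)):
            if not float(n).is_integer() or n < 0:
                raise InvalidFormulaError(f"{self.name or 'formula'}: {label} count must be a non-negative integer, got {n}")
        computed = self.computed_mass
        if self.molar_mass is None:
            object.__setattr__(self, "molar_mass", computed)
        elif self.molar_mass <= 0:
            raise InvalidFormulaError(f"{self.name or 'formula'}: molar mass must be positive")
        elif abs(self.molar_mass - computed) > 0.5:
            raise InvalidFormulaError(
                f"{self.name or 'formula'}: molar mass {self.molar_mass} inconsistent with "
                f"composition (expected ~{computed:.3f} g/mol)"
            )
        if computed <= 0:
            raise InvalidFormulaError(f"{self.name or 'formula'}: empty formula")

    @property
    def computed_mass(self) -> float:
        return (
            self.n_c * ATOMIC_MASS["C"]
            + self.n_h * ATOMIC_MASS["H"]
            + self.n_o * ATOMIC_MASS["O"]
            + self.n_n * ATOMIC_MASS["N"]
        )

    @classmethod
    def from_string(cls, formula: str, molar_mass: float | None = None, name: str = "") -> "ElementalFormula":
        """Parse a Hill-style formula such as ``C6H12O6`` or ``CH4N2O``."""
        counts = {"C": 0, "H": 0, "O": 0, "N": 0}
        consumed = 0
        for m in _FORMULA_RE.finditer(formula):
            if not m.group(0):
                continue
            element, digits = m.group(1), m.group(2)
            if element not in counts:
                raise InvalidFormulaError(f"unsupported element {element!r} in {formula!r}")
            counts[element] += int(digits) if digits else 1
            consumed += len(m.group(0))
        if consumed != len(formula):
            raise InvalidFormulaError(f"could not parse formula {formula!r}")
        return cls(counts["C"], counts["H"], counts["O"], counts["N"], molar_mass, name or formula)


def thod_per_gram(formula: ElementalFormula) -> float:
    """Theoretical oxygen demand in gCOD per gram of compound.

    Nitrogen leaves as ammonia and is not oxidized.  Returns 0 when the
    oxygen demand is non-positive (water, ammonia, fully oxidized species).
    """
    if not isinstance(formula, ElementalFormula):
        raise InvalidFormulaError("thod_per_gram expects an ElementalFormula")
    o2_mol = formula.n_c + (formula.n_h - 3.0 * formula.n_n) / 4.0 - formula.n_o / 2.0
    if o2_mol <= 0.0:
        return 0.0
    return O2_MOLAR_MASS * o2_mol / formula.molar_mass


@lru_cache(maxsize=1)
def compound_library() -> dict[str, ElementalFormula]:
    """Versioned compound library shipped with the package (YAML)."""
    text = resources.files("gutenergy.data").joinpath("compounds.yaml").read_text()
    raw = yaml.safe_load(text)
    lib = {}
    for name, spec in raw["compounds"].items():
        lib[name] = ElementalFormula.from_string(spec["formula"], spec.get("molar_mass"), name=name)
    return lib


@dataclass(frozen=True)
class MacronutrientProfile:
    """Daily macronutrient intake in grams, plus total metabolizable kcal.

    ``cho_total_g`` includes fiber (NSP) and resistant starch, so available
    sugar+starch is ``cho_total_g - fiber_nsp_g - resistant_starch_g``.
    """

    cho_total_g: float
    fat_g: float
    protein_g: float
    fiber_nsp_g: float = 0.0
    resistant_starch_g: float = 0.0
    kcal_total: float = 0.0

    def __post_init__(self) -> None:
        for name in ("cho_total_g", "fat_g", "protein_g", "fiber_nsp_g", "resistant_starch_g", "kcal_total"):
            if getattr(self, name) < 0:
                raise InvalidProfileError(f"{name} must be >= 0")
        if self.available_cho_g < -1e-9:
            raise InvalidProfileError(
                "fiber_nsp_g + resistant_starch_g exceeds cho_total_g "
                f"({self.fiber_nsp_g} + {self.resistant_starch_g} > {self.cho_total_g})"
            )

    @property
    def available_cho_g(self) -> float:
        """Available sugar + starch: CHO minus resistant starch minus fiber."""
        return self.cho_total_g - self.resistant_starch_g - self.fiber_nsp_g

    def __add__(self, other: "MacronutrientProfile") -> "MacronutrientProfile":
        return MacronutrientProfile(
            self.cho_total_g + other.cho_total_g,
            self.fat_g + other.fat_g,
            self.protein_g + other.protein_g,
            self.fiber_nsp_g + other.fiber_nsp_g,
            self.resistant_starch_g + other.resistant_starch_g,
            self.kcal_total + other.kcal_total,
        )

    def scaled(self, factor: float) -> "MacronutrientProfile":
        if factor < 0:
            raise InvalidProfileError("scale factor must be >= 0")
        return MacronutrientProfile(
            self.cho_total_g * factor,
            self.fat_g * factor,
            self.protein_g * factor,
            self.fiber_nsp_g * factor,
            self.resistant_starch_g * factor,
            self.kcal_total * factor,
        )


@dataclass(frozen=True)
class CODVector:
    """Daily intake expressed as gCOD per substrate class."""

    ass_gcod: float = 0.0  # available sugar + starch
    rs_gcod: float = 0.0
    nsp_gcod: float = 0.0
    protein_gcod: float = 0.0
    fat_gcod: float = 0.0

    def __post_init__(self) -> None:
        for name in ("ass_gcod", "rs_gcod", "nsp_gcod", "protein_gcod", "fat_gcod"):
            if getattr(self, name) < 0:
                raise InvalidProfileError(f"{name} must be >= 0")

    def total(self) -> float:
        return self.ass_gcod + self.rs_gcod + self.nsp_gcod + self.protein_gcod + self.fat_gcod

    def as_dict(self) -> dict[str, float]:
        return {
            "ass": self.ass_gcod,
            "rs": self.rs_gcod,
            "nsp": self.nsp_gcod,
            "protein": self.protein_gcod,
            "fat": self.fat_gcod,
        }

    def __add__(self, other: "CODVector") -> "CODVector":
        return CODVector(
            self.ass_gcod + other.ass_gcod,
            self.rs_gcod + other.rs_gcod,
            self.nsp_gcod + other.nsp_gcod,
            self.protein_gcod + other.protein_gcod,
            self.fat_gcod + other.fat_gcod,
        )


@dataclass(frozen=True)
class CODCoefficients:
    """Per-class gCOD/g conversion factors and Atwater kcal/g factors.

    Available sugar+starch is converted with a configurable sugar:starch
    blend of the monomer (glucose) and polymer (anhydroglucose) factors;
    condensation raises COD per gram, so the polymer factor exceeds the
    sugar factor.  Fiber carries full COD but only 2 kcal/g metabolizable
    energy -- exactly the asymmetry that motivates a diet-specific
    kcal-per-gCOD ratio.
    """

    sugar_gcod_per_g: float
    polymer_gcod_per_g: float
    protein_gcod_per_g: float
    fat_gcod_per_g: float
    sugar_fraction_of_available: float = 0.20
    atwater_kcal_per_g: Mapping[str, float] = field(
        default_factory=lambda: {"available_cho": 4.0, "fiber": 2.0, "protein": 4.0, "fat": 9.0}
    )

    def __post_init__(self) -> None:
        for name in ("sugar_gcod_per_g", "polymer_gcod_per_g", "protein_gcod_per_g", "fat_gcod_per_g"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if not 0.0 <= self.sugar_fraction_of_available <= 1.0:
            raise ConfigurationError("sugar_fraction_of_available must lie in [0, 1]")
        if self.polymer_gcod_per_g <= self.sugar_gcod_per_g:
            raise ConfigurationError("polymer carbohydrate factor must exceed the sugar factor")

    @property
    def available_cho_gcod_per_g(self) -> float:
        f = self.sugar_fraction_of_available
        return f * self.sugar_gcod_per_g + (1.0 - f) * self.polymer_gcod_per_g

    @classmethod
    def from_stoichiometry(cls, sugar_fraction: float = 0.20) -> "CODCoefficients":
        """Recompute factors from ThOD of representative compounds."""
        lib = compound_library()
        return cls(
            sugar_gcod_per_g=thod_per_gram(lib["glucose"]),
            polymer_gcod_per_g=thod_per_gram(lib["anhydroglucose"]),
            protein_gcod_per_g=thod_per_gram(lib["protein-residue"]),
            fat_gcod_per_g=thod_per_gram(lib["tripalmitin"]),
            sugar_fraction_of_available=sugar_fraction,
        )

    def with_sugar_fraction(self, sugar_fraction: float) -> "CODCoefficients":
        return replace(self, sugar_fraction_of_available=sugar_fraction)


@lru_cache(maxsize=1)
def default_coefficients() -> CODCoefficients:
    return CODCoefficients.from_stoichiometry()


def intake_to_cod(profile: MacronutrientProfile, coeffs: CODCoefficients | None = None) -> CODVector:
    """Convert a macronutrient profile (g/day) to a five-class COD vector."""
    coeffs = coeffs or default_coefficients()
    ass_g = profile.available_cho_g
    if ass_g < -1e-9:
        raise InvalidProfileError("available sugar+starch is negative")
    ass_g = max(ass_g, 0.0)
    return CODVector(
        ass_gcod=ass_g * coeffs.available_cho_gcod_per_g,
        rs_gcod=profile.resistant_starch_g * coeffs.polymer_gcod_per_g,
        nsp_gcod=profile.fiber_nsp_g * coeffs.polymer_gcod_per_g,
        protein_gcod=profile.protein_g * coeffs.protein_gcod_per_g,
        fat_gcod=profile.fat_g * coeffs.fat_gcod_per_g,
    )


def kcal_per_gcod(profile: MacronutrientProfile, coeffs: CODCoefficients | None = None) -> float:
    """Diet-specific kcal/gCOD ratio: kcal_total over total dietary COD.

    Defined so that round-tripping the whole diet through
    :func:`cod_to_kcal` is exact.
    """
    if profile.kcal_total <= 0:
        raise ConfigurationError("profile.kcal_total must be > 0 to define a kcal/gCOD ratio")
    total = intake_to_cod(profile, coeffs).total()
    if total <= 0:
        raise ConfigurationError("profile has zero dietary COD")
    return profile.kcal_total / total


def cod_to_kcal(gcod: float, ratio: float) -> float:
    """kcal equivalent of ``gcod`` at a given diet-specific kcal/gCOD ratio."""
    if ratio <= 0:
        raise ConfigurationError("kcal/gCOD ratio must be > 0")
    return gcod * ratio


@lru_cache(maxsize=1)
def scfa_cod_factors() -> dict[str, float]:
    """gCOD per gram for each short-chain fatty acid."""
    lib = compound_library()
    return {acid: thod_per_gram(lib[compound]) for acid, compound in SCFA_COMPOUNDS.items()}


def scfa_mass_to_cod(
    acetate_mg: float = 0.0,
    propionate_mg: float = 0.0,
    n_butyrate_mg: float = 0.0,
    iso_butyrate_mg: float = 0.0,
) -> float:
    """Total gCOD of a per-acid SCFA mass set (mg)."""
    masses = {
        "acetate": acetate_mg,
        "propionate": propionate_mg,
        "n_butyrate": n_butyrate_mg,
        "iso_butyrate": iso_butyrate_mg,
    }
    for acid, mg in masses.items():
        if mg < 0:
            raise InvalidProfileError(f"{acid} mass must be >= 0")
    factors = scfa_cod_factors()
    return sum(mg / 1000.0 * factors[acid] for acid, mg in masses.items())
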