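"""In-silico multicompartment gut transit, reaction, and absorption model.

Three compartments are tracked in COD units (gCOD/day):

1. **Upper gastrointestinal tract** -- the host absorbs a digestibility
   fraction of available sugar+starch, protein, and fat; fiber (NSP) and
   resistant starch pass entirely to the colon.  Minimally processed diets
   (large food particles) incur a particle penalty subtracted from the
   digestibilities.
2. **Colon** -- each substrate class is fermented to an extent set by the
   colonic transit time (CTT) through a steady-state continuous-stirred
   closure, phi = k*tau / (1 + k*tau) for a first-order rate k (1/h) and
   residence time tau (h).  Fermented COD is partitioned into microbial
   biomass (yield Y), gas (fraction g), and SCFAs (the remainder, split per
   acid); a fraction f_abs of produced SCFA is absorbed by the host.  An
   endogenous host input (mucin, sloughed cells) joins the slowly fermenting
   residual class.
3. **Feces / body** -- fecal COD is unfermented residue + biomass +
   unabsorbed SCFA.  Host metabolizable energy is fecal-based:
   ``ME% = 100 * (1 - fecal/intake)``; gas COD leaves the system but is not
   fecal, so fecal-based ME counts it as metabolized (a true-absorption ME
   is also reported).

COD is conserved exactly: intake + endogenous = upper-GI absorbed + SCFA
absorbed + gas + fecal COD.

Calibration (:func:`calibrate` / :meth:`GutModel.fit`) adjusts the
physiological parameters within bounds by deterministic bounded least
squares against published model predictions for the two reference diets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.optimize import least_squares

from .diets import DIET_PROCESSED, reference_diets
from .stoichiometry import (
    CODCoefficients,
    CODVector,
    MacronutrientProfile,
    default_coefficients,
    intake_to_cod,
    kcal_per_gcod,
)

__all__ = [
    "SCFA_ACIDS",
    "GutModelParams",
    "ColonOutput",
    "ModelPrediction",
    "CalibrationTarget",
    "CalibrationResult",
    "REFERENCE_TARGETS",
    "DEFAULT_BOUNDS",
    "upper_gi_absorb",
    "colon_ferment",
    "predict_me",
    "calibrate",
    "calibrated_params",
    "GutModel",
    "GutModelResults",
]

SCFA_ACIDS = ("acetate", "propionate", "n_butyrate", "iso_butyrate")


class ParameterError(ValueError):
    """Raised when model parameters violate their invariants."""


@dataclass(frozen=True)
class GutModelParams:
    """Physiological parameters of the transit-reaction-absorption model.

    Defaults are pre-calibration values from physiological literature
    ranges; :func:`calibrate` refines them within :data:`DEFAULT_BOUNDS`.
    """

    d_ass: float = 0.96       # upper-GI digestibility, available sugar+starch
    d_protein: float = 0.91
    d_fat: float = 0.95
    particle_penalty: float = 0.03   # subtracted from digestibilities when unprocessed
    k_rs: float = 0.08        # 1/h first-order colonic fermentation rates
    k_nsp: float = 0.05
    k_residual: float = 0.10
    biomass_yield: float = 0.20      # COD fraction of fermented substrate to biomass
    gas_fraction: float = 0.04       # COD fraction to H2/CH4
    f_abs: float = 0.95       # fraction of produced SCFA absorbed by the host
    endogenous_gcod_day: float = 15.0  # mucin + sloughed cells entering the colon
    ctt_fixed_h: float = 48.0
    scfa_split: Mapping[str, float] = field(
        default_factory=lambda: {"acetate": 0.50, "propionate": 0.22, "n_butyrate": 0.22, "iso_butyrate": 0.06}
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("d_ass", "d_protein", "d_fat", "particle_penalty", "biomass_yield", "gas_fraction", "f_abs"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} must lie in [0, 1]")
        for name in ("k_rs", "k_nsp", "k_residual"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.endogenous_gcod_day < 0:
            raise ParameterError("endogenous_gcod_day must be >= 0")
        if self.ctt_fixed_h < 0:
            raise ParameterError("ctt_fixed_h must be >= 0")
        if self.biomass_yield + self.gas_fraction > 1.0:
            raise ParameterError("biomass_yield + gas_fraction must not exceed 1")
        split_sum = sum(self.scfa_split.values())
        if abs(split_sum - 1.0) > 1e-9:
            raise ParameterError(f"scfa_split must sum to 1, got {split_sum}")
        if any(v < 0 for v in self.scfa_split.values()):
            raise ParameterError("scfa_split fractions must be >= 0")

    def replace(self, **kwargs) -> "GutModelParams":
        return replace(self, **kwargs)

    def to_yaml(self, path) -> None:
        data = {k: (dict(v) if isinstance(v, Mapping) else v) for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GutModelParams":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


@dataclass(frozen=True)
class ColonOutput:
    """Daily COD balance of the colonic compartment (all gCOD/day)."""

    influent: Mapping[str, float]        # per class: rs, nsp, residual (incl. endogenous)
    fermented: float
    biomass: float
    gas: float
    scfa_produced: Mapping[str, float]   # per acid
    scfa_absorbed: Mapping[str, float]
    fecal_residual: Mapping[str, float]  # unfermented COD per class

    def influent_total(self) -> float:
        return sum(self.influent.values())

    def scfa_produced_total(self) -> float:
        return sum(self.scfa_produced.values())

    def scfa_absorbed_total(self) -> float:
        return sum(self.scfa_absorbed.values())

    def fecal_residual_total(self) -> float:
        return sum(self.fecal_residual.values())


@dataclass(frozen=True)
class ModelPrediction:
    """Model outputs for one diet/participant."""

    me_percent: float                    # fecal-based (gas counted as metabolized)
    me_true_absorption: float            # 100 * (upper-GI + SCFA absorbed) / intake
    fecal_gcod_day: float
    fecal_breakdown: Mapping[str, float]  # undigested, biomass, unabsorbed_scfa
    scfa_absorbed: Mapping[str, float]
    scfa_absorbed_total: float
    gas_gcod_day: float
    intake_gcod_day: float
    upper_gi_absorbed_gcod_day: float
    colon: ColonOutput


def upper_gi_absorb(
    intake: CODVector, params: GutModelParams, processed: bool = True
) -> tuple[float, CODVector]:
    """Host absorption in the upper GI tract.

    Returns (host-absorbed gCOD/day, colon influent CODVector).  Fiber and
    resistant starch pass entirely to the colon; the particle penalty
    applies only to minimally processed (``processed=False``) diets.
    COD is conserved: ``intake.total() == absorbed + influent.total()``.
    """
    penalty = 0.0 if processed else params.particle_penalty
    d_eff = {
        "ass": params.d_ass - penalty,
        "protein": params.d_protein - penalty,
        "fat": params.d_fat - penalty,
    }
    if min(d_eff.values()) < 0:
        raise ParameterError("particle penalty drives an effective digestibility below 0")
    absorbed = (
        d_eff["ass"] * intake.ass_gcod
        + d_eff["protein"] * intake.protein_gcod
        + d_eff["fat"] * intake.fat_gcod
    )
    influent = CODVector(
        ass_gcod=(1.0 - d_eff["ass"]) * intake.ass_gcod,
        rs_gcod=intake.rs_gcod,
        nsp_gcod=intake.nsp_gcod,
        protein_gcod=(1.0 - d_eff["protein"]) * intake.protein_gcod,
        fat_gcod=(1.0 - d_eff["fat"]) * intake.fat_gcod,
    )
    return absorbed, influent


def colon_ferment(
    influent: CODVector,
    endogenous_gcod_day: float,
    ctt_h: float,
    params: GutModelParams,
) -> ColonOutput:
    """Colonic fermentation at residence time ``ctt_h``.

    Three kinetic classes: resistant starch, NSP, and a residual class
    pooling undigested sugar/starch, protein, fat, and the endogenous host
    input.  Extent of fermentation per class follows the steady-state CSTR
    closure phi = k*tau/(1 + k*tau), which preserves the monotone CTT
    dependence and the COD balance of the full transit-chain model.
    """
    if ctt_h < 0:
        raise ParameterError("ctt_h must be >= 0")
    if endogenous_gcod_day < 0:
        raise ParameterError("endogenous input must be >= 0")
    classes = {
        "rs": influent.rs_gcod,
        "nsp": influent.nsp_gcod,
        "residual": influent.ass_gcod + influent.protein_gcod + influent.fat_gcod + endogenous_gcod_day,
    }
    rates = {"rs": params.k_rs, "nsp": params.k_nsp, "residual": params.k_residual}
    fermented_by_class = {
        name: amount * (rates[name] * ctt_h / (1.0 + rates[name] * ctt_h))
        for name, amount in classes.items()
    }
    fecal_residual = {name: classes[name] - fermented_by_class[name] for name in classes}
    fermented = sum(fermented_by_class.values())
    biomass = params.biomass_yield * fermented
    gas = params.gas_fraction * fermented
    scfa_pool = (1.0 - params.biomass_yield - params.gas_fraction) * fermented
    produced = {acid: scfa_pool * frac for acid, frac in params.scfa_split.items()}
    absorbed = {acid: params.f_abs * amount for acid, amount in produced.items()}
    return ColonOutput(
        influent=classes,
        fermented=fermented,
        biomass=biomass,
        gas=gas,
        scfa_produced=produced,
        scfa_absorbed=absorbed,
        fecal_residual=fecal_residual,
    )


def predict_me(
    profile: MacronutrientProfile,
    params: GutModelParams | None = None,
    ctt_mode: str = "fixed",
    ctt_h: float | None = None,
    processed: bool = True,
    coefficients: CODCoefficients | None = None,
) -> ModelPrediction:
    """Run the full model on a diet profile and return its predictions.

    ``ctt_mode='fixed'`` uses ``params.ctt_fixed_h`` (48 h) for everyone;
    ``ctt_mode='measured'`` requires ``ctt_h``.
    """
    params = params or GutModelParams()
    if ctt_mode == "fixed":
        tau = params.ctt_fixed_h
    elif ctt_mode == "measured":
        if ctt_h is None:
            raise ValueError("ctt_mode='measured' requires ctt_h")
        tau = ctt_h
    else:
        raise ValueError(f"unknown ctt_mode {ctt_mode!r}")
    intake = intake_to_cod(profile, coefficients)
    absorbed_upper, influent = upper_gi_absorb(intake, params, processed=processed)
    colon = colon_ferment(influent, params.endogenous_gcod_day, tau, params)
    unabsorbed_scfa = colon.scfa_produced_total() - colon.scfa_absorbed_total()
    fecal = colon.fecal_residual_total() + colon.biomass + unabsorbed_scfa
    intake_total = intake.total()
    me = 100.0 * (1.0 - fecal / intake_total) if intake_total > 0 else 100.0
    me_abs = (
        100.0 * (absorbed_upper + colon.scfa_absorbed_total()) / intake_total
        if intake_total > 0
        else 100.0
    )
    return ModelPrediction(
        me_percent=me,
        me_true_absorption=me_abs,
        fecal_gcod_day=fecal,
        fecal_breakdown={
            "undigested": colon.fecal_residual_total(),
            "biomass": colon.biomass,
            "unabsorbed_scfa": unabsorbed_scfa,
        },
        scfa_absorbed=dict(colon.scfa_absorbed),
        scfa_absorbed_total=colon.scfa_absorbed_total(),
        gas_gcod_day=colon.gas,
        intake_gcod_day=intake_total,
        upper_gi_absorbed_gcod_day=absorbed_upper,
        colon=colon,
    )


# --------------------------------------------------------------------------
# calibration


@dataclass(frozen=True)
class CalibrationTarget:
    """One published model prediction to reproduce, with its tolerance."""

    name: str
    value: float
    tol: float          # relative fraction, or absolute for kind='absolute'
    kind: str = "relative"


#: published model predictions on the reference diets (fixed 48-h CTT)
REFERENCE_TARGETS: tuple[CalibrationTarget, ...] = (
    CalibrationTarget("biomass_mbd", 19.6, 0.15),
    CalibrationTarget("biomass_wd", 9.4, 0.15),
    CalibrationTarget("scfa_abs_mbd", 72.3, 0.15),
    CalibrationTarget("scfa_abs_wd", 36.4, 0.15),
    CalibrationTarget("me_mbd", 92.4, 1.5, kind="absolute"),
    CalibrationTarget("me_wd", 95.2, 1.5, kind="absolute"),
    CalibrationTarget("fecal_kcal_diff", 110.0, 0.15),
)

#: free parameters and their calibration box
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "d_ass": (0.90, 0.99),
    "d_protein": (0.85, 0.97),
    "d_fat": (0.90, 0.99),
    "particle_penalty": (0.0, 0.05),
    "k_rs": (0.01, 0.50),
    "k_nsp": (0.01, 0.50),
    "k_residual": (0.01, 0.50),
    "biomass_yield": (0.10, 0.30),
    "f_abs": (0.50, 0.99),
    "endogenous_gcod_day": (0.0, 25.0),
}


@dataclass(frozen=True)
class CalibrationResult:
    params: GutModelParams
    residuals: Mapping[str, tuple[float, float]]  # name -> (predicted, target)
    scaled_cost: float
    n_targets: int

    def within_tolerance(self, targets: Sequence[CalibrationTarget] = REFERENCE_TARGETS) -> bool:
        by_name = {t.name: t for t in targets}
        for name, (pred, target) in self.residuals.items():
            t = by_name[name]
            err = abs(pred - target)
            limit = t.tol if t.kind == "absolute" else t.tol * abs(target)
            if err > limit:
                return False
        return True


def reference_predictions(
    params: GutModelParams, kcal: float = 2000.0, coefficients: CODCoefficients | None = None
) -> dict[str, float]:
    """The seven calibration quantities at fixed 48-h CTT on the reference diets."""
    mbd, wd = reference_diets(kcal)
    pred_m = predict_me(mbd, params, ctt_mode="fixed", processed=DIET_PROCESSED["MBD"], coefficients=coefficients)
    pred_w = predict_me(wd, params, ctt_mode="fixed", processed=DIET_PROCESSED["WD"], coefficients=coefficients)
    ratio_m = kcal_per_gcod(mbd, coefficients)
    ratio_w = kcal_per_gcod(wd, coefficients)
    return {
        "biomass_mbd": pred_m.colon.biomass,
        "biomass_wd": pred_w.colon.biomass,
        "scfa_abs_mbd": pred_m.scfa_absorbed_total,
        "scfa_abs_wd": pred_w.scfa_absorbed_total,
        "me_mbd": pred_m.me_percent,
        "me_wd": pred_w.me_percent,
        "fecal_kcal_diff": pred_m.fecal_gcod_day * ratio_m - pred_w.fecal_gcod_day * ratio_w,
    }


def _scaled_residuals(preds: Mapping[str, float], targets: Sequence[CalibrationTarget]) -> np.ndarray:
    out = []
    for t in targets:
        if t.name not in preds:
            raise KeyError(f"no prediction available for calibration target {t.name!r}")
        err = preds[t.name] - t.value
        scale = t.tol if t.kind == "absolute" else t.tol * abs(t.value)
        out.append(err / scale)
    return np.asarray(out)


def calibrate(
    targets: Sequence[CalibrationTarget] = REFERENCE_TARGETS,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    start: GutModelParams | None = None,
    kcal: float = 2000.0,
    coefficients: CODCoefficients | None = None,
) -> CalibrationResult:
    """Fit the free parameters to the published targets within bounds.

    Deterministic bounded least squares on tolerance-scaled residuals from a
    fixed set of starting points (the defaults plus the bound-box midpoint);
    parameters whose bounds collapse to a point are held fixed.  Raises if
    any bound interval is inverted.
    """
    bounds = dict(DEFAULT_BOUNDS if bounds is None else bounds)
    start = start or GutModelParams()
    for name, (lo, hi) in bounds.items():
        if lo > hi:
            raise ParameterError(f"infeasible bounds for {name}: ({lo}, {hi})")
    free = [name for name, (lo, hi) in bounds.items() if hi > lo]
    fixed = {name: lo for name, (lo, hi) in bounds.items() if hi == lo}
    base = start.replace(**fixed)

    def make_params(x: np.ndarray) -> GutModelParams:
        return base.replace(**{name: float(v) for name, v in zip(free, x)})

    def fun(x: np.ndarray) -> np.ndarray:
        return _scaled_residuals(reference_predictions(make_params(x), kcal, coefficients), targets)

    if not free:
        preds = reference_predictions(base, kcal, coefficients)
        res_map = {t.name: (preds[t.name], t.value) for t in targets}
        cost = float(np.sum(_scaled_residuals(preds, targets) ** 2))
        return CalibrationResult(base, res_map, cost, len(targets))

    lo = np.array([bounds[n][0] for n in free])
    hi = np.array([bounds[n][1] for n in free])
    starts = [
        np.clip([getattr(base, n) for n in free], lo, hi),
        (lo + hi) / 2.0,
    ]
    best = None
    for x0 in starts:
        fit = least_squares(fun, x0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
        if best is None or fit.cost < best.cost:
            best = fit
    params = make_params(best.x)
    preds = reference_predictions(params, kcal, coefficients)
    res_map = {t.name: (preds[t.name], t.value) for t in targets}
    return CalibrationResult(params, res_map, float(2.0 * best.cost), len(targets))


@lru_cache(maxsize=1)
def calibrated_params() -> GutModelParams:
    """Default-target calibrated parameter set (memoized; deterministic)."""
    return calibrate().params


# --------------------------------------------------------------------------
# model/results wrappers


class GutModel:
    """Transit-reaction-absorption model object.

    ``GutModel().predict(profile, ...)`` runs the forward model;
    ``GutModel().fit()`` calibrates the parameters against the published
    reference predictions and returns a :class:`GutModelResults`.
    """

    def __init__(self, params: GutModelParams | None = None, coefficients: CODCoefficients | None = None):
        self.params = params or GutModelParams()
        self.coefficients = coefficients or default_coefficients()

    def predict(
        self,
        profile: MacronutrientProfile,
        ctt_mode: str = "fixed",
        ctt_h: float | None = None,
        processed: bool = True,
    ) -> ModelPrediction:
        return predict_me(profile, self.params, ctt_mode, ctt_h, processed, self.coefficients)

    def fit(
        self,
        targets: Sequence[CalibrationTarget] = REFERENCE_TARGETS,
        bounds: Mapping[str, tuple[float, float]] | None = None,
        kcal: float = 2000.0,
    ) -> "GutModelResults":
        calib = calibrate(targets, bounds, start=self.params, kcal=kcal, coefficients=self.coefficients)
        return GutModelResults(self, calib)


class GutModelResults:
    """Calibrated model: fitted parameters, target residuals, and predictions."""

    def __init__(self, model: GutModel, calibration: CalibrationResult):
        self.model = GutModel(calibration.params, model.coefficients)
        self.params = calibration.params
        self.calibration = calibration

    def predict(self, profile: MacronutrientProfile, **kwargs) -> ModelPrediction:
        return self.model.predict(profile, **kwargs)

    def summary(self) -> str:
        lines = ["Gut model calibration", "=" * 54]
        lines.append(f"{'target':<18}{'fitted':>10}{'published':>12}{'rel.err':>10}")
        for name, (pred, target) in self.calibration.residuals.items():
            rel = (pred - target) / target if target else math.nan
            lines.append(f"{name:<18}{pred:>10.2f}{target:>12.2f}{rel:>+10.1%}")
        lines.append("-" * 54)
        lines.append("Fitted parameters:")
        for name in DEFAULT_BOUNDS:
            lines.append(f"  {name:<22}{getattr(self.params, name):.4f}")
        return "\n".join(lines)
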