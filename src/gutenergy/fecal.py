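"""PEG-marker fecal accounting and host metabolizable energy.

Feces collected over a multi-day period are pooled into a single composite;
a fixed daily dose of non-absorbable PEG3350 (1.5 g/day, 0.5 g per meal)
taken throughout the period lets incomplete or over-complete collections be
normalized to true 24-h equivalents: the recovery fraction is (PEG recovered
per day) / (PEG dosed per day), and every composite quantity is divided by
``period_days * recovery`` to obtain a daily value.

Host metabolizable energy (ME) is the percentage of dietary energy, in COD,
not lost in feces: ``ME% = 100 * (1 - fecal_gCOD/day / intake_gCOD/day)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

AVOGADRO = 6.022e23
#: average molar mass of a DNA base pair, g/mol per bp
BP_MOLAR_MASS = 660.0

__all__ = [
    "FecalComposite",
    "PegRecovery",
    "HostMEResult",
    "RecoveryError",
    "peg_recovery",
    "normalize_daily",
    "host_me",
    "nonmetabolizable_kcal",
    "absorbed_kcal",
    "total_fecal_scfa",
    "plasmid_copy_number",
    "daily_16s_copies",
]


class RecoveryError(ValueError):
    """Raised when PEG-based normalization is impossible or invalid."""


@dataclass(frozen=True)
class FecalComposite:
    """Pooled fecal measurements over one collection period (default 6 days)."""

    wet_weight_g: float
    cod_g: float
    peg_g: float
    scfa_mg: Mapping[str, float] = field(default_factory=dict)  # per-acid mg in composite
    copies_per_g: float = 0.0
    period_days: float = 6.0

    def __post_init__(self) -> None:
        if self.period_days <= 0:
            raise ValueError("period_days must be > 0")
        for name in ("wet_weight_g", "cod_g", "peg_g", "copies_per_g"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for acid, mg in self.scfa_mg.items():
            if mg < 0:
                raise ValueError(f"scfa_mg[{acid!r}] must be >= 0")


@dataclass(frozen=True)
class PegRecovery:
    """Marker recovery for one composite; one factor per composite, not per stool."""

    dose_g_per_day: float
    measured_g_per_day: float
    recovery: float
    warning: bool = False  # set when recovery falls outside [0.3, 1.2]


@dataclass(frozen=True)
class HostMEResult:
    me_percent: float
    fecal_gcod_day: float
    intake_gcod_day: float
    nonmetabolizable_kcal_day: float | None = None
    implausible: bool = False  # fecal COD exceeded intake COD


def peg_recovery(composite: FecalComposite, dose_g_per_day: float = 1.5) -> PegRecovery:
    """Recovery fraction of the PEG marker for one composite.

    Recovery above 1 is retained (assay error can exceed dosing; capping
    would bias daily estimates downward) but flagged, as is recovery below
    0.3, via the ``warning`` field.
    """
    if dose_g_per_day <= 0:
        raise RecoveryError("PEG dose must be > 0")
    if composite.peg_g <= 0:
        raise RecoveryError("no PEG recovered in composite: 24-h normalization is impossible")
    measured = composite.peg_g / composite.period_days
    recovery = measured / dose_g_per_day
    flagged = not 0.3 <= recovery <= 1.2
    if flagged:
        warnings.warn(f"PEG recovery {recovery:.3f} outside [0.3, 1.2]", stacklevel=2)
    return PegRecovery(dose_g_per_day, measured, recovery, warning=flagged)


def normalize_daily(quantity_in_composite: float, period_days: float, recovery: float) -> float:
    """Composite quantity -> per-day value, corrected for marker recovery.

    At recovery 1 this is the naive daily mean; under-collection
    (recovery < 1) inflates the estimate accordingly.
    """
    if recovery <= 0:
        raise RecoveryError("recovery must be > 0")
    if period_days <= 0:
        raise ValueError("period_days must be > 0")
    return quantity_in_composite / (period_days * recovery)


def host_me(fecal_gcod_day: float, intake_gcod_day: float, ei_kcal: float | None = None) -> HostMEResult:
    """Host metabolizable energy from daily fecal and intake COD.

    ``me_percent = 100 * (1 - fecal/intake)``.  Fecal COD above intake yields
    a negative ME, which is physiologically implausible; it is returned but
    flagged rather than raised, since it can arise from assay noise.
    """
    if intake_gcod_day <= 0:
        raise ValueError("intake_gcod_day must be > 0")
    if fecal_gcod_day < 0:
        raise ValueError("fecal_gcod_day must be >= 0")
    me = 100.0 * (1.0 - fecal_gcod_day / intake_gcod_day)
    implausible = fecal_gcod_day > intake_gcod_day
    if implausible:
        warnings.warn("fecal COD exceeds intake COD: negative metabolizable energy", stacklevel=2)
    nm = nonmetabolizable_kcal(me, ei_kcal) if ei_kcal is not None else None
    return HostMEResult(me, fecal_gcod_day, intake_gcod_day, nm, implausible)


def nonmetabolizable_kcal(me_percent: float, ei_kcal: float) -> float:
    """Daily kcal not absorbed by the host: EI * (1 - ME/100)."""
    if ei_kcal <= 0:
        raise ValueError("ei_kcal must be > 0")
    if me_percent > 100.0:
        raise ValueError("me_percent cannot exceed 100")
    return ei_kcal * (1.0 - me_percent / 100.0)


def absorbed_kcal(me_percent: float, ei_kcal: float) -> float:
    """Daily kcal absorbed by the host: EI * ME/100 (complement of the above)."""
    if ei_kcal <= 0:
        raise ValueError("ei_kcal must be > 0")
    return ei_kcal * me_percent / 100.0


def total_fecal_scfa(composite: FecalComposite, recovery: float) -> dict[str, float]:
    """Per-acid and total fecal SCFA, as mg/day and mg over the period.

    Each acid is normalized by :func:`normalize_daily`; the total is the sum
    of acetate, propionate, and butyrate (plus any further acids present).
    """
    out: dict[str, float] = {}
    total_day = 0.0
    for acid, mg in composite.scfa_mg.items():
        daily = normalize_daily(mg, composite.period_days, recovery)
        out[f"{acid}_mg_day"] = daily
        out[f"{acid}_mg_period"] = daily * composite.period_days
        total_day += daily
    out["total_mg_day"] = total_day
    out["total_mg_period"] = total_day * composite.period_days
    return out


def plasmid_copy_number(dna_ng_per_ul: float, plasmid_length_bp: float) -> float:
    """qPCR standard: plasmid copies/uL from DNA concentration and length.

    ``copies = dna * 6.022e23 / (length * 1e9 * 660)``.
    """
    if plasmid_length_bp <= 0:
        raise ValueError("plasmid_length_bp must be > 0")
    if dna_ng_per_ul < 0:
        raise ValueError("dna_ng_per_ul must be >= 0")
    return dna_ng_per_ul * AVOGADRO / (plasmid_length_bp * 1e9 * BP_MOLAR_MASS)


def daily_16s_copies(
    copies_per_g: float, fecal_wet_weight_g: float, period_days: float, recovery: float
) -> float:
    """Daily 16S rRNA gene copies: copies/g x composite weight, PEG-normalized."""
    if copies_per_g < 0 or fecal_wet_weight_g < 0:
        raise ValueError("copies_per_g and fecal_wet_weight_g must be >= 0")
    return normalize_daily(copies_per_g * fecal_wet_weight_g, period_days, recovery)
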