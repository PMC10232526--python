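"""Synthetic crossover cohort generator.

Emulates a 17-participant randomized 2x2 crossover (8 participants start on
the Western Diet, 9 on the Microbiome Enhancer Diet) with ~2000 kcal/day
energy-balanced diets, per-diet colonic transit time (CTT) distributions,
PEG-marker recovery noise, and 6-day fecal composites consistent with the
gut model plus measurement noise -- so every pipeline stage is testable
without any download.

Generative structure of measured host metabolizable energy (ME) on the MBD
arm: two standardized microbial latents -- fecal propionate (z1) and biomass
(z2) -- carry configurable per-SD effects on ME (defaults -2.1 and -1.6
%ME/SD), with residual noise sized so the two-term final model attains the
configured sample R^2 at n = 17.  The CTT pathway is mediated: z1 is
negatively correlated with the gut model's CTT-driven ME (shorter transit
leaves more fermentation products in feces), so measured CTT correlates with
ME and survives a correlation screen, but has no partial effect once the two
microbial factors are in the model.  Fecal composites are derived from the
resulting true ME and the participant's dietary COD, then degraded with
lognormal assay noise and truncated-normal PEG recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from . import fecal
from .diets import DIET_PROCESSED, reference_diets
from .endpoints import MEAL_GRID_MIN, iauc
from .gut_model import GutModelParams, calibrated_params, predict_me
from .stoichiometry import MacronutrientProfile, intake_to_cod

__all__ = [
    "GeneratorConfig",
    "Cohort",
    "generate_cohort",
    "reference_diets",
    "measured_me_table",
    "candidate_matrix",
    "CANDIDATE_FAMILIES",
]

DIETS = ("WD", "MBD")
MEAL_STARTS_MIN = (0.0, 300.0, 660.0)
ANALYTES = ("leptin", "glp1", "pp")

#: family label of every candidate factor in the determinants screen
CANDIDATE_FAMILIES: dict[str, str] = {
    "biomass_log10_copies": "biomass",
    "ctt_h": "transit",
    "si_transit_h": "transit",
    "ileocecal_ph": "ph",
    "fecal_acetate_mg_day": "scfa_fecal",
    "fecal_propionate_mg_day": "scfa_fecal",
    "fecal_butyrate_mg_day": "scfa_fecal",
    "fecal_total_scfa_mg_day": "scfa_fecal",
    "fecal_acetate_propionate_ratio": "scfa_fecal",
    "serum_acetate_um": "scfa_circulating",
    "serum_propionate_um": "scfa_circulating",
    "serum_butyrate_um": "scfa_circulating",
    "serum_total_um": "scfa_circulating",
    "serum_acetate_propionate_ratio": "scfa_circulating",
    "glp1_iauc": "hormone",
}

_SCHEMAS: dict[str, list[str]] = {
    "participants": ["participant_id", "sequence", "design_kcal_day"],
    "diet_days": [
        "participant_id", "diet", "period", "cho_total_g", "fat_g", "protein_g",
        "fiber_nsp_g", "resistant_starch_g", "kcal_total", "processed",
        "ei_kcal_day", "ee_kcal_day",
    ],
    "fecal_composites": [
        "participant_id", "diet", "period", "period_days", "wet_weight_g", "cod_g",
        "peg_g", "acetate_mg", "propionate_mg", "butyrate_mg", "copies_per_g",
    ],
    "ctt": [
        "participant_id", "diet", "period", "ctt_h", "si_transit_h",
        "colonic_ph_median", "ileocecal_ph",
    ],
    "serum_scfa": ["participant_id", "diet", "period", "acetate_um", "propionate_um", "butyrate_um"],
    "hormone_timepoints": ["participant_id", "diet", "period", "analyte", "meal", "time_min", "value"],
    "activity_minutes": ["participant_id", "diet", "period", "minute", "counts"],
    "truth": [
        "participant_id", "diet", "period", "sequence", "true_ctt_h", "me_true",
        "me_model", "z_propionate", "z_biomass", "epsilon", "recovery",
        "intake_gcod_day", "fecal_gcod_day_true",
    ],
}


def _sem_to_sd(sem: float, n: int = 17) -> float:
    return sem * math.sqrt(n)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the emulated trial.

    Distribution centers follow the published cohort (s.e.m. converted to SD
    with sqrt(n), n = 17); assay noise levels and ancillary distributions
    are fixed realistic choices documented in the methods note.
    """

    n_participants: int = 17
    n_sequence1: int = 8          # sequence 1 = WD then MBD
    seed: int = 0
    kcal_mean: float = 2000.0
    kcal_sd: float = 250.0
    period_days: float = 6.0
    # colonic transit (h): means are the printed per-diet means; SD = sem*sqrt(17)
    ctt_mean_h: Mapping[str, float] = field(default_factory=lambda: {"MBD": 29.7, "WD": 39.2})
    ctt_sd_h: Mapping[str, float] = field(
        default_factory=lambda: {"MBD": _sem_to_sd(4.4), "WD": _sem_to_sd(6.2)}
    )
    ctt_min_h: float = 5.0
    ctt_assay_sd_h: float = 2.0
    # PEG marker
    peg_dose_g_day: float = 1.5
    peg_assay_cv: float = 0.018
    recovery_mean: float = 0.9
    recovery_sd: float = 0.08
    recovery_bounds: tuple[float, float] = (0.6, 1.1)
    # measurement noise (lognormal CVs)
    cod_cv: float = 0.03
    scfa_cv: float = 0.05
    copies_cv: float = 0.10
    diet_jitter_cv: float = 0.02   # per-participant deviation of consumed vs designed grams
    # measured-ME structure
    me_mean: Mapping[str, float] = field(default_factory=lambda: {"MBD": 89.5, "WD": 95.4})
    anchor_me_means: bool = True
    microbial_effects: bool = True
    effect_propionate: float = -2.1   # % ME per SD of 6-day fecal propionate
    effect_biomass: float = -1.6      # % ME per SD of log10 16S copies/day
    target_r2: float = 0.58           # fraction of MBD ME variance carried by the two latents
    ctt_propionate_rho: float = -0.5  # mediation: short CTT -> high fecal propionate
    wd_me_extra_sd: float = 0.4
    # fecal microbial assays; acetate/butyrate share a fermentation latent with
    # propionate (coupling scfa_sibling_rho) but propionate alone carries the
    # ME effect, so it has the strongest outcome correlation in its family
    propionate_mean_mg: Mapping[str, float] = field(default_factory=lambda: {"MBD": 2500.0, "WD": 1200.0})
    propionate_sd_mg: Mapping[str, float] = field(default_factory=lambda: {"MBD": 858.6, "WD": 400.0})
    acetate_mean_mg: Mapping[str, float] = field(default_factory=lambda: {"MBD": 6000.0, "WD": 2900.0})
    acetate_sd_mg: Mapping[str, float] = field(default_factory=lambda: {"MBD": 2000.0, "WD": 1000.0})
    butyrate_mean_mg: Mapping[str, float] = field(default_factory=lambda: {"MBD": 2100.0, "WD": 1000.0})
    butyrate_sd_mg: Mapping[str, float] = field(default_factory=lambda: {"MBD": 750.0, "WD": 350.0})
    scfa_sibling_rho: float = 0.4
    log10_copies_mean: Mapping[str, float] = field(default_factory=lambda: {"MBD": 12.4, "WD": 12.0})
    log10_copies_sd: float = 0.49
    serum_fecal_rho: float = 0.4
    wet_weight_g_day: Mapping[str, float] = field(default_factory=lambda: {"MBD": 190.0, "WD": 115.0})
    wet_weight_sd: float = 35.0
    # energy balance: EI - EE ~ N(5, 15) kcal/day, inside the +/-50 target
    balance_mean_kcal: float = 5.0
    balance_sd_kcal: float = 15.0
    # sleep window: 8 h, ~3.5 h motion-free
    sleep_window_min: int = 480
    still_minute_prob: float = 0.4375
    params: GutModelParams | None = None   # None -> calibrated defaults

    def __post_init__(self) -> None:
        if self.n_participants < 4 or not 0 < self.n_sequence1 < self.n_participants:
            raise ValueError("need >= 4 participants split across both sequences")
        if not 0.0 < self.target_r2 < 1.0:
            raise ValueError("target_r2 must lie in (0, 1)")
        for name in ("kcal_sd", "recovery_sd", "ctt_assay_sd_h", "wd_me_extra_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(sd <= 0 for sd in self.ctt_sd_h.values()):
            raise ValueError("ctt_sd_h entries must be > 0")
        if not -1.0 <= self.ctt_propionate_rho <= 1.0:
            raise ValueError("ctt_propionate_rho must lie in [-1, 1]")

    def noise_free(self) -> "GeneratorConfig":
        """Copy with all measurement noise, recovery noise, and the microbial
        latent structure switched off -- the cohort then closes the loop with
        the gut model exactly."""
        return replace(
            self,
            peg_assay_cv=0.0,
            recovery_mean=1.0,
            recovery_sd=0.0,
            recovery_bounds=(1.0, 1.0),
            cod_cv=0.0,
            scfa_cv=0.0,
            copies_cv=0.0,
            diet_jitter_cv=0.0,
            ctt_assay_sd_h=0.0,
            anchor_me_means=False,
            microbial_effects=False,
            wd_me_extra_sd=0.0,
        )


@dataclass
class Cohort:
    """Generated tables (tidy CSV bundle) plus the configuration used."""

    participants: pd.DataFrame
    diet_days: pd.DataFrame
    fecal_composites: pd.DataFrame
    ctt: pd.DataFrame
    serum_scfa: pd.DataFrame
    hormone_timepoints: pd.DataFrame
    activity_minutes: pd.DataFrame
    truth: pd.DataFrame
    config: GeneratorConfig | None = None

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in _SCHEMAS}

    def write_bundle(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables().items():
            df.to_csv(path / f"{name}.csv", index=False)

    @classmethod
    def read_bundle(cls, path) -> "Cohort":
        path = Path(path)
        loaded = {}
        for name, columns in _SCHEMAS.items():
            fpath = path / f"{name}.csv"
            if not fpath.exists():
                raise FileNotFoundError(f"bundle table missing: {fpath}")
            df = pd.read_csv(fpath)
            for col in columns:
                if col not in df.columns:
                    raise ValueError(f"table {name!r}: missing column {col!r}")
            extra = [c for c in df.columns if c not in columns]
            if extra:
                raise ValueError(f"table {name!r}: unexpected columns {extra}")
            loaded[name] = df[columns]
        return cls(**loaded)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float = np.inf, size=None):
    if sd == 0.0:
        return np.full(size, float(np.clip(mean, lo, hi))) if size else float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _lognoise(rng: np.random.Generator, cv: float, size=None):
    """Mean-one multiplicative lognormal noise with the given CV."""
    if cv == 0.0:
        return np.ones(size) if size else 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, size=size)


def _jittered_profile(base: MacronutrientProfile, rng: np.random.Generator, cv: float) -> MacronutrientProfile:
    """Realized consumption: designed grams with small multiplicative wobble."""
    if cv == 0.0:
        return base
    f = _lognoise(rng, cv, size=5)
    fiber = base.fiber_nsp_g * f[0]
    rs = base.resistant_starch_g * f[1]
    avail = base.available_cho_g * f[2]
    fat = base.fat_g * f[3]
    protein = base.protein_g * f[4]
    kcal = (avail + rs) * 4.0 + fiber * 2.0 + protein * 4.0 + fat * 9.0
    return MacronutrientProfile(avail + rs + fiber, fat, protein, fiber, rs, kcal)


def _hormone_rows(rng, pid, diet, period):
    """18 timepoints over ~12 h: 3 meals x the -30..+180 min grid, 3 analytes."""
    shapes = {  # baseline lognormal (mu, sigma), response size, peak (min), width
        "leptin": (math.log(20000.0), 0.25, 0.15, 120.0, 70.0),
        "glp1": (math.log(8.0), 0.30, 1.20, 45.0, 40.0),
        "pp": (math.log(80.0), 0.30, 1.50, 30.0, 50.0),
    }
    diet_factor = {"leptin": 0.70, "glp1": 1.15, "pp": 1.40}
    rows = []
    for analyte, (mu, sig, resp, peak, width) in shapes.items():
        baseline = rng.lognormal(mu, sig)
        amp = resp * (diet_factor[analyte] if diet == "MBD" else 1.0) * rng.lognormal(0.0, 0.2)
        for meal_i, start in enumerate(MEAL_STARTS_MIN):
            for t in MEAL_GRID_MIN:
                shape = math.exp(-((t - peak) ** 2) / (2.0 * width**2)) if t > 0 else 0.0
                value = baseline * (1.0 + amp * shape) * _lognoise(rng, 0.04)
                rows.append((pid, diet, period, analyte, meal_i, start + t, value))
    return rows


def generate_cohort(config: GeneratorConfig | None = None) -> Cohort:
    """Generate the full synthetic cohort for one seed (deterministic)."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    params = cfg.params or calibrated_params()
    n = cfg.n_participants
    pids = [f"P{i + 1:02d}" for i in range(n)]
    seq = np.ones(n, dtype=int) * 2
    seq[rng.permutation(n)[: cfg.n_sequence1]] = 1

    kcal = _truncnorm(rng, cfg.kcal_mean, cfg.kcal_sd, 1200.0, size=n)
    balance = rng.normal(cfg.balance_mean_kcal, cfg.balance_sd_kcal, size=(n, 2))

    # pass 1: diets, transit, and pure-model predictions per participant-period
    arm: dict[str, dict[str, list]] = {d: {k: [] for k in ("idx", "period", "profile", "tau", "pred")} for d in DIETS}
    for i in range(n):
        mbd_base, wd_base = reference_diets(kcal[i])
        base = {"MBD": mbd_base, "WD": wd_base}
        for period in (1, 2):
            diet = ("WD" if period == 1 else "MBD") if seq[i] == 1 else ("MBD" if period == 1 else "WD")
            profile = _jittered_profile(base[diet], rng, cfg.diet_jitter_cv)
            tau = float(_truncnorm(rng, cfg.ctt_mean_h[diet], cfg.ctt_sd_h[diet], cfg.ctt_min_h))
            pred = predict_me(profile, params, ctt_mode="measured", ctt_h=tau, processed=DIET_PROCESSED[diet])
            a = arm[diet]
            a["idx"].append(i)
            a["period"].append(period)
            a["profile"].append(profile)
            a["tau"].append(tau)
            a["pred"].append(pred)

    # pass 2: latent microbial structure and true measured-ME per arm
    me_true: dict[tuple[int, str], float] = {}
    latents: dict[tuple[int, str], tuple[float, float, float]] = {}
    for diet in DIETS:
        a = arm[diet]
        me_model = np.array([p.me_percent for p in a["pred"]])
        centered = me_model - me_model.mean()
        if diet == "MBD" and cfg.microbial_effects:
            sd_model = me_model.std()
            w = centered / sd_model if sd_model > 0 else np.zeros_like(centered)
            rho = cfg.ctt_propionate_rho
            z1 = rho * w + math.sqrt(1.0 - rho * rho) * rng.standard_normal(len(w))
            z2 = rng.standard_normal(len(w))
            explained = cfg.effect_propionate**2 + cfg.effect_biomass**2
            resid_var = explained * (1.0 - cfg.target_r2) / cfg.target_r2
            meas_var = ((100.0 - cfg.me_mean["MBD"]) * math.hypot(cfg.cod_cv, cfg.peg_assay_cv)) ** 2
            eps_sd = math.sqrt(max(resid_var - meas_var, 0.0))
            eps = rng.normal(0.0, eps_sd, size=len(w))
            alpha = cfg.me_mean[diet] if cfg.anchor_me_means else me_model.mean()
            me = alpha + cfg.effect_propionate * z1 + cfg.effect_biomass * z2 + eps
        elif diet == "WD" and (cfg.anchor_me_means or cfg.wd_me_extra_sd > 0):
            z1 = rng.standard_normal(len(centered))  # reserved draws keep streams aligned
            z2 = rng.standard_normal(len(centered))
            eps = rng.normal(0.0, cfg.wd_me_extra_sd, size=len(centered))
            alpha = cfg.me_mean[diet] if cfg.anchor_me_means else me_model.mean()
            me = alpha + centered + eps
        else:
            z1 = np.zeros(len(centered))
            z2 = np.zeros(len(centered))
            eps = np.zeros(len(centered))
            me = me_model
        me = np.minimum(me, 99.5)
        for j, i in enumerate(a["idx"]):
            me_true[(i, diet)] = float(me[j])
            latents[(i, diet)] = (float(z1[j]), float(z2[j]), float(eps[j]))

    # pass 3: measured tables
    cols: dict[str, list] = {name: [] for name in _SCHEMAS}
    for i in range(n):
        cols["participants"].append((pids[i], int(seq[i]), float(kcal[i])))
        for slot, period in enumerate((1, 2)):
            diet = ("WD" if period == 1 else "MBD") if seq[i] == 1 else ("MBD" if period == 1 else "WD")
            a = arm[diet]
            j = a["idx"].index(i)
            profile, tau, pred = a["profile"][j], a["tau"][j], a["pred"][j]
            z1, z2, eps = latents[(i, diet)]
            me = me_true[(i, diet)]
            intake_gcod = intake_to_cod(profile).total()
            fecal_daily = intake_gcod * (1.0 - me / 100.0)

            ei = profile.kcal_total
            ee = ei - balance[i, slot]
            cols["diet_days"].append(
                (pids[i], diet, period, profile.cho_total_g, profile.fat_g, profile.protein_g,
                 profile.fiber_nsp_g, profile.resistant_starch_g, profile.kcal_total,
                 DIET_PROCESSED[diet], ei, ee)
            )

            recovery = float(_truncnorm(rng, cfg.recovery_mean, cfg.recovery_sd, *cfg.recovery_bounds))
            days = cfg.period_days
            wet_daily = float(_truncnorm(rng, cfg.wet_weight_g_day[diet], cfg.wet_weight_sd, 40.0))
            cod_g = fecal_daily * days * recovery * _lognoise(rng, cfg.cod_cv)
            peg_g = cfg.peg_dose_g_day * days * recovery * _lognoise(rng, cfg.peg_assay_cv)
            wet_g = wet_daily * days * recovery

            z_prop = z1 if diet == "MBD" else float(rng.standard_normal())
            kap = cfg.scfa_sibling_rho
            mix = math.sqrt(max(1.0 - kap * kap, 0.0))
            z_ac = kap * z_prop + mix * rng.standard_normal()
            z_bu = kap * z_prop + mix * rng.standard_normal()
            prop_total = max(cfg.propionate_mean_mg[diet] + cfg.propionate_sd_mg[diet] * z_prop, 50.0)
            ac_total = max(cfg.acetate_mean_mg[diet] + cfg.acetate_sd_mg[diet] * z_ac, 100.0)
            bu_total = max(cfg.butyrate_mean_mg[diet] + cfg.butyrate_sd_mg[diet] * z_bu, 50.0)
            acetate_mg = ac_total * recovery * _lognoise(rng, cfg.scfa_cv)
            propionate_mg = prop_total * recovery * _lognoise(rng, cfg.scfa_cv)
            butyrate_mg = bu_total * recovery * _lognoise(rng, cfg.scfa_cv)

            daily_copies = 10.0 ** (cfg.log10_copies_mean[diet] + cfg.log10_copies_sd * (z2 if diet == "MBD" else rng.standard_normal()))
            copies_per_g = daily_copies * days * recovery / wet_g * _lognoise(rng, cfg.copies_cv)
            cols["fecal_composites"].append(
                (pids[i], diet, period, days, wet_g, cod_g, peg_g, acetate_mg, propionate_mg, butyrate_mg, copies_per_g)
            )

            ctt_meas = max(tau + rng.normal(0.0, cfg.ctt_assay_sd_h), 2.0) if cfg.ctt_assay_sd_h > 0 else tau
            si_transit = float(_truncnorm(rng, 4.5, 1.2, 1.0))
            ph_shift = -0.1 if diet == "MBD" else 0.0
            cols["ctt"].append(
                (pids[i], diet, period, ctt_meas, si_transit,
                 rng.normal(6.8 + ph_shift, 0.35), rng.normal(6.4 + ph_shift, 0.30))
            )

            lam = cfg.serum_fecal_rho
            bases = {"acetate": 60.0, "propionate": 5.0, "butyrate": 3.0}
            zf = {"acetate": 0.0, "propionate": (z1 if diet == "MBD" else 0.0), "butyrate": 0.0}
            diet_scale = 1.3 if diet == "MBD" else 1.0
            serum = {
                acid: bases[acid] * diet_scale
                * math.exp(0.3 * (lam * zf[acid] + math.sqrt(1.0 - lam * lam) * rng.standard_normal()))
                for acid in bases
            }
            cols["serum_scfa"].append((pids[i], diet, period, serum["acetate"], serum["propionate"], serum["butyrate"]))

            cols["hormone_timepoints"].extend(_hormone_rows(rng, pids[i], diet, period))

            still = rng.random(cfg.sleep_window_min) < cfg.still_minute_prob
            counts = np.where(still, rng.integers(0, 3, cfg.sleep_window_min), 6 + rng.poisson(9.0, cfg.sleep_window_min))
            cols["activity_minutes"].extend(
                (pids[i], diet, period, int(m), int(c)) for m, c in enumerate(counts)
            )

            cols["truth"].append(
                (pids[i], diet, period, int(seq[i]), tau, me, pred.me_percent, z1, z2, eps,
                 recovery, intake_gcod, fecal_daily)
            )

    frames = {name: pd.DataFrame(cols[name], columns=_SCHEMAS[name]) for name in _SCHEMAS}
    return Cohort(**frames, config=cfg)


# --------------------------------------------------------------------------
# derived views used by downstream analyses


def measured_me_table(cohort: Cohort) -> pd.DataFrame:
    """Measured host ME per participant-period via the fecal-accounting path."""
    comps = cohort.fecal_composites
    diets = cohort.diet_days.set_index(["participant_id", "period"])
    seqs = cohort.participants.set_index("participant_id")["sequence"]
    dose = cohort.config.peg_dose_g_day if cohort.config else 1.5
    rows = []
    for _, row in comps.iterrows():
        comp = fecal.FecalComposite(
            wet_weight_g=row.wet_weight_g,
            cod_g=row.cod_g,
            peg_g=row.peg_g,
            scfa_mg={"acetate": row.acetate_mg, "propionate": row.propionate_mg, "butyrate": row.butyrate_mg},
            copies_per_g=row.copies_per_g,
            period_days=row.period_days,
        )
        rec = fecal.peg_recovery(comp, dose)
        d = diets.loc[(row.participant_id, row.period)]
        profile = MacronutrientProfile(
            d.cho_total_g, d.fat_g, d.protein_g, d.fiber_nsp_g, d.resistant_starch_g, d.kcal_total
        )
        intake_gcod = intake_to_cod(profile).total()
        fecal_daily = fecal.normalize_daily(row.cod_g, row.period_days, rec.recovery)
        res = fecal.host_me(fecal_daily, intake_gcod, ei_kcal=d.ei_kcal_day)
        scfa = fecal.total_fecal_scfa(comp, rec.recovery)
        copies_day = fecal.daily_16s_copies(row.copies_per_g, row.wet_weight_g, row.period_days, rec.recovery)
        rows.append(
            (row.participant_id, row.diet, row.period, int(seqs[row.participant_id]),
             res.me_percent, res.fecal_gcod_day, intake_gcod, res.nonmetabolizable_kcal_day,
             rec.recovery, scfa["acetate_mg_day"], scfa["propionate_mg_day"],
             scfa["butyrate_mg_day"], scfa["total_mg_day"], copies_day)
        )
    return pd.DataFrame(
        rows,
        columns=["participant_id", "diet", "period", "sequence", "me_percent", "fecal_gcod_day",
                 "intake_gcod_day", "nonmetabolizable_kcal_day", "recovery", "acetate_mg_day",
                 "propionate_mg_day", "butyrate_mg_day", "total_scfa_mg_day", "copies_per_day"],
    )


def _glp1_iauc(cohort: Cohort, diet: str) -> pd.Series:
    h = cohort.hormone_timepoints
    sub = h[(h.analyte == "glp1") & (h.diet == diet)]
    out = {}
    for pid, df_p in sub.groupby("participant_id"):
        total = 0.0
        for _, df_m in df_p.groupby("meal"):
            start = df_m.time_min.min() + 30.0  # meal start: first grid point is -30
            rel = df_m.time_min.to_numpy(float) - start
            order = np.argsort(rel)
            total += iauc(rel[order], df_m.value.to_numpy(float)[order])
        out[pid] = total
    return pd.Series(out, name="glp1_iauc")


def candidate_matrix(cohort: Cohort, diet: str = "MBD") -> tuple[pd.DataFrame, dict[str, str], pd.Series]:
    """The 15-factor candidate table, family labels, and the ME outcome.

    All factors are computed from the *measured* tables (fecal accounting
    with PEG normalization, measured CTT, serum assays, hormone iAUC), i.e.
    what an analyst would actually have.
    """
    me = measured_me_table(cohort)
    me_d = me[me.diet == diet].set_index("participant_id")
    ctt = cohort.ctt
    ctt_d = ctt[ctt.diet == diet].set_index("participant_id")
    serum = cohort.serum_scfa
    serum_d = serum[serum.diet == diet].set_index("participant_id")
    cand = pd.DataFrame(index=me_d.index)
    cand["biomass_log10_copies"] = np.log10(me_d["copies_per_day"])
    cand["ctt_h"] = ctt_d["ctt_h"]
    cand["si_transit_h"] = ctt_d["si_transit_h"]
    cand["ileocecal_ph"] = ctt_d["ileocecal_ph"]
    cand["fecal_acetate_mg_day"] = me_d["acetate_mg_day"]
    cand["fecal_propionate_mg_day"] = me_d["propionate_mg_day"]
    cand["fecal_butyrate_mg_day"] = me_d["butyrate_mg_day"]
    cand["fecal_total_scfa_mg_day"] = me_d["total_scfa_mg_day"]
    cand["fecal_acetate_propionate_ratio"] = me_d["acetate_mg_day"] / me_d["propionate_mg_day"]
    cand["serum_acetate_um"] = serum_d["acetate_um"]
    cand["serum_propionate_um"] = serum_d["propionate_um"]
    cand["serum_butyrate_um"] = serum_d["butyrate_um"]
    cand["serum_total_um"] = serum_d[["acetate_um", "propionate_um", "butyrate_um"]].sum(axis=1)
    cand["serum_acetate_propionate_ratio"] = serum_d["acetate_um"] / serum_d["propionate_um"]
    cand["glp1_iauc"] = _glp1_iauc(cohort, diet)
    outcome = me_d["me_percent"].rename("me_percent")
    return cand, dict(CANDIDATE_FAMILIES), outcome
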