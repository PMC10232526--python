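"""Transit-reaction-absorption model: balances, limits, monotonicity, calibration."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gutenergy.diets import DIET_PROCESSED, reference_diets
from gutenergy.gut_model import (
    DEFAULT_BOUNDS,
    CalibrationTarget,
    GutModel,
    GutModelParams,
    ParameterError,
    calibrate,
    colon_ferment,
    predict_me,
    reference_predictions,
    upper_gi_absorb,
)
from gutenergy.stoichiometry import CODVector, MacronutrientProfile, intake_to_cod


def random_params(rng) -> GutModelParams:
    y = rng.uniform(0.05, 0.5)
    g = rng.uniform(0.0, 1.0 - y) * 0.5
    s = rng.dirichlet(np.ones(4))
    return GutModelParams(
        d_ass=rng.uniform(0.5, 1.0),
        d_protein=rng.uniform(0.5, 1.0),
        d_fat=rng.uniform(0.5, 1.0),
        particle_penalty=rng.uniform(0.0, 0.05),
        k_rs=rng.uniform(0.0, 1.0),
        k_nsp=rng.uniform(0.0, 1.0),
        k_residual=rng.uniform(0.0, 1.0),
        biomass_yield=y,
        gas_fraction=g,
        f_abs=rng.uniform(0.0, 1.0),
        endogenous_gcod_day=rng.uniform(0.0, 30.0),
        scfa_split={"acetate": s[0], "propionate": s[1], "n_butyrate": s[2], "iso_butyrate": s[3]},
    )


def random_profile(rng) -> MacronutrientProfile:
    fib, rs = rng.uniform(0, 80), rng.uniform(0, 50)
    avail = rng.uniform(50, 350)
    fat, prot = rng.uniform(30, 150), rng.uniform(30, 150)
    kcal = (avail + rs) * 4 + fib * 2 + prot * 4 + fat * 9
    return MacronutrientProfile(avail + fib + rs, fat, prot, fib, rs, kcal)


def test_params_validation():
    with pytest.raises(ParameterError):
        GutModelParams(biomass_yield=0.7, gas_fraction=0.5)
    with pytest.raises(ParameterError):
        GutModelParams(scfa_split={"acetate": 0.9, "propionate": 0.2, "n_butyrate": 0.0, "iso_butyrate": 0.0})
    with pytest.raises(ParameterError):
        GutModelParams(d_ass=1.2)


class TestUpperGI:
    def test_zero_intake(self):
        absorbed, influent = upper_gi_absorb(CODVector(), GutModelParams())
        assert absorbed == 0.0 and influent.total() == 0.0

    def test_full_digestion_limit(self):
        params = GutModelParams(d_ass=1.0, particle_penalty=0.0)
        intake = CODVector(ass_gcod=100.0)
        absorbed, influent = upper_gi_absorb(intake, params, processed=False)
        assert absorbed == pytest.approx(100.0) and influent.total() == pytest.approx(0.0)

    def test_fiber_and_rs_pass_to_colon(self):
        intake = CODVector(rs_gcod=30.0, nsp_gcod=50.0)
        absorbed, influent = upper_gi_absorb(intake, GutModelParams())
        assert absorbed == 0.0
        assert influent.rs_gcod == 30.0 and influent.nsp_gcod == 50.0

    def test_particle_penalty_applies_only_unprocessed(self):
        intake = CODVector(ass_gcod=100.0)
        a_proc, _ = upper_gi_absorb(intake, GutModelParams(), processed=True)
        a_raw, _ = upper_gi_absorb(intake, GutModelParams(), processed=False)
        assert a_proc - a_raw == pytest.approx(100.0 * GutModelParams().particle_penalty)

    def test_cod_conserved(self, rng):
        for _ in range(20):
            intake = intake_to_cod(random_profile(rng))
            params = random_params(rng)
            absorbed, influent = upper_gi_absorb(intake, params, processed=bool(rng.integers(2)))
            assert absorbed + influent.total() == pytest.approx(intake.total(), rel=1e-12)


class TestColon:
    def test_zero_transit_means_no_fermentation(self):
        influent = CODVector(rs_gcod=30.0, nsp_gcod=40.0, ass_gcod=10.0)
        out = colon_ferment(influent, 10.0, 0.0, GutModelParams())
        assert out.fermented == 0.0 and out.biomass == 0.0
        assert out.fecal_residual_total() == pytest.approx(influent.total() + 10.0)

    def test_fast_kinetics_limit(self):
        params = GutModelParams(k_rs=1e6)
        out = colon_ferment(CODVector(rs_gcod=30.0), 0.0, 48.0, params)
        assert out.fecal_residual["rs"] == pytest.approx(0.0, abs=1e-3)

    def test_internal_balances(self, rng):
        for _ in range(20):
            params = random_params(rng)
            influent = intake_to_cod(random_profile(rng))
            out = colon_ferment(influent, rng.uniform(0, 20), rng.uniform(0, 120), params)
            for name in ("rs", "nsp", "residual"):
                share = out.influent[name]
                assert out.fecal_residual[name] <= share + 1e-12
            assert out.fermented == pytest.approx(
                out.biomass + out.gas + out.scfa_produced_total(), rel=1e-9
            )
            assert out.influent_total() == pytest.approx(
                out.fermented + out.fecal_residual_total(), rel=1e-9
            )


class TestPredictME:
    def test_nothing_reaches_colon_gives_100(self):
        params = GutModelParams(d_ass=1.0, d_protein=1.0, d_fat=1.0, particle_penalty=0.0, endogenous_gcod_day=0.0)
        profile = MacronutrientProfile(200.0, 50.0, 60.0, 0.0, 0.0, kcal_total=1490.0)
        assert predict_me(profile, params).me_percent == pytest.approx(100.0)

    def test_me_increases_with_f_abs(self):
        mbd, _ = reference_diets()
        grid = [predict_me(mbd, GutModelParams(f_abs=f), processed=False).me_percent for f in np.linspace(0.1, 0.99, 8)]
        assert np.all(np.diff(grid) > 0)

    def test_me_nondecreasing_in_ctt(self, calibrated):
        mbd, _ = reference_diets()
        taus = np.linspace(0.0, 120.0, 25)
        mes = [predict_me(mbd, calibrated, ctt_mode="measured", ctt_h=t, processed=False).me_percent for t in taus]
        assert np.all(np.diff(mes) >= -1e-12)

    def test_wd_exceeds_mbd_default_and_calibrated(self, calibrated):
        mbd, wd = reference_diets()
        for params in (GutModelParams(), calibrated):
            me_m = predict_me(mbd, params, processed=DIET_PROCESSED["MBD"]).me_percent
            me_w = predict_me(wd, params, processed=DIET_PROCESSED["WD"]).me_percent
            assert me_w > me_m

    def test_breakdown_sums_to_fecal(self, calibrated):
        mbd, _ = reference_diets()
        pred = predict_me(mbd, calibrated, processed=False)
        assert sum(pred.fecal_breakdown.values()) == pytest.approx(pred.fecal_gcod_day, rel=1e-12)
        assert pred.me_percent == pytest.approx(100.0 * (1 - pred.fecal_gcod_day / pred.intake_gcod_day))


class TestCalibrate:
    def test_targets_met_by_defaults_returns_defaults(self):
        defaults = GutModelParams()
        preds = reference_predictions(defaults)
        targets = [CalibrationTarget(k, v, 0.15) for k, v in preds.items()]
        res = calibrate(targets=targets)
        for name in DEFAULT_BOUNDS:
            assert getattr(res.params, name) == pytest.approx(getattr(defaults, name), abs=1e-6)

    def test_single_parameter_matches_bisection_oracle(self):
        # one free parameter (biomass yield), one target: the MBD biomass;
        # fermented COD is independent of Y, so the root is Y* = target/fermented
        target = CalibrationTarget("biomass_mbd", 15.0, 0.15)
        bounds = {name: (getattr(GutModelParams(), name),) * 2 for name in DEFAULT_BOUNDS}
        bounds["biomass_yield"] = (0.10, 0.30)

        def f(y):
            return reference_predictions(GutModelParams(biomass_yield=y))["biomass_mbd"] - 15.0

        lo, hi = 0.10, 0.30
        for _ in range(60):  # bisection oracle
            mid = 0.5 * (lo + hi)
            if f(lo) * f(mid) <= 0:
                hi = mid
            else:
                lo = mid
        res = calibrate(targets=[target], bounds=bounds)
        assert res.params.biomass_yield == pytest.approx(0.5 * (lo + hi), abs=1e-6)

    def test_infeasible_bounds_rejected(self):
        with pytest.raises(ParameterError):
            calibrate(bounds={"biomass_yield": (0.3, 0.1)})

    def test_model_results_wrapper(self, calibrated):
        results = GutModel().fit()
        assert results.params == calibrated
        text = results.summary()
        assert "biomass_mbd" in text and "f_abs" in text
        mbd, _ = reference_diets()
        assert results.predict(mbd, processed=False).me_percent == pytest.approx(
            predict_me(mbd, calibrated, processed=False).me_percent
        )
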