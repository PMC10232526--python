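"""Synthetic cohort: determinism, round-trip, validation, direction properties."""

import numpy as np
import pandas as pd
import pytest

from gutenergy.cohort import (
    _SCHEMAS,
    Cohort,
    GeneratorConfig,
    candidate_matrix,
    generate_cohort,
    measured_me_table,
)
from gutenergy.diets import reference_diets
from gutenergy.endpoints import motion_free_sleep


class TestReferenceDiets:
    def test_isocaloric_and_macronutrient_matched(self):
        mbd, wd = reference_diets(2000.0)
        assert mbd.kcal_total == wd.kcal_total == 2000.0
        assert mbd.fat_g == pytest.approx(wd.fat_g)
        assert mbd.protein_g == pytest.approx(wd.protein_g)
        # 50/34/16 kcal split, fiber at 2 kcal/g
        atwater = (mbd.available_cho_g + mbd.resistant_starch_g) * 4 + mbd.fiber_nsp_g * 2
        assert atwater == pytest.approx(0.50 * 2000.0)
        assert mbd.fat_g * 9 == pytest.approx(0.34 * 2000.0)
        assert mbd.protein_g * 4 == pytest.approx(0.16 * 2000.0)

    def test_fiber_and_rs_contrast(self):
        mbd, wd = reference_diets(2000.0)
        assert (mbd.fiber_nsp_g, mbd.resistant_starch_g) == (45.0, 30.0)
        assert (wd.fiber_nsp_g, wd.resistant_starch_g) == (15.0, 3.0)
        # WD fiber density mirrors habitual ~7.5 g/1000 kcal intake
        assert wd.fiber_nsp_g / 2.0 == pytest.approx(7.5)

    def test_linear_scaling(self):
        mbd2000, _ = reference_diets(2000.0)
        mbd2500, _ = reference_diets(2500.0)
        assert mbd2500.fiber_nsp_g == pytest.approx(mbd2000.fiber_nsp_g * 1.25)
        assert mbd2500.kcal_total == pytest.approx(2500.0)


class TestGeneration:
    def test_same_seed_reproduces_bundle_exactly(self, tmp_path):
        a = generate_cohort(GeneratorConfig(seed=7))
        b = generate_cohort(GeneratorConfig(seed=7))
        for name in _SCHEMAS:
            pd.testing.assert_frame_equal(getattr(a, name), getattr(b, name))
        a.write_bundle(tmp_path / "a")
        b.write_bundle(tmp_path / "b")
        for name in _SCHEMAS:
            assert (tmp_path / "a" / f"{name}.csv").read_bytes() == (tmp_path / "b" / f"{name}.csv").read_bytes()

    def test_different_seeds_differ(self):
        a = generate_cohort(GeneratorConfig(seed=1))
        b = generate_cohort(GeneratorConfig(seed=2))
        assert not a.truth["me_true"].equals(b.truth["me_true"])

    def test_design_structure(self, default_cohort):
        parts = default_cohort.participants
        assert len(parts) == 17
        assert (parts.sequence == 1).sum() == 8 and (parts.sequence == 2).sum() == 9
        dd = default_cohort.diet_days
        # every participant sees both diets, one per period, alternating by sequence
        per = dd.groupby("participant_id")["diet"].nunique()
        assert (per == 2).all()
        merged = dd.merge(parts, on="participant_id")
        seq1_p1 = merged[(merged.sequence == 1) & (merged.period == 1)]
        assert (seq1_p1.diet == "WD").all()

    def test_tables_pass_downstream_validation(self, default_cohort):
        me = measured_me_table(default_cohort)
        assert len(me) == 34
        assert (me.me_percent < 100).all() and (me.me_percent > 50).all()
        cand, fam, outcome = candidate_matrix(default_cohort)
        assert cand.shape == (17, 15)
        assert set(cand.columns) == set(fam)
        assert cand.notna().all().all()
        assert len(outcome) == 17

    def test_round_trip_bundle(self, tmp_path, default_cohort):
        default_cohort.write_bundle(tmp_path / "bundle")
        back = Cohort.read_bundle(tmp_path / "bundle")
        for name in _SCHEMAS:
            pd.testing.assert_frame_equal(
                getattr(back, name), getattr(default_cohort, name), check_dtype=False
            )

    def test_empty_cohort_round_trip(self, tmp_path):
        empty = Cohort(**{name: pd.DataFrame(columns=cols) for name, cols in _SCHEMAS.items()})
        empty.write_bundle(tmp_path / "empty")
        back = Cohort.read_bundle(tmp_path / "empty")
        for name, cols in _SCHEMAS.items():
            assert list(getattr(back, name).columns) == cols
            assert len(getattr(back, name)) == 0

    def test_schema_mismatch_is_descriptive(self, tmp_path, default_cohort):
        default_cohort.write_bundle(tmp_path / "bad")
        df = pd.read_csv(tmp_path / "bad" / "ctt.csv").drop(columns=["ctt_h"])
        df.to_csv(tmp_path / "bad" / "ctt.csv", index=False)
        with pytest.raises(ValueError, match="ctt_h"):
            Cohort.read_bundle(tmp_path / "bad")


class TestDirectionProperties:
    def test_me_lower_on_mbd_for_most_participants(self, default_cohort):
        me = measured_me_table(default_cohort)
        piv = me.pivot_table(index="participant_id", columns="diet", values="me_percent")
        assert int((piv.MBD < piv.WD).sum()) >= 15

    def test_wd_me_range_narrower_than_mbd(self, default_cohort):
        me = measured_me_table(default_cohort)
        piv = me.pivot_table(index="participant_id", columns="diet", values="me_percent")
        assert piv.WD.max() - piv.WD.min() < piv.MBD.max() - piv.MBD.min()

    def test_fecal_scfa_and_copies_higher_on_mbd(self, default_cohort):
        me = measured_me_table(default_cohort)
        piv_scfa = me.pivot_table(index="participant_id", columns="diet", values="total_scfa_mg_day")
        piv_cop = me.pivot_table(index="participant_id", columns="diet", values="copies_per_day")
        assert piv_scfa.MBD.mean() > piv_scfa.WD.mean()
        assert piv_cop.MBD.mean() > piv_cop.WD.mean()

    def test_motion_free_sleep_near_study_value(self, default_cohort):
        act = default_cohort.activity_minutes
        hours = act.groupby(["participant_id", "period"])["counts"].apply(
            lambda c: motion_free_sleep(c.to_numpy())
        )
        assert hours.mean() == pytest.approx(3.5, abs=0.4)

    def test_energy_balance_within_target(self, default_cohort):
        dd = default_cohort.diet_days
        balance = dd.ei_kcal_day - dd.ee_kcal_day
        assert balance.abs().max() < 60.0
        assert abs(balance.mean() - 5.0) < 10.0


class TestClosedLoop:
    def test_noise_free_me_matches_gut_model_exactly(self):
        cfg = GeneratorConfig(seed=3).noise_free()
        cohort = generate_cohort(cfg)
        me = measured_me_table(cohort).set_index(["participant_id", "period"])
        truth = cohort.truth.set_index(["participant_id", "period"])
        for key in truth.index:
            assert me.loc[key, "me_percent"] == pytest.approx(truth.loc[key, "me_model"], rel=1e-9)
            assert truth.loc[key, "me_true"] == pytest.approx(truth.loc[key, "me_model"], rel=1e-12)
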