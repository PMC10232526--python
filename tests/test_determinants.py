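"""Screen/prune/BIC selection pipeline and the 2x2 crossover estimator."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from gutenergy.determinants import (
    MEDeterminants,
    crossover_diet_effect,
    per_sd_effects,
    prune_families,
    screen,
    select_bic,
    stepwise_select,
)


class TestScreen:
    def test_identical_candidate_retained(self, rng):
        y = pd.Series(rng.normal(size=17))
        cand = pd.DataFrame({"self": y, "noise": rng.normal(size=17)})
        table = screen(cand, y)
        assert bool(table.loc["self", "kept"])
        assert table.loc["self", "pearson_p"] < 1e-10

    def test_constant_candidate_skipped(self, rng):
        y = pd.Series(rng.normal(size=17))
        cand = pd.DataFrame({"const": np.ones(17)})
        with pytest.warns(UserWarning):
            table = screen(cand, y)
        assert not bool(table.loc["const", "kept"])

    def test_null_retention_rate_matches_threshold(self, rng):
        # under the null, the Pearson branch alone keeps ~20% of candidates
        n_sim, n = 2000, 17
        y = rng.normal(size=n)
        cand = pd.DataFrame(rng.normal(size=(n, n_sim)), columns=[f"c{i}" for i in range(n_sim)])
        table = screen(cand, pd.Series(y), p_threshold=0.2)
        pearson_rate = float((table["pearson_p"] < 0.2).mean())
        assert pearson_rate == pytest.approx(0.2, abs=0.03)
        # the either-test union rule keeps at least as many
        assert float(table["kept"].mean()) >= pearson_rate


class TestPruneFamilies:
    def test_perfectly_correlated_family_collapses(self, rng):
        x = rng.normal(size=17)
        y = pd.Series(2.0 * x + rng.normal(scale=0.5, size=17))
        cand = pd.DataFrame({"a1": x, "a2": x.copy()})
        kept = prune_families(cand, y, {"a1": "fam", "a2": "fam"})
        assert len(kept) == 1

    def test_strongest_member_represents_family(self, rng):
        driver = rng.normal(size=40)
        y = pd.Series(driver + rng.normal(scale=0.3, size=40))
        cand = pd.DataFrame(
            {
                "propionate": driver + rng.normal(scale=0.2, size=40),
                "acetate": driver + rng.normal(scale=2.0, size=40),
                "butyrate": driver + rng.normal(scale=2.0, size=40),
            }
        )
        kept = prune_families(cand, y, dict.fromkeys(cand.columns, "scfa"))
        assert kept == ["propionate"]

    def test_cross_family_threshold_is_inclusive(self, rng):
        # construct a pair with |rho| just below 0.75: both retained
        n = 400
        a = rng.normal(size=n)
        b = 0.70 * a + np.sqrt(1 - 0.70**2) * rng.normal(size=n)
        y = pd.Series(a + rng.normal(size=n))
        cand = pd.DataFrame({"a": a, "b": b})
        kept = prune_families(cand, y, {"a": "f1", "b": "f2"})
        assert set(kept) == {"a", "b"}
        # and a near-collinear cross-family pair loses its weaker member
        c = a + rng.normal(scale=0.05, size=n)
        cand2 = pd.DataFrame({"a": a, "c": c})
        with pytest.warns(UserWarning):
            kept2 = prune_families(cand2, y, {"a": "f1", "c": "f2"})
        assert len(kept2) == 1


class TestSelectBIC:
    def test_noise_free_single_driver(self, rng):
        x = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        y = pd.Series(3.0 * x["b"] + 1.0)
        chosen, path = select_bic(x, y)
        assert chosen == ("b",)
        assert len(path) == 8  # all subsets of three candidates

    def test_matches_manual_enumeration(self, rng):
        x = pd.DataFrame(rng.normal(size=(18, 3)), columns=list("abc"))
        y = pd.Series(x["a"] - 0.5 * x["c"] + rng.normal(scale=0.5, size=18))
        chosen, path = select_bic(x, y)
        # oracle: recompute BIC for every subset with statsmodels
        import itertools

        best_bic, best_set = None, None
        n = len(y)
        for k in range(4):
            for subset in itertools.combinations("abc", k):
                X = sm.add_constant(x[list(subset)]) if subset else np.ones((n, 1))
                rss = float(sm.OLS(y, X).fit().ssr)
                bic = n * np.log(rss / n) + (k + 1) * np.log(n)
                if best_bic is None or bic < best_bic - 1e-12:
                    best_bic, best_set = bic, tuple(subset)
        assert set(chosen) == set(best_set)

    def test_stepwise_agrees_with_exhaustive_on_small_battery(self, rng):
        for trial in range(20):
            x = pd.DataFrame(rng.normal(size=(25, 3)), columns=list("abc"))
            beta = rng.choice([0.0, 1.5], size=3)
            y = pd.Series(x.to_numpy() @ beta + rng.normal(scale=0.6, size=25))
            exhaustive, _ = select_bic(x, y)
            stepwise = stepwise_select(x, y)
            assert set(stepwise) == set(exhaustive)

    def test_refuses_unidentifiable(self, rng):
        x = pd.DataFrame(rng.normal(size=(6, 4)))
        x.columns = list("abcd")
        with pytest.raises(ValueError):
            select_bic(x, pd.Series(rng.normal(size=6)))


class TestPerSDEffects:
    def test_standardized_predictor_equals_raw_coef(self, rng):
        x = pd.DataFrame({"z": rng.normal(size=30)})
        x["z"] = (x["z"] - x["z"].mean()) / x["z"].std(ddof=1)
        y = pd.Series(2.0 * x["z"] + rng.normal(scale=0.4, size=30))
        table, r2 = per_sd_effects(["z"], x, y)
        assert table.loc["z", "coef_per_sd"] == pytest.approx(table.loc["z", "coef"], rel=1e-9)
        assert 0 < r2 <= 1

    def test_unit_change_invariance(self, rng):
        x = pd.DataFrame({"v": rng.normal(10, 3, size=30)})
        y = pd.Series(0.5 * x["v"] + rng.normal(size=30))
        t1, _ = per_sd_effects(["v"], x, y)
        x2 = pd.DataFrame({"v": 2.0 * x["v"]})
        t2, _ = per_sd_effects(["v"], x2, y)
        assert t1.loc["v", "coef_per_sd"] == pytest.approx(t2.loc["v", "coef_per_sd"], rel=1e-9)
        assert t1.loc["v", "ci_low"] == pytest.approx(t2.loc["v", "ci_low"], rel=1e-9)


def make_crossover(values_by_participant):
    """values_by_participant: {pid: (sequence, period1_value, period2_value)}"""
    rows = []
    for pid, (seq, v1, v2) in values_by_participant.items():
        d1, d2 = ("WD", "MBD") if seq == 1 else ("MBD", "WD")
        rows.append(dict(participant=pid, sequence=seq, period=1, diet=d1, value=v1))
        rows.append(dict(participant=pid, sequence=seq, period=2, diet=d2, value=v2))
    return pd.DataFrame(rows)


class TestCrossover:
    def test_no_effect(self):
        df = make_crossover({f"P{i}": (1 + i % 2, 5.0, 5.0) for i in range(6)})
        res = crossover_diet_effect(df)
        assert res.diet_effect == 0.0 and res.diet_p == 1.0

    def test_pure_additive_diet_effect_recovered_exactly(self):
        delta = 3.0
        df = make_crossover(
            {
                "P1": (1, 10.0, 10.0 + delta),
                "P2": (1, 20.0, 20.0 + delta),
                "P3": (2, 13.0 + delta, 13.0),
                "P4": (2, 23.0 + delta, 23.0),
            }
        )
        res = crossover_diet_effect(df)
        assert res.diet_effect == pytest.approx(delta, rel=1e-12)
        assert res.period_effect == pytest.approx(0.0, abs=1e-12)
        # sequence-2 participants sit 3 units higher at baseline: half the
        # sum-contrast (6) is the sequence effect
        assert res.sequence_effect == pytest.approx(3.0)

    def test_matches_ols_oracle_on_balanced_data(self, rng):
        for _ in range(20):
            n = 12
            seqs = np.array([1] * 6 + [2] * 6)
            subj = rng.normal(0, 2, n)
            diet_eff, period_eff = rng.normal(0, 3, 2)
            data = {}
            for i in range(n):
                base = 50 + subj[i]
                if seqs[i] == 1:  # WD then MBD
                    v1 = base + rng.normal()
                    v2 = base + diet_eff + period_eff + rng.normal()
                else:
                    v1 = base + diet_eff + rng.normal()
                    v2 = base + period_eff + rng.normal()
                data[f"P{i}"] = (seqs[i], v1, v2)
            df = make_crossover(data)
            res = crossover_diet_effect(df)
            X = pd.get_dummies(
                df[["diet", "period"]].assign(sequence=df.sequence.astype(str)),
                columns=["diet", "period", "sequence"],
                drop_first=True,
            ).astype(float)
            fit = sm.OLS(df.value.to_numpy(), sm.add_constant(X)).fit()
            assert res.diet_effect == pytest.approx(fit.params["diet_WD"] * -1.0, abs=1e-10)
            assert res.period_effect == pytest.approx(fit.params["period_2"], abs=1e-10)

    def test_incomplete_participant_excluded(self):
        df = make_crossover({"P1": (1, 1.0, 2.0), "P2": (1, 2.0, 3.0), "P3": (2, 3.0, 2.0), "P4": (2, 4.0, 3.0)})
        df = pd.concat([df, pd.DataFrame([dict(participant="P5", sequence=1, period=1, diet="WD", value=9.0)])])
        with pytest.warns(UserWarning):
            res = crossover_diet_effect(df)
        assert res.excluded == ("P5",)
        assert res.n_participants == 4


def test_pipeline_chooses_true_drivers(rng):
    n = 17
    z1, z2 = rng.normal(size=n), rng.normal(size=n)
    y = pd.Series(90 - 2.1 * z1 - 1.6 * z2 + rng.normal(scale=1.0, size=n))
    cand = pd.DataFrame(
        {
            "propionate": z1,
            "biomass": z2,
            "noise_a": rng.normal(size=n),
            "noise_b": rng.normal(size=n),
        }
    )
    fam = {"propionate": "scfa", "biomass": "biomass", "noise_a": "ph", "noise_b": "hormone"}
    res = MEDeterminants(y, cand, fam).fit()
    assert {"propionate", "biomass"} <= set(res.chosen)
    assert res.r2 > 0.5
    assert "final model" in res.summary()
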