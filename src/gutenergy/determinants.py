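"""Determinants of host metabolizable energy, and the 2x2 crossover estimator.

The multi-step selection procedure mirrors an exploratory determinants
analysis on a small cohort:

1. **Screen** -- keep candidate factors whose Pearson *or* Spearman
   correlation with the outcome has P < 0.2.
2. **Family pruning** -- within each factor family (e.g. the fecal SCFAs)
   keep only the member most strongly correlated with the outcome; across
   families drop the weaker of any pair with |rho| >= 0.75.
3. **BIC selection** -- exhaustive best-subset OLS over the pruned set,
   choosing the model minimizing ``BIC = n*ln(RSS/n) + k*ln(n)`` with k
   counting slopes plus intercept (exhaustive search is exact for <= 15
   candidates; a P-value stepwise variant is retained for fidelity checks).
4. **Per-SD effects** -- each chosen coefficient and its 95% CI scaled by
   the predictor's sample SD.

The 2x2 crossover diet effect is estimated in closed form: with period
differences d_i = y_i(period 1) - y_i(period 2), the diet effect is
(mean d in the sequence starting with the test diet - mean d in the other
sequence)/2, with two-sample t inference; the sequence (carryover) effect
uses participant sums.  This equals the least-squares solution of the
diet + period + sequence linear model on balanced complete data.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "screen",
    "prune_families",
    "select_bic",
    "stepwise_select",
    "per_sd_effects",
    "crossover_diet_effect",
    "SelectionResult",
    "CrossoverResult",
    "MEDeterminants",
    "MEDeterminantsResults",
]


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of the screen -> prune -> BIC pipeline."""

    screened: pd.DataFrame          # per-candidate screen statistics with 'kept'
    pruned: tuple[str, ...]
    chosen: tuple[str, ...]
    coef_per_sd: pd.DataFrame       # effect per predictor SD with 95% CI
    r2: float
    bic_path: pd.DataFrame          # every candidate model with its BIC

    def __post_init__(self) -> None:
        if not set(self.chosen) <= set(self.pruned):
            raise ValueError("chosen terms must be a subset of the pruned set")


@dataclass(frozen=True)
class CrossoverResult:
    diet_effect: float
    diet_p: float
    period_effect: float
    period_p: float
    sequence_effect: float
    sequence_p: float
    n_participants: int
    excluded: tuple[str, ...] = ()


def _corr_pair(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    pr, pp = stats.pearsonr(x, y)
    sr, sp = stats.spearmanr(x, y)
    return float(pr), float(pp), float(sr), float(sp)


def screen(
    candidates: pd.DataFrame,
    outcome: pd.Series,
    p_threshold: float = 0.2,
    min_pairs: int = 5,
) -> pd.DataFrame:
    """Correlation screen: keep factors with Pearson or Spearman P < threshold.

    Returns a table indexed by factor with both correlation coefficients and
    P values and a boolean ``kept`` column.  Constant candidates are skipped
    with a warning (kept = False, statistics NaN).
    """
    rows = []
    y_all = pd.Series(outcome)
    for name in candidates.columns:
        x = candidates[name]
        mask = x.notna() & y_all.notna()
        if mask.sum() < min_pairs:
            raise ValueError(f"candidate {name!r} has fewer than {min_pairs} complete pairs")
        xv, yv = x[mask].to_numpy(float), y_all[mask].to_numpy(float)
        if np.ptp(xv) == 0.0:
            warnings.warn(f"candidate {name!r} is constant; skipped", stacklevel=2)
            rows.append((name, np.nan, np.nan, np.nan, np.nan, False))
            continue
        pr, pp, sr, sp = _corr_pair(xv, yv)
        rows.append((name, pr, pp, sr, sp, bool(pp < p_threshold or sp < p_threshold)))
    return pd.DataFrame(
        rows, columns=["factor", "pearson_r", "pearson_p", "spearman_rho", "spearman_p", "kept"]
    ).set_index("factor")


def _outcome_strength(screened: pd.DataFrame, name: str) -> float:
    row = screened.loc[name]
    return float(np.nanmax([abs(row["pearson_r"]), abs(row["spearman_rho"])]))


def prune_families(
    candidates: pd.DataFrame,
    outcome: pd.Series,
    families: Mapping[str, str],
    rho_threshold: float = 0.75,
    screened: pd.DataFrame | None = None,
) -> list[str]:
    """Collapse each family to its best member, then break strong cross-family pairs.

    ``families`` maps factor name -> family label (required for every
    surviving factor).  Within a family the member most strongly correlated
    with the outcome survives (max of |Pearson|, |Spearman|; ties broken
    lexicographically by name).  Then any cross-family pair with
    |Pearson| or |Spearman| >= ``rho_threshold`` loses its weaker member.
    """
    if screened is None:
        screened = screen(candidates, outcome, p_threshold=1.1)
    names = [n for n in candidates.columns if bool(screened.loc[n, "kept"])] if "kept" in screened else list(candidates.columns)
    missing = [n for n in names if n not in families]
    if missing:
        raise ValueError(f"factors without a family label: {missing}")

    # within-family: keep the best-correlated member (deterministic tie-break)
    survivors: list[str] = []
    for fam in sorted({families[n] for n in names}):
        members = sorted(n for n in names if families[n] == fam)
        best = max(members, key=lambda n: (_outcome_strength(screened, n), [-ord(c) for c in n]))
        survivors.append(best)
    survivors.sort()

    # cross-family: drop the weaker of any prohibitively correlated pair,
    # visiting pairs in descending order of inter-correlation
    pairs = []
    for a, b in itertools.combinations(survivors, 2):
        mask = candidates[a].notna() & candidates[b].notna()
        pr, _, sr, _ = _corr_pair(candidates[a][mask].to_numpy(float), candidates[b][mask].to_numpy(float))
        rho = max(abs(pr), abs(sr))
        if rho >= rho_threshold:
            pairs.append((rho, a, b))
    dropped: set[str] = set()
    for rho, a, b in sorted(pairs, key=lambda t: (-t[0], t[1], t[2])):
        if a in dropped or b in dropped:
            continue
        weaker = min((a, b), key=lambda n: (_outcome_strength(screened, n), [-ord(c) for c in n]))
        dropped.add(weaker)
        warnings.warn(
            f"dropping {weaker!r}: |rho|={rho:.2f} with {(b if weaker == a else a)!r}", stacklevel=2
        )
    return [n for n in survivors if n not in dropped]


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def _bic(rss: float, n: int, k_params: int, tss: float = 1.0) -> float:
    # floor RSS relative to the outcome scale: once a fit is exact to machine
    # precision, only the parameter-count penalty should discriminate
    rss = max(rss, tss * 1e-12, 1e-300)
    return n * np.log(rss / n) + k_params * np.log(n)


def select_bic(candidates: pd.DataFrame, outcome: pd.Series) -> tuple[tuple[str, ...], pd.DataFrame]:
    """Exhaustive best-subset OLS under BIC.

    Returns the BIC-minimal subset and the full BIC path (one row per
    candidate model, including the intercept-only model).  Refuses clearly
    unidentifiable problems (n <= candidates + 2).
    """
    names = list(candidates.columns)
    y = pd.Series(outcome).to_numpy(float)
    n = y.size
    if n <= len(names) + 2:
        raise ValueError(f"n={n} too small to select among {len(names)} candidates")
    X_full = candidates.to_numpy(float)
    tss = float(((y - y.mean()) ** 2).sum())
    rows = []
    best: tuple[float, tuple[str, ...]] | None = None
    for size in range(len(names) + 1):
        for subset in itertools.combinations(range(len(names)), size):
            X = np.column_stack([np.ones(n)] + [X_full[:, j] for j in subset])
            rss = _ols_rss(X, y)
            bic = _bic(rss, n, len(subset) + 1, tss)
            chosen = tuple(names[j] for j in subset)
            rows.append((chosen, len(subset), rss, bic))
            if best is None or bic < best[0] - 1e-12:
                best = (bic, chosen)
    path = pd.DataFrame(rows, columns=["terms", "n_terms", "rss", "bic"]).sort_values("bic", kind="stable")
    return best[1], path.reset_index(drop=True)


def stepwise_select(
    candidates: pd.DataFrame,
    outcome: pd.Series,
    p_enter: float = 0.15,
    p_stay: float = 0.15,
) -> tuple[str, ...]:
    """P-value driven stepwise selection, final model by lowest BIC on the path.

    Mirrors classic stepwise software: entry/stay P thresholds steer which
    models are visited, and the visited model with the lowest BIC is
    returned.  The exhaustive :func:`select_bic` is the definitive selector.
    """
    names = list(candidates.columns)
    y = pd.Series(outcome).to_numpy(float)
    n = y.size
    tss = float(((y - y.mean()) ** 2).sum())

    def model_bic(terms: list[str]) -> float:
        X = sm.add_constant(candidates[terms].to_numpy(float)) if terms else np.ones((n, 1))
        rss = float(sm.OLS(y, X).fit().ssr)
        return _bic(rss, n, len(terms) + 1, tss)

    current: list[str] = []
    visited: dict[tuple[str, ...], float] = {(): model_bic([])}
    while True:
        changed = False
        # forward step: add the most significant candidate below p_enter
        best_p, best_name = None, None
        for name in names:
            if name in current:
                continue
            X = sm.add_constant(candidates[current + [name]].to_numpy(float))
            p = sm.OLS(y, X).fit().pvalues[-1]
            if p < p_enter and (best_p is None or p < best_p):
                best_p, best_name = p, name
        if best_name is not None:
            current.append(best_name)
            changed = True
        # backward step: drop the least significant term above p_stay
        if current:
            X = sm.add_constant(candidates[current].to_numpy(float))
            pvals = sm.OLS(y, X).fit().pvalues[1:]
            worst = int(np.argmax(pvals))
            if pvals[worst] > p_stay:
                current.pop(worst)
                changed = True
        key = tuple(sorted(current))
        if key not in visited:
            visited[key] = model_bic(list(key))
        if not changed:
            # also score every subset of the final path model (all are
            # reachable by backward elimination); pick the BIC minimum
            for r in range(len(current)):
                for sub in itertools.combinations(sorted(current), r):
                    if sub not in visited:
                        visited[sub] = model_bic(list(sub))
            return min(sorted(visited), key=lambda k: visited[k])


def per_sd_effects(
    chosen: Sequence[str],
    candidates: pd.DataFrame,
    outcome: pd.Series,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, float]:
    """Fit the chosen model and report effects per predictor SD with CIs.

    Each raw coefficient (and its CI bounds) is multiplied by the
    predictor's sample SD, so the effect is unit-free; doubling a
    predictor's units leaves its per-SD effect unchanged.  Returns
    (effects table, model R^2).
    """
    y = pd.Series(outcome).to_numpy(float)
    if not chosen:
        return (
            pd.DataFrame(columns=["coef", "sd", "coef_per_sd", "ci_low", "ci_high", "p"]),
            0.0,
        )
    X = sm.add_constant(candidates[list(chosen)].to_numpy(float))
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha)
    rows = []
    for i, name in enumerate(chosen, start=1):
        sd = float(candidates[name].std(ddof=1))
        rows.append(
            (
                name,
                float(fit.params[i]),
                sd,
                float(fit.params[i]) * sd,
                float(ci[i, 0]) * sd,
                float(ci[i, 1]) * sd,
                float(fit.pvalues[i]),
            )
        )
    table = pd.DataFrame(rows, columns=["factor", "coef", "sd", "coef_per_sd", "ci_low", "ci_high", "p"]).set_index("factor")
    return table, float(fit.rsquared)


def crossover_diet_effect(
    records: pd.DataFrame,
    value_col: str = "value",
    diet_order: tuple[str, str] = ("WD", "MBD"),
) -> CrossoverResult:
    """Closed-form 2x2 crossover estimation of diet, period, and sequence effects.

    ``records`` needs columns participant, period (1/2), diet, and the
    outcome.  The diet effect is reported as ``diet_order[1] -
    diet_order[0]`` (default MBD - WD).  Participants lacking either period
    are excluded with a warning (complete-case analysis).
    """
    ref, test = diet_order
    required = {"participant", "period", "diet", value_col}
    if not required <= set(records.columns):
        raise ValueError(f"records must contain columns {sorted(required)}")
    wide = records.pivot_table(index="participant", columns="period", values=value_col, aggfunc="first")
    diets = records.pivot_table(index="participant", columns="period", values="diet", aggfunc="first")
    complete = wide.notna().all(axis=1) if set(wide.columns) >= {1, 2} else pd.Series(False, index=wide.index)
    excluded = tuple(str(p) for p in wide.index[~complete])
    if excluded:
        warnings.warn(f"excluding participants with one period: {excluded}", stacklevel=2)
    wide = wide[complete]
    diets = diets.loc[wide.index]
    if wide.empty:
        raise ValueError("no participant has complete 2x2 data")

    starts_with_test = diets[1] == test
    d = wide[1] - wide[2]      # period-1 minus period-2
    s = wide[1] + wide[2]
    d_test_first, d_ref_first = d[starts_with_test], d[~starts_with_test]
    s_test_first, s_ref_first = s[starts_with_test], s[~starts_with_test]
    if len(d_test_first) < 2 or len(d_ref_first) < 2:
        raise ValueError("each sequence group needs at least 2 complete participants")

    def two_sample(a: pd.Series, b: pd.Series) -> tuple[float, float]:
        """Half the group contrast with pooled-variance two-sample t inference."""
        n1, n2 = len(a), len(b)
        est = (a.mean() - b.mean()) / 2.0
        sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2)) / 2.0
        if se == 0.0:
            return float(est), 1.0 if est == 0.0 else 0.0
        t = est / se
        p = 2.0 * stats.t.sf(abs(t), n1 + n2 - 2)
        return float(est), float(p)

    diet_effect, diet_p = two_sample(d_test_first, d_ref_first)
    # period-2 minus period-1 effect: -(mean of all d's); same contrast machinery
    period_effect, period_p = two_sample(-d_ref_first, d_test_first)
    sequence_effect, sequence_p = two_sample(s_test_first, s_ref_first)
    return CrossoverResult(
        diet_effect=diet_effect,
        diet_p=diet_p,
        period_effect=period_effect,
        period_p=period_p,
        sequence_effect=sequence_effect,
        sequence_p=sequence_p,
        n_participants=int(len(wide)),
        excluded=excluded,
    )


class MEDeterminants:
    """Model object for the determinants-of-ME selection procedure.

    Parameters
    ----------
    outcome : Series of host ME (%) indexed by participant.
    candidates : DataFrame of candidate factors (participants x factors).
    families : mapping factor name -> family label.
    """

    def __init__(self, outcome: pd.Series, candidates: pd.DataFrame, families: Mapping[str, str]):
        self.outcome = pd.Series(outcome)
        self.candidates = pd.DataFrame(candidates)
        self.families = dict(families)

    def fit(
        self,
        p_screen: float = 0.2,
        rho_threshold: float = 0.75,
        selector: str = "exhaustive",
    ) -> "MEDeterminantsResults":
        screened = screen(self.candidates, self.outcome, p_screen)
        pruned = prune_families(
            self.candidates, self.outcome, self.families, rho_threshold, screened=screened
        )
        sub = self.candidates[pruned]
        if selector == "exhaustive":
            chosen, path = select_bic(sub, self.outcome)
        elif selector == "stepwise":
            chosen = stepwise_select(sub, self.outcome)
            _, path = select_bic(sub, self.outcome)
        else:
            raise ValueError(f"unknown selector {selector!r}")
        effects, r2 = per_sd_effects(chosen, self.candidates, self.outcome)
        result = SelectionResult(
            screened=screened,
            pruned=tuple(pruned),
            chosen=tuple(chosen),
            coef_per_sd=effects,
            r2=r2,
            bic_path=path,
        )
        return MEDeterminantsResults(self, result)


class MEDeterminantsResults:
    """Fitted selection pipeline with a readable summary."""

    def __init__(self, model: MEDeterminants, selection: SelectionResult):
        self.model = model
        self.selection = selection

    @property
    def chosen(self) -> tuple[str, ...]:
        return self.selection.chosen

    @property
    def r2(self) -> float:
        return self.selection.r2

    @property
    def coef_per_sd(self) -> pd.DataFrame:
        return self.selection.coef_per_sd

    def summary(self) -> str:
        s = self.selection
        lines = ["Determinants of host metabolizable energy", "=" * 60]
        kept = list(s.screened.index[s.screened["kept"].fillna(False)])
        lines.append(f"screened (P<0.2, either test): {len(kept)}/{len(s.screened)} factors")
        lines.append(f"after family pruning        : {', '.join(s.pruned) or '(none)'}")
        lines.append(f"BIC-selected final model    : {', '.join(s.chosen) or '(intercept only)'}")
        lines.append(f"final model R^2             : {s.r2:.3f}")
        if len(s.coef_per_sd):
            lines.append("-" * 60)
            lines.append(f"{'factor':<28}{'per-SD effect':>14}{'95% CI':>18}")
            for name, row in s.coef_per_sd.iterrows():
                lines.append(
                    f"{name:<28}{row['coef_per_sd']:>+14.2f}"
                    f"   [{row['ci_low']:+.2f}, {row['ci_high']:+.2f}]"
                )
        return "\n".join(lines)
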