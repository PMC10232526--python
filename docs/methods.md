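# Methods

This note documents the models and procedures implemented in `gutenergy`,
their assumptions, the parameters that matter, and the design choices made
where the design was genuinely open. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## COD as the energy currency

Chemical oxygen demand counts electron equivalents: the grams of O2 required
to oxidize organic matter completely, with organic nitrogen leaving as
ammonia rather than being oxidized (humans cannot use ammonia as an electron
donor, so ammonia oxidation would overstate energy available to the host).
For a compound CcHhOoNn the combustion balance

    CcHhOoNn + (c + (h-3n)/4 - o/2) O2 -> c CO2 + n NH3 + (h-3n)/2 H2O

gives the theoretical oxygen demand (ThOD) per gram. Negative or zero demand
(water, urea, ammonia) is clamped to zero. Standard atomic weights (C 12.011,
H 1.008, O 15.999, N 14.007) are used throughout; the shipped compound
library (`data/compounds.yaml`) tabulates molar masses, which are verified
against the composition (within 0.5 g/mol) at load time.

Per-class dietary COD factors are recomputed at import from representative
compounds rather than hard-coded: sugars from glucose (1.066 gCOD/g),
polymeric carbohydrate — starch, resistant starch (RS), non-starch
polysaccharide (NSP) — from anhydroglucose (1.184; condensation raises COD
per gram), protein from a generic residue C16H24O5N4 (1.498, nitrogen
excluded from oxidation), fat from tripalmitin (2.874). Available
sugar+starch (total carbohydrate minus RS minus fiber) uses a configurable
20:80 sugar:starch blend; moving the split end-to-end changes diet totals by
under 2%.

kcal and COD are related per diet: the ratio kcal_total / total dietary gCOD
is defined so that round-tripping a whole diet is exact. This is a
reconstruction — fiber carries full COD but only 2 kcal/g of metabolizable
energy, so no universal kcal/gCOD constant exists, which is exactly why the
ratio is diet-specific. Typical diets fall in 0.25-0.40 gCOD/kcal; this
sanity band is property-tested.

## Fecal accounting

Feces are pooled over the collection period (default 6 days) into a single
composite, so one PEG-recovery factor applies per composite, not per stool.
Recovery = (PEG recovered / period) / (1.5 g/day dose); daily values are
composite / (period x recovery). Recovery above 1 is retained with a warning
rather than capped — assay error can exceed dosing, and capping would bias
daily estimates downward. Recovery outside [0.3, 1.2] sets a warning flag.
Zero recovered PEG makes normalization impossible and raises.

Host ME is fecal-based: 100 x (1 - fecal/intake gCOD). Fecal COD above
intake yields a negative ME, flagged as implausible but returned (assay
noise can produce it). "Non-metabolizable kcal" is EI x (1 - ME/100); the
complementary absorbed-kcal quantity is also exposed because the verbal
definition ("multiplying ME by energy intake") literally names the absorbed
quantity — both readings are available, the labeled one is the default.

## The gut model

Three compartments in daily-average gCOD flows:

1. **Upper GI.** The host absorbs digestibility fractions d of available
   sugar+starch, protein, and fat; fiber and RS pass entirely to the colon.
   Minimally processed diets (large particles) subtract a particle penalty
   delta from each digestibility.
2. **Colon.** Three kinetic classes — RS, NSP, and a residual class pooling
   undigested macronutrients plus an endogenous host input E (mucin,
   sloughed cells) — ferment to extent phi_i = k_i tau / (1 + k_i tau) at
   residence time tau (the colonic transit time, CTT). This steady-state
   CSTR closure replaces a full ODE transit chain: daily-average flows are
   the only observables here, and the closure preserves the monotone CTT
   dependence and exact COD balance. Fermented COD splits into biomass
   (yield Y), gas (fraction g), and SCFAs (remainder, split 0.50 / 0.22 /
   0.22 / 0.06 across acetate, propionate, n-butyrate, iso-butyrate on a COD
   basis; a single global split because no class-resolved split is
   established). A fraction f_abs of produced SCFA is absorbed.
3. **Feces/body.** Fecal COD = unfermented residue + biomass + unabsorbed
   SCFA. Fecal-based ME counts excreted gas as "metabolized" because the
   measured endpoint is defined on feces; a true-absorption ME
   (upper-GI + SCFA absorbed over intake) is reported alongside.

Global COD conservation — intake + E = upper-GI absorbed + SCFA absorbed +
gas + fecal — holds to 1e-9 relative for any parameter set and is tested
over a 1000-point random sweep.

### Parameters, defaults, and calibration

| parameter | units | default | bounds | meaning |
|---|---|---|---|---|
| d_ass, d_protein, d_fat | fraction | 0.96, 0.91, 0.95 | 0.90-0.99, 0.85-0.97, 0.90-0.99 | upper-GI digestibility |
| particle_penalty | fraction | 0.03 | 0-0.05 | digestibility loss on unprocessed diets |
| k_rs, k_nsp, k_residual | 1/h | 0.08, 0.05, 0.10 | 0.01-0.50 | colonic fermentation rates |
| biomass_yield Y | COD fraction | 0.20 | 0.10-0.30 | fermented COD to microbial cells |
| gas_fraction g | COD fraction | 0.04 | fixed | fermented COD to H2/CH4 |
| f_abs | fraction | 0.95 | 0.50-0.99 | produced SCFA absorbed by host |
| endogenous_gcod_day E | gCOD/day | 15 | 0-25 | host-derived colonic input |
| ctt_fixed_h | h | 48 | fixed | population-level CTT |

Defaults are physiological-literature values; `calibrate()` refines the free
parameters by bounded least squares (scipy `least_squares`, trust-region
reflective) on tolerance-scaled residuals against seven published model
predictions for the 2000-kcal reference diets: biomass 19.6/9.4 gCOD/day
(MBD/WD), SCFA absorbed 72.3/36.4 gCOD/day, fixed-CTT ME 92.4/95.2%, and a
110 kcal/day fecal-energy difference. Scaling each residual by its tolerance
(15% relative; 1.5 ME percentage points) makes the optimizer trade targets
against each other in tolerance units. The seven targets are not jointly
consistent at a single reference-diet pair (equal-intake MEs of 92.4/95.2%
imply a ~56 kcal fecal difference, not 110), so the fitted optimum sits near
the edges of the ME bands; every target still lands inside its tolerance.
Calibration is deterministic: fixed starting points (the defaults and the
bound-box midpoint), no randomness. Degenerate bounds (lo == hi) pin a
parameter; inverted bounds raise.

### Reference diets

Both diets supply 50% CHO / 34% fat / 16% protein of kcal (the study
population's habitual profile, which matched the study diets). Per 2000
kcal: MBD 45 g fiber + 30 g RS, minimally processed; WD 15 g fiber + 3 g RS,
processed (the WD fiber density, 7.5 g/1000 kcal, mirrors habitual Western
intake). Fiber counts 2 kcal/g when gram amounts are derived from kcal
targets, keeping Atwater kcal and profile grams mutually consistent.
Profiles scale linearly with energy intake. The MBD fiber/RS grams are
stated assumptions (menu-level composition is not public); they are exposed
in configuration and the calibration tolerances absorb the uncertainty.

## Agreement statistics

Lin's concordance correlation uses population (n-denominator) moments per
the original definition — the n vs n-1 choice changes rho_c at small n, so
it is fixed and documented. cb = rho_c / r is NaN when r = 0 (rho_c is still
returned); zero variance in either vector is a degenerate-input error.
Bland-Altman differences are oriented measured - modeled; limits of
agreement are mean +/- 1.96 sample SD, the mean-difference CI is t-based,
and proportional bias is the OLS slope of differences on pair means. The
paired t-test is classical (df = n-1, two-sided); zero-variance differences
report P = 1 (zero mean) or P = 0 (non-zero mean) rather than raising.

## Determinants of ME

The selection procedure mirrors an exploratory small-cohort analysis:

1. **Screen**: keep factors with Pearson *or* Spearman P < 0.2 against the
   outcome (both named without a rule in the source procedure; the union is
   the permissive reading). Constant factors are skipped with a warning.
2. **Family pruning**: within each factor family keep the member most
   strongly correlated with the outcome (max of |Pearson|, |Spearman|; ties
   broken lexicographically and logged); across families drop the weaker
   member of any pair with |rho| >= 0.75.
3. **Selection**: exhaustive best-subset OLS under
   BIC = n ln(RSS/n) + k ln(n), k counting slopes plus intercept (BIC
   conventions differ by constants that cancel in comparisons; this one is
   fixed and documented). Exhaustive search is exact for <= 15 candidates
   and removes the entry/stay-threshold ambiguity of stepwise software. A
   stepwise variant (P-driven steps, lowest-BIC model on the visited path)
   is retained for fidelity checks and must agree with exhaustive search on
   small batteries. RSS is floored at TSS x 1e-12 so machine-zero fits are
   compared by parameter count alone. Problems with n <= candidates + 2 are
   refused as unidentifiable.
4. **Per-SD effects**: each chosen coefficient and its 95% CI are multiplied
   by the predictor's sample SD (statsmodels OLS); effects are therefore
   invariant to the predictor's units.

The 2x2 crossover estimator is closed-form: with period differences
d_i = y_i1 - y_i2, the diet effect is half the between-sequence contrast of
d (two-sample pooled-t inference), the period effect is minus half their
sum, and the sequence (carryover) effect is half the between-sequence
contrast of participant sums. On balanced complete data this equals the
least-squares solution of the diet + period + sequence linear model (tested
against statsmodels OLS to 1e-10). Participants missing a period are
excluded with a warning (complete-case).

## The synthetic cohort

The generator emulates the study conditions: n = 17 with an 8/9 sequence
split (WD-first / MBD-first), ~2000 +/- 250 kcal energy-balanced diets
(EI - EE ~ N(5, 15) kcal/day, inside the +/-50 kcal target), true CTT drawn
per diet from truncated normals at the published means (29.7 h MBD, 39.2 h
WD; SD = s.e.m. x sqrt(17), truncated at 5 h), PEG recovery ~ truncated
normal (0.9, 0.08) on [0.6, 1.1], and lognormal assay noise (COD 3%, SCFA
5%, 16S 10%, PEG 1.8% — the published assay RSD). Measured CTT adds 2 h of
assay noise. Consumed diets wobble 2% around the designed grams.

Measured ME on the MBD arm has the generative structure

    ME_i = 89.5 - 2.1 z1_i - 1.6 z2_i + eps_i        (%),

where z1 (fecal propionate, SD 858.6 mg/6 days) and z2 (biomass, SD 0.49
log10 16S copies/day) are standard-normal latents and eps is sized so the
two latents carry 58% of the ME variance (`target_r2` is this population
fraction; at n = 17 the upward small-sample bias of the sample R^2 and
assay attenuation of the measured predictors roughly cancel, so the mean
sample R^2 of the two-term model is also ~0.59). The CTT pathway is
*mediated*: z1 is correlated (-0.5) with the gut model's CTT-driven ME, so
measured CTT correlates with measured ME and survives the screen, but has
no partial effect once the two microbial factors are in the model — the
transit model alone cannot generate the observed MBD ME spread, which is
precisely why the microbial factors matter. Fecal acetate and butyrate carry
their own latents coupled 0.4 to z1: siblings are intercorrelated but
propionate retains the strongest outcome correlation in its family. The WD
arm is anchored at 95.4% with the model's CTT variation plus 0.4% noise, so
its ME range is much narrower than the MBD's.

Fecal composites are then derived *backward* from true ME and dietary COD
(fecal gCOD/day = intake x (1 - ME/100)), scaled by period and recovery, and
degraded with assay noise — so the fecal-accounting path recovers ME up to
measurement error, and exactly (1e-9) when noise is off
(`GeneratorConfig.noise_free()`), closing the loop with the gut model.
Hormone curves (leptin, GLP-1, pancreatic polypeptide; 18 timepoints over
three meals on the -30/-15/+30/+60/+120/+180 min grid), minute-level radar
counts (~3.5 motion-free hours of an 8-h window), serum SCFAs, colonic pH,
and small-intestinal transit complete the 15-factor candidate set.

What the generator does **not** emulate: taxonomic composition and sequence
data, menu-level food items, within-period day-to-day dynamics (a single
composite per period), correlated multi-analyte hormone physiology, or any
participant-level covariates (age, sex, BMI). Passing tests therefore show
the pipeline's statistical machinery is correct under the stated generative
assumptions — not that real cohorts satisfy those assumptions.

## Simulation experiments and problem sizes

`recovery_experiment` (200 cohorts, seeds base..base+199) runs best-subset
BIC selection over the three-factor entry set that screening and pruning
produce on study-like data (CTT, fecal propionate, biomass) and fits the
designated two-term final model on every cohort for effect recovery, CI
coverage of the true effects, and R^2. Keeping the recovery/coverage
estimates on the fixed two-term model avoids confounding them with
selective inference. `ctt_mode_experiment` (20 cohorts, pairs pooled across
cohorts for stable concordance estimates) compares fixed-48-h and
measured-CTT predictions against latent-true ME. Cohort counts were chosen
so both experiments complete in well under a minute per hundred cohorts on
one CPU while leaving Monte-Carlo error far smaller than the effects being
measured.

## Known limitations

* The colon closure is a steady-state CSTR; spatially resolved segments,
  community dynamics, pH feedback, and gas speciation are out of scope.
* The kcal/gCOD ratio convention is a per-diet reconstruction; the original
  kcal-to-COD conversion model is external to this package.
* iAUC defaults to the net (signed) convention, with a positive-only variant
  available; the energy-balance sign defaults to EI - EE with the opposite
  convention available.
* The exhaustive BIC selector is exact but not a replication of any specific
  stepwise software path; the stepwise variant approximates one.
* Calibration reconciles mutually inconsistent published targets by
  tolerance-scaled compromise; parameter estimates are therefore effective
  values, not measurements.
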