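# gutenergy

Quantitative bioenergetics of the human gut microbiome, in chemical-oxygen-demand
(COD) units.

Controlled-feeding crossover trials can measure how much dietary energy the gut
microbiome diverts away from the host: feed the same participants a fiber- and
resistant-starch-rich "microbiome enhancer" diet (MBD) and a highly digestible
Western diet (WD) at equal kcal and macronutrients, collect all feces over a
6-day calorimetry block, and express both diet and feces as electron
equivalents (grams of COD). Host metabolizable energy (ME) is then

```
ME% = 100 x (1 - fecal gCOD/day / intake gCOD/day)
```

`gutenergy` implements the full analysis stack around that endpoint, for
researchers in nutrition, microbiome science, and environmental biotechnology:

* **COD stoichiometry** (`gutenergy.stoichiometry`) — theoretical oxygen demand
  per gram from an elemental formula, with nitrogen leaving as ammonia
  (humans do not oxidize ammonia): `ThOD = M_O2 (c + (h - 3n)/4 - o/2) / M`
  for CcHhOoNn. Macronutrient intakes are converted into a five-class COD
  vector (available sugar+starch, resistant starch, non-starch polysaccharide,
  protein, fat) and back to kcal through a diet-specific kcal/gCOD ratio.
* **PEG-marker fecal accounting** (`gutenergy.fecal`) — 6-day fecal composites
  are normalized to 24-h equivalents using recovery of a 1.5 g/day
  polyethylene-glycol marker; host ME, non-metabolizable kcal, daily fecal
  SCFAs, and daily 16S rRNA gene copies (a biomass surrogate) follow.
* **A gut transit-reaction-absorption model** (`gutenergy.gut_model`) — three
  compartments in gCOD/day: upper-GI host digestion, colonic microbial
  fermentation with first-order kinetics and a colonic-transit-time (CTT)
  dependent extent `phi = k*tau/(1 + k*tau)`, COD partitioning into microbial
  biomass, gas, and short-chain fatty acids (SCFAs) partially absorbed by the
  host, and a fecal-based ME prediction. COD is conserved to 1e-9.
  `GutModel().fit()` calibrates the physiological parameters against published
  model predictions by deterministic bounded least squares.
* **Agreement statistics** (`gutenergy.agreement`) — Lin's concordance
  correlation with its precision (r) / accuracy (Cb) decomposition,
  Bland-Altman systematic and proportional bias, paired t.
* **Determinants of ME** (`gutenergy.determinants`) — the multi-step selection
  procedure (P<0.2 correlation screen, factor-family pruning at |rho|>=0.75,
  exhaustive best-subset OLS under BIC, per-SD effects with 95% CIs) plus a
  closed-form 2x2 crossover diet/period/sequence estimator.
* **A synthetic crossover cohort** (`gutenergy.cohort`) — a fully specified
  17-participant generator (8/9 sequence split, ~2000 kcal diets, per-diet CTT
  distributions, PEG recovery noise, fecal composites consistent with the gut
  model plus assay noise) so the entire pipeline is testable without any
  participant data.

## Worked example

```python
from gutenergy import GutModel
print(GutModel().fit().summary())
```

```
Gut model calibration
======================================================
target                fitted   published   rel.err
biomass_mbd            19.36       19.60     -1.2%
biomass_wd              9.51        9.40     +1.2%
scfa_abs_mbd           73.17       72.30     +1.2%
scfa_abs_wd            35.95       36.40     -1.2%
me_mbd                 91.23       92.40     -1.3%
me_wd                  96.37       95.20     +1.2%
fecal_kcal_diff       102.91      110.00     -6.4%
```

Read: on the calibrated 2000-kcal reference diets at a fixed 48-h CTT, the
model routes 19.4 gCOD/day into microbial biomass on the MBD versus 9.5 on the
WD, absorbs 73.2 vs 36.0 gCOD/day of microbially produced SCFAs into the host,
and predicts 91.2% vs 96.4% host metabolizable energy — a ~103 kcal/day extra
fecal energy loss on the MBD. Biomass is >25% of fecal COD on both diets.

Running the determinants pipeline on a synthetic cohort:

```python
from gutenergy import GeneratorConfig, generate_cohort, candidate_matrix, MEDeterminants

cohort = generate_cohort(GeneratorConfig(seed=1))
candidates, families, me = candidate_matrix(cohort)
print(MEDeterminants(me, candidates, families).fit().summary())
```

```
Determinants of host metabolizable energy
============================================================
screened (P<0.2, either test): 7/15 factors
after family pruning        : biomass_log10_copies, ctt_h, fecal_propionate_mg_day, serum_butyrate_um
BIC-selected final model    : biomass_log10_copies, fecal_propionate_mg_day
final model R^2             : 0.728
------------------------------------------------------------
factor                       per-SD effect            95% CI
biomass_log10_copies                 -1.05   [-1.98, -0.12]
fecal_propionate_mg_day              -2.14   [-3.07, -1.21]
```

Read: of 15 candidate host and microbial factors, the screen and family
pruning leave colonic transit plus the two microbial factors; BIC selects
fecal propionate and biomass, and each SD increment of fecal propionate in
this cohort is associated with a 2.1% lower host ME.

A thin CLI wraps the same functionality: `gutenergy synth`, `gutenergy
predict-me`, `gutenergy evaluate`, `gutenergy determinants`.

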