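# Methods

## The analysis

`hbi-swap` models what happens to adult beverage-intake quality and to
weight classification when one 8-oz serving of sugar-sweetened beverage
(SSB) per day is replaced with water. The pipeline is a deterministic
sequence over single-day dietary recalls:

1. **Classification.** Each consumed beverage item is mapped into one of
   eight groups: water; unsweetened coffee/tea; low-fat (<1.5 % fat,
   skim, soy) milk; diet (non-calorically sweetened) beverages; 100 %
   fruit juice; alcohol; whole (≥1.5 % fat) milk; SSB (soda, fruit
   drinks, sweetened coffee/tea, energy/sports drinks, meal-replacement
   drinks). Classification is table-driven with longest-prefix matching
   and fails loudly on unmapped items — a silent default would bias every
   downstream estimate.
2. **Summarization.** Per person: ounces per group, beverage energy,
   percent of energy from beverages (beverage kcal / total recalled
   kcal × 100; 0 when total energy is 0), SSB servings (ounces / 8),
   and the serving bin. The bins partition servings as {0}, (0,1],
   (1,2], (2,∞) — the four-way partition that makes bin prevalences sum
   to 100 %.
3. **HBI scoring** (below).
4. **Substitution.** For every person in an eligible bin (by default all
   SSB consumers): SSB ounces fall by 8 (floored at 0), water ounces
   rise by 8, and both beverage and total energy fall by 100 kcal —
   clamped, by default, at the energy actually present in the person's
   SSB records, so energy can never go negative. One serving is pinned
   to 237 mL of water. The HBI is rescored on the counterfactual
   intake, and the percent change in HBI is computed per person.
5. **Weight scenarios.** Published water-for-SSB intervention trials
   observed weight changes between −0.40 kg (8-month follow-up) and
   −1.99 kg (6-month follow-up). Each scenario applies its delta
   uniformly to substituted persons, recomputes BMI = kg/m² rounded to
   one decimal (half away from zero — the tie rule is a package choice,
   as conventional reporting does not name one), and reassigns the
   categories underweight (<18.5), normal (18.5–24.9), overweight
   (25.0–29.9), obese (≥30.0) on the rounded value. Underweight is
   carried in all outputs so prevalences conserve to 100 %.
6. **Estimation.** All population quantities are survey-weighted.

## HBI scoring engine

The Healthy Beverage Index is a ten-component 0–100 adherence score:
one component per beverage group, one for percent of energy from
beverages, one for meeting the daily fluid requirement (Daily
Recommended Intake: 3.7 L for adult men, 2.7 L for non-pregnant,
non-lactating women; overridable). Each component is configured with a
full-credit band `[standard_lo, standard_hi]`, a `zero_point`, a
`max_points` allocation and a mode. Inside the band a component scores
`max_points`; in `proportional` mode points decay linearly to 0 at the
zero point; `binary` components are all-or-nothing. Totals are
guaranteed to lie in [0, 100] because the ten allocations must sum
to 100.

The engine is config-driven because component standards vary across
index versions; the shipped defaults (`data/hbi_components.yaml`) are:

| component | full credit | zero point | max | mode |
|---|---|---|---|---|
| water (% of fluid req.) | ≥50 % | 0 % | 15 | proportional |
| unsweetened coffee/tea (oz) | ≤32 | 64 | 5 | proportional |
| low-fat milk (oz) | ≤16 | 32 | 5 | proportional |
| diet beverages (oz) | ≤32 | 64 | 5 | proportional |
| 100 % juice (oz) | ≤8 | 16 | 5 | proportional |
| alcohol (oz) | ≤24 | 48 | 5 | proportional |
| whole milk (oz) | ≤8 | 24 | 10 | proportional |
| SSB (oz) | ≤4 | 16 | 20 | proportional |
| % energy from beverages | ≤10 % | 30 % | 20 | proportional |
| meets fluid requirement | ≥100 % | — | 10 | binary |

Rationale: SSB and beverage energy carry the largest allocations, as
they do in the published index; the SSB zero point at two servings and
the energy band anchored at the accepted 10–14 % range make the score
sensitive exactly where the substitution acts. Proportional decay (not
binary steps) is what produces smooth per-person percent changes in
HBI. The fluid-requirement component counts fluid from all eight
groups. Alcohol scoring is not sex-specific by default; a stricter or
sex-specific standard can be supplied via YAML. Substituting water for
SSB can, by construction, never lower any component: SSB and
percent-energy move toward their bands, water moves toward its band,
total fluid volume never falls, and every other metric is unchanged.

## Survey estimation

Point estimates are Hajek weighted means; prevalences are weighted
means of 0/100 indicators. Variances use first-order Taylor
linearization with between-PSU variation within strata,
`Σ_h n_h/(n_h−1) Σ_j (z_hj − z̄_h)²` over PSU totals of the linearized
scores — the standard design-based estimator for a stratified
multistage sample (replicate weights would be the alternative; one
estimator suffices here). Subpopulations (age group × bin cells) are
estimated by zeroing non-domain scores rather than subsetting, keeping
the full design in the variance. Single-PSU strata are centred at the
grand mean of PSU totals; estimates and SEs are invariant to rescaling
all weights. Observed-vs-counterfactual contrasts use a weighted
*paired* t-test on per-person differences (both arms are the same
individuals), with design degrees of freedom (#PSUs − #strata) and
Bonferroni correction over the number of cells actually tested, at
α = 0.05. When no design columns are supplied the SE falls back to a
weighted iid form and is flagged `design_based=False`.

## Synthetic population generator

The generator emulates the statistical structure the analysis needs,
not any real respondent:

- **Age groups** 19–29 / 30–49 / 50–65 / 66+ with shares
  0.190/0.329/0.264/0.217 (the analytic sample's composition).
- **SSB** is zero-inflated gamma per age group: a point mass of
  non-consumers (0.374/0.483/0.634/0.711) and a gamma for consumers
  with means 29.6/27.2/20.8/14.7 oz. Gamma (not lognormal) gives a
  closed-form mean parameterization; shapes 1.96/1.95/2.33/2.32 were
  fitted once so the implied serving-bin proportions track the
  published consumer distribution at the 8 oz and 16 oz cut-points.
- **Other groups** are independent gamma draws with the published
  per-age-group mean ounces (shape 1 by default; water shape 1.5).
  Independence across groups within person is a known simplification —
  real beverage patterns are correlated — so cross-group covariances
  carry no information here.
- **Energy.** Beverage energy uses fixed densities (kcal/fl oz): SSB
  12.5 (so 8 oz = 100 kcal, matching the substitution constant), juice
  14.0, whole milk 18.6, low-fat milk 12.75, alcohol 12.5, coffee/tea
  0.3, water and diet 0. Total energy is normal with the published
  age-group means and realistic per-person SDs (600–750 kcal), floored
  at 500 kcal and never below beverage energy.
- **Anthropometrics.** BMI is lognormal (μ = 3.321, σ = 0.211, solved
  so the implied category prevalences sit near the reported adult
  distribution: ≈2.8 % underweight, ≈29 % normal, ≈33 % overweight,
  ≈35 % obese); height is normal (1.68 ± 0.095 m, truncated to
  1.30–2.20); weight is derived as BMI × height².
- **Design.** Persons are assigned round-robin to 15 strata × 2 PSUs;
  weights are lognormal with CV 0.5, normalized to mean 1 so weighted
  and unweighted n are comparable.

Because only means/SEs of the source tables are published, every
distributional family here is a modelling assumption. Passing tests on
this population therefore demonstrate the *pipeline's* correctness and
the qualitative structure of the findings (score gradients across
bins, direction and order of prevalence shifts), not numeric agreement
with the original survey estimates, which would require the actual
survey files.

## Numerical choices and edge cases

- BMI rounding: decimal half-away-from-zero on the repr of the float
  ratio; category comparison on integer tenths, so 18.5 and 25.0 land
  in their inclusive categories exactly.
- Persons with observed HBI = 0 have an undefined percent change; they
  are flagged (`None`) and excluded from percent-change aggregation.
- A paired test with identically zero differences returns statistic 0,
  p = 1 (trivially non-significant); zero variance with a nonzero mean
  is flagged as undefined rather than reported as infinite.
- Ingest excludes (and counts) persons with no beverage rows *and*
  missing total energy — the missing-dietary-data rule; a missing
  total with beverage rows present is an error, not an exclusion.
- Volumes convert at 29.5735 mL/fl oz everywhere except the 8-oz
  substitution serving, which uses the 237 mL policy constant.

## Problem sizes

Default test and pipeline runs use populations of 200–1,000 persons;
calibration-style checks (bin-proportion recovery, HBI bin gradient)
use 20,000 persons, and the estimator type-I-error check uses 500
replicates of 600 persons — sizes at which Monte-Carlo error is small
relative to the 3-SE test tolerances while the full suite stays fast.

## Known limitations

- No within-person correlation between beverage groups; no multi-day
  recalls or usual-intake modelling.
- The shipped food-code/label mapping is a miniature fixture, not a
  versioned food-database linkage.
- Weight deltas are applied uniformly within eligible bins, with no
  dose-response in SSB servings and no energy-balance (kcal→kg)
  modelling — deltas are consumed as literature parameters.
- The default HBI cut-point table is a package-authored transcription
  of the index's component standards; analyses tied to a specific HBI
  version should supply their own YAML.
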