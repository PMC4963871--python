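# hbi-swap

Counterfactual beverage-substitution modelling for adult dietary-recall
data: what happens to beverage-intake quality and to weight
classification if one daily 8-oz serving of sugar-sweetened beverage
(SSB) is replaced with water?

The package is aimed at nutrition epidemiologists working with
single-day 24-h recalls from complex surveys. It provides:

- **Beverage classification** into the eight Healthy Beverage Index
  (HBI) groups (water, unsweetened coffee/tea, low-fat milk, diet
  beverages, 100 % juice, alcohol, whole milk, SSB), table-driven and
  loud on unmapped items;
- **HBI scoring** — the ten-component 0–100 adherence index
  (config-driven standards, full-credit band with linear decay to a
  zero point);
- **The substitution counterfactual** — per eligible person, SSB −8 oz,
  water +8 oz (one serving ≡ 237 mL), beverage *and* total energy
  −100 kcal, HBI rescored on the counterfactual intake;
- **Weight scenarios** — literature weight deltas (−0.40 to −1.99 kg)
  applied to substituted persons, BMI recomputed (kg/m², rounded to one
  decimal) and categories reassigned (underweight <18.5, normal
  18.5–24.9, overweight 25.0–29.9, obese ≥30.0);
- **Survey-weighted estimation** — Hajek means and prevalences with
  Taylor-linearized SEs over a stratified PSU design, weighted paired
  t-tests with Bonferroni correction;
- **A synthetic population generator** calibrated to published adult
  beverage-intake tables (zero-inflated gamma SSB by age group,
  stratified two-PSU design), so the entire pipeline is testable with
  no external data.

Per person, SSB servings `s = oz/8` fall into bins {0}, (0,1], (1,2],
(2,∞); the HBI total is `Σ_c points_c` with `Σ_c max_c = 100`; the
substitution maps `(ssb, water, E_bev, E_tot) → (ssb−8, water+8,
E_bev−100, E_tot−100)` with floors; population estimates are
`x̄_w = Σ w_i x_i / Σ w_i` with design-based variance
`Σ_h n_h/(n_h−1) Σ_j (z_hj − z̄_h)²`. Details: [docs/methods.md](docs/methods.md).

## Worked example

```python
import numpy as np
import hbi_swap as hs

pop = hs.generate_population(hs.default_config(n_persons=2000, seed=42))
summaries = [hs.summarize_person(p) for p in pop.persons]
pairs = hs.substitute_all(summaries)          # one 8-oz SSB serving -> water

w  = np.array([p.svy_weight for p in pop.persons])
st = np.array([p.stratum for p in pop.persons])
ps = np.array([p.psu for p in pop.persons])
bins    = np.array([s.bin.value for s in summaries])
hbi_obs = np.array([pr.observed_hbi.total for pr in pairs])
hbi_pred = np.array([pr.predicted_hbi.total for pr in pairs])

for b in ["NON_CONSUMER", "ONE", "ONE_TO_TWO", "GT_TWO"]:
    est = hs.survey_mean(hbi_obs, w, st, ps, domain_mask=(bins == b))
    print(f"{b:13s} n={(bins == b).sum():4d}  HBI {est.estimate:.1f} ({est.se:.1f})")

mask = bins == "ONE_TO_TWO"
test = hs.paired_t(hbi_pred, hbi_obs, w, st, ps, m_comparisons=3, domain_mask=mask)
print(f"paired t (1-2 servings, predicted vs observed): t={test.statistic:.1f}, "
      f"p_bonferroni={test.p_bonferroni:.2g}")
```

prints

```
NON_CONSUMER  n=1108  HBI 79.9 (0.2)
ONE           n= 129  HBI 75.6 (1.3)
ONE_TO_TWO    n= 215  HBI 61.7 (0.8)
GT_TWO        n= 548  HBI 50.9 (0.5)
paired t (1-2 servings, predicted vs observed): t=76.4, p_bonferroni=2.2e-20
```

Mean beverage-quality scores fall monotonically with each additional
SSB serving bin — non-consumers sit near 80 of 100, heavy consumers
near 51 — and the water substitution raises scores significantly in
every consumer bin (here the 1–2-servings cell, tested against its
own observed scores with a design-based paired t on 3 comparisons).

## Command line

```sh
hbi-swap simulate --out data/ --n 2000 --seed 42
hbi-swap summarize --persons data/persons.tsv --beverages data/beverages.tsv --out summaries.tsv
hbi-swap score     --persons data/persons.tsv --beverages data/beverages.tsv --out scores.tsv
hbi-swap run       --out report/ --n 2000 --seed 42     # full pipeline
```

`run` writes per-person intermediates (`summaries.tsv`, `pairs.tsv`,
`reclassified_*.tsv`) plus report tables: intake by age group, the SSB
serving-bin distribution, substitution impact on beverage energy, HBI
by age × bin, percent change in HBI, and BMI-category prevalences
under each weight scenario. Every printed cell is recomputable from
the persisted intermediates.

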