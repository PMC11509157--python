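# bordertrap

Spatial analysis of pheromone border-trapping trials in orchards.

When aggregation-pheromone "mini-sailboat" traps are lined up along one
border of an apple orchard to mass-trap the brown marmorated stink bug
(*Halyomorpha halys*), the interesting outcome is not only how much fruit
is damaged but *where*. `bordertrap` is the analysis pipeline for such
trials, for entomologists and crop-protection researchers: it scores fruit
damage at assessment points, joins it with trap catches and border
geometry, fits distance-decay count models, and summarizes the resulting
curves into the two headline distances of a border-trapping trial.

## The statistics at the core

Per assessment point with class counts N₁..N₆ (six injury classes with
damage coefficients V = 0, 1, 2.5, 5, 8.5, 15.5):

- damage incidence (%) = 100 · (N − N₁)/N,
- damage severity = Σᵢ≥₂ NᵢVᵢ / Σᵢ≥₂ Nᵢ (mean coefficient per injured
  fruit),
- catch index = Σₓ Hₓ/d²ₓᵢ from season trap totals Hₓ at distances dₓᵢ
  (a √Σ(Hₓ/dₓᵢ)² variant is selectable).

Injured-fruit counts are fit by a log-link negative binomial regression
with log(assessed fruit) offset, starting from catch index, nearest-trap
distance, variety, management, trap presence and its interactions with
management and border distance, reduced by backward AIC elimination.
The fitted curves (per stratum: trap vs control plots) are integrated to
the **d50** — the border distance within which half of the predicted
damage mass lies — and subtracted (control − trap) to locate the
**crossover**, the distance of equal predicted damage beyond which the
trap stratum is better off. Catch series get their own negative binomial
model (sex × trap part × date) with Wald contrasts, one-way ANOVAs,
likelihood-ratio analysis of deviance (type II/III) and Pearson-χ²
goodness of fit alongside.

Because trials of this kind rarely publish raw per-point data, the package
includes a seeded synthetic-trial generator (`OrchardScenario`) whose
defaults emulate a realistic four-plot trial; every stage is testable
end-to-end from it. See `docs/methods.md` for models, assumptions and
parameter rationale.

## Worked example

```sh
bordertrap analyze --seed 1 --out results/
bordertrap report --out results/
```

which prints, for the default synthetic trial:

```
Traps: 8  total catch 4457
Mean catch per trap: 557.12 ± 58.13
Sex ratio (M:F): 0.89:1  males on sail 70.0%
Incidence d50 — control: 44.9 m, trap: 20.1 m
Incidence crossover: 51.32 m
Severity d50 — control: 39.4 m, trap: 39.4 m
Severity crossover: undefined (no sign change)
```

Reading: the eight traps caught ≈557 adults each over the season, with
slightly more females than males and ~70% of males retained on the sticky
sail. In the trap plots half of the predicted damage mass lies within
20.1 m of the border versus 44.9 m in control plots — the traps pulled the
damage toward the border — and beyond the 51.32 m crossover the trap plots
show *less* predicted damage than the controls. Severity carries no
distance signal in this trial (the generator gives both strata the same
injury-count law), so its curves coincide and the crossover is reported
undefined rather than invented.

The same run from Python:

```python
from bordertrap import run_pipeline
report = run_pipeline({}, out_dir="results", seed=1)
report["incidence_curves"]
# {'d50_control_m': 44.93, 'd50_trap_m': 20.08, 'crossover_m': 51.32}
```

`results/` then holds `summary.json`, per-point metrics, per-stratum curve
CSVs (`distance, prediction, se, cumulated_fraction`) and the catches
table. `bordertrap synth` writes a synthetic trial out as the CSV/GeoJSON
input files that `analyze` also accepts for real field data (flat TOML
config; see `bordertrap --help`).

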