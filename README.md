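# cohortlife

Female-based cohort life-table analysis for daily-census rearing studies.
From individual rearing records (stage durations, fate, sex, adult
longevity, daily egg counts) the package builds age-specific survival and
fecundity schedules, computes the four demographic parameters — net
reproductive rate (R0), mean generation time (T), intrinsic rate of
increase (r_m, via a bracketed Euler–Lotka solve) and finite rate of
increase (lambda) — with leave-one-out jackknife standard errors and
Tukey studentized-range comparisons across treatments, plus stage-level
descriptive statistics (Kruskal–Wallis with DSCF post hoc, one-way ANOVA
with Tukey–Kramer post hoc). A fully specified synthetic-cohort generator
with exact analytic expectations makes every stage testable without any
external data.

## Layout

| module | purpose |
| --- | --- |
| `cohortlife.records` | individual/cohort data model, CSV I/O, validation, lost-record exclusion |
| `cohortlife.schedules` | census quantities (SURV, SR, NF) and l_x / m_x schedules |
| `cohortlife.demography` | R0, T, r_m (Euler–Lotka root), lambda |
| `cohortlife.jackknife` | leave-one-out pseudo-values, SEs, Tukey comparison of treatments |
| `cohortlife.stage_stats` | stage/reproductive summaries, KW+DSCF, ANOVA+Tukey, headline ratios |
| `cohortlife.simulate` | synthetic cohorts, analytic-expectation oracle, diet presets |
| `cohortlife.report` / `cohortlife.cli` | orchestration, tables, figures, JSON bundle, CLI |

## CLI

```sh
# three calibrated diet presets -> individuals.csv + fecundity.csv
cohortlife simulate --seed 1 --out-dir data/

# deterministic analysis: schedules, parameter table, summaries, figures, JSON
cohortlife analyze --individuals data/individuals.csv --fecundity data/fecundity.csv \
    --out-dir results/ --age-origin egg --jackknife-unit individual --alpha 0.05

# render the parameter table from an existing bundle
cohortlife report --bundle results/results.json

# both steps in one go (custom cohorts via --config cohorts.toml)
cohortlife all --seed 1 --out-dir results/
```

Input formats: an individuals CSV
(`id,treatment,fate,sex,dur_egg,dur_n1,...,dur_n5,adult_longevity`, empty
field = absent) and a long-format fecundity CSV (`id,age_day,eggs` with
`age_day` the 1-based day of adult life). Simulation configs are TOML or
YAML; see `cohortlife.simulate.config_from_dict` for the schema.

## Conventions worth knowing

- Ages are integer days; an individual dying on day `d` is alive at ages
  `< d` (death-day exclusive). Default age origin is egg deposition;
  `adult_emergence` is available everywhere.
- `l_x = SURV * NSF_x / NF`; `m_x` uses the mean eggs per *living* female
  times the cohort sex ratio, which makes
  `sum(l_x m_x) = SURV * SR * total_eggs / NF` hold to machine precision.
- Only `fate=lost` records are discarded before analysis; immature deaths
  stay in the survival denominator.
- The jackknife deletes whole individuals by default (so survival and sex
  ratio vary across replicates); `--jackknife-unit female` restricts
  deletion to adult females.
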