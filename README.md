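# damsleep

Sleep, activity and lifespan analysis for *Drosophila* activity-monitor
(DAM) ageing experiments.

Trikinetics-style monitors count infrared-beam breaks per fly tube once
a minute; ageing studies run cohorts of different ages, sexes and
background strains through these monitors and through parallel lifespan
assays. `damsleep` provides the full analysis chain for such data, for
researchers in behavioural chronobiology and the biology of ageing:

* **`dam_io`** — read/write DAM-dialect monitor files (per-beam and
  per-tube), sum beams per tube, and extract analysis windows aligned
  to the light schedule (e.g. 48 h starting at the first lights-on
  after 24 h of acclimation).
* **`behaviour_metrics`** — per-fly, per-day measures: day/night/total
  activity counts; sleep minutes (sleep = ≥ 5 consecutive minutes of
  zero counts); sleep-bout number and mean length; 30-min binned
  population traces; morning and evening anticipation indices
  (AI = activity in the last 3 h before a light transition ÷ activity
  in the last 6 h, so a flat profile gives 0.5); and a viability filter
  that excludes flies with fewer than 3 counts in the final 180 min.
* **`survival`** — Kaplan–Meier curves and medians, percent decreases
  in median lifespan, k-group log-rank tests, and Cox proportional
  hazards (Newton–Raphson, Efron ties) with a likelihood-ratio test of
  the sex×strain interaction.
* **`group_stats`** — two-way ANOVA (Type II sums of squares),
  Dunnett's many-to-one comparisons against the youngest cohort
  (multivariate-t family-wise p by seeded Monte Carlo), Bonferroni.
* **`synthetic_data`** — a seeded generator of DAM-format cohorts with
  known ground truth: alternating-renewal sleep/wake runs, crepuscular
  Poisson activity with anticipation ramps and startle responses,
  dead-fly and empty-tube artefacts, and Gompertz lifespans with
  censoring.
* **`pipeline` / `cli`** — a manifest-driven end-to-end flow
  (parse → metrics → compiled per-measure tables → statistics) with an
  exclusion log and deterministic, byte-identical outputs for a fixed
  seed.

The scientific details — scoring rules, model assumptions, generator
design and validation experiments — are in [`docs/methods.md`](docs/methods.md).

## Worked example

Simulate a two-cohort experiment, write DAM files plus a manifest, and
run the whole pipeline:

```sh
damsleep simulate --seed 7 --n-flies 8 --groups CS:female:2,CS:female:6 demo
damsleep run-all demo/manifest.yaml
```

which prints the run summary

```json
{
  "manifest_hash": "c9fdaf71731e02d8",
  "n_flies_excluded": 0,
  "n_flies_kept": 16,
  "n_monitors": 2,
  "seed": 7,
  "version": "0.1.0",
  "window_hours": 48.0
}
```

and writes one tidy CSV per measure plus `averaged.csv`, whose first
row for this seed is

```
fly_id,monitor,tube,age_weeks,sex,strain,activity_total,...,sleep_night,...,morning_ai,evening_ai
Monitor001_t01,Monitor001,1,2,female,CS,2594.5,...,468.5,...,0.6998,0.6020
```

— this fly produced 2594.5 activity counts per day (day-averaged over
the 2 recording days), slept 468.5 min per night, and shows a morning
anticipation index of 0.70 (well above the 0.5 of a flat profile:
its activity rises towards dawn). `anova.csv` and `dunnett.csv` hold
the age×sex ANOVA per strain and the per-(strain, sex) Dunnett
comparisons of each age against the 2-week control, with significance
stars at the 0.05/0.01/0.001/0.0001 thresholds.

For lifespan tables (`id,time_days,event,strain,sex` CSV):

```sh
damsleep survival records.csv out/
```

writes KM medians per group, within-strain male-vs-female percent
median decreases, all pairwise log-rank tests within strain and within
sex, and the Cox sex×strain interaction p-value.

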