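# Methods

## Scope

`damsleep` implements the standard analysis chain for *Drosophila*
activity-monitor (DAM) ageing experiments: parsing per-beam monitor
files, summing beams per tube, scoring sleep and anticipation per fly,
filtering flies that died during recording, compiling tidy per-measure
tables, and the statistics used on such data — Kaplan–Meier/log-rank/
Cox for lifespan and two-way ANOVA with Dunnett or Bonferroni
comparisons for behavioural measures. A seeded synthetic generator
stands in for raw recordings so every stage can be tested against
known ground truth.

## Behavioural scoring

**Sleep.** The standard fly proxy: a sleep bout is a maximal run of
consecutive minutes with zero activity counts of length ≥ 5 min
(`sleep_threshold_minutes`, configurable). Runs truncated by the
analysis-window edges count if their within-window length reaches the
threshold; there is no look-ahead outside the window.

**Phase attribution.** Day is the half-open interval
[lights-on, lights-off); the lights-on minute belongs to day. A bout
spanning a phase boundary is split at the boundary by default: each
phase receives its overlapped minutes and one bout tally, so
day + night = total holds exactly for sleep minutes, and phase bout
length = phase minutes / phase bouts. The alternative of assigning a
whole bout to its onset phase is supported
(`bout_boundary_rule="onset"`) because published scripts differ on
this point; the split rule was made the default because it is the only
rule under which all three phase-resolved measures decompose
additively.

**Anticipation index.** AI = activity summed over the `numerator_hours`
(default 3 h) immediately preceding a light transition divided by
activity over the `denominator_hours` (default 6 h) preceding it.
Morning AI uses lights-on (window in the late night), evening AI uses
lights-off (window in the late day). A flat activity profile gives
AI = numerator/denominator = 0.5 exactly; values lie in [0, 1]. A zero
denominator yields a missing value, never zero — substituting zero
would bias group means downward. The window lengths are configurable
because conventions vary between labs; 3 h/6 h is the common published
choice.

**Viability.** A fly is scored dead when its final 180 min of analysed
recording hold fewer than 3 activity counts; dead flies (and empty
tubes, which fail the same rule) are excluded from every metric table
and listed in the exclusion log. The boundary is inclusive: exactly 3
counts means alive.

**Aggregation.** All measures are computed per recording day (windows
are whole 24-h cycles starting at lights-on) and then averaged within
fly; days with undefined values are omitted from the mean with the
count retained. Population traces use fixed Zeitgeber-time bins
(default 30 min, 48 bins/day); per-fly day-averaging precedes the
cross-fly mean ± SEM. With a single fly the SEM is reported as 0 with
a warning.

## Monitor-file handling

The reader accepts tab-separated rows
`index, date (DD Mon YY), time, status, 6 metadata columns, light
flag, count columns`, with the count-column geometry (tubes × beams
per tube, column order) fully described by a `BeamLayout`; both the
per-beam dialect (e.g. 8 tubes × 15 beams = 120 columns) and the
already-summed per-tube dialect are read by the same code, so
first-stage output files round-trip. Malformed rows raise an error
naming the line. Rows with a status code outside the valid set
(default {1}) are kept but flagged; a fly whose analysis window
contains flagged minutes is excluded, not silently repaired. Missing
minutes up to a configurable limit (default 5) are filled with flagged
zero-count rows so run-length sleep scoring stays well defined; longer
gaps abort with an alignment error, because silently bridging them
would fabricate sleep.

## Survival statistics

Kaplan–Meier is the plain product-limit estimator; the median is the
first event time with S(t) ≤ 0.5 (the convention of the common
survival packages), undefined (NaN) when the curve never reaches 0.5.
Percent median decrease is 100 × (reference − comparison)/reference,
sign-preserving. The k-group log-rank test accumulates observed minus
expected deaths with the hypergeometric covariance at every pooled
death time and uses a pseudo-inverse for degenerate risk sets. The Cox
model maximises the partial likelihood by Newton–Raphson with
step-halving and the Efron tie correction (the default of the R
`survival` package, kept for comparability with published analyses);
Efron and Breslow coincide on tie-free data, and at β = 0 the score
statistic for a single binary covariate reproduces the two-group
log-rank statistic, which the tests exploit as a cross-module check.
The sex-by-strain interaction is tested by the likelihood ratio of the
full model (sex + strain + sex×strain, treatment coding) against the
main-effects model. Vial-level transfer tallies (deaths/censors per
transfer day) are expanded to individual records at the transfer day,
matching the granularity of thrice-weekly scoring.

## Group statistics

The two-way fixed-effects ANOVA uses Type II sums of squares, computed
by explicit model comparison (residual sums of squares of nested
least-squares fits). Type II is the standard marginal-effects choice
for the unbalanced cell sizes these cohorts produce (17–32 flies per
condition after exclusions) and reduces to the classical decomposition
on balanced data, which the tests verify definitionally.

Dunnett's many-to-one comparisons use pooled-variance t statistics
against the control level (the youngest age group). Family-wise
adjusted p-values are P(max_j |T_j| ≥ |t_obs|) under the joint null,
where the T_j follow the multivariate t distribution with correlation
λ_i λ_j, λ_j = √(n_j/(n_j + n_0)), induced by the shared control mean.
The probability is evaluated by seed-controlled Monte Carlo (default
10⁵ draws; Monte-Carlo standard error reported) rather than quadrature
so arbitrary unbalanced designs are handled uniformly; the balanced
k = 2 case is verified against direct bivariate-t integration, and
general cases against an independent implementation. One family is one
(strain, sex, measure) panel. Bonferroni adjustment is min(1, m·p).

## Synthetic cohorts

The generator emulates what these experiments actually record, with
every parameter in `SimConfig`:

* **Sleep–wake structure**: a discrete-time alternating-renewal
  process matched to the 1-min sampling. Wake runs are geometric with
  per-phase means (defaults 40 min by day, 15 min by night). Sleep
  runs are geometric shifted to a minimum of 5 min with the configured
  mean preserved (defaults 10 min by day, 30 min by night —
  consolidated night sleep). The shift exists because inactivity
  shorter than the scoring threshold is not sleep by definition: an
  unshifted geometric run conditioned on reaching the threshold has
  mean `threshold − 1` above its nominal mean, which would bias every
  recovered bout statistic by ~13% before any measurement error.
* **Activity**: each wake minute emits a Poisson count with intensity
  = baseline (2 counts/min) + linear anticipation ramps rising over
  the 6 h before each transition (peak amplitude 3 counts/min) + a
  post-transition startle (amplitude 4, 30-min decay). Sleep minutes
  emit zero; wake minutes may also emit zero by Poisson chance, as
  real monitors do.
* **Anticipation** acts through two coupled channels: the intensity
  ramp, and earlier pre-transition waking — sleep runs starting inside
  a ramp window have their mean shortened by up to
  `wake_ramp_coupling` (default 0.5) in proportion to the group's
  ramp-slope multiplier and the position in the window. The coupling
  reflects that behavioural anticipation in flies is largely a
  wake-timing phenomenon; a pure intensity ramp cannot express a
  detectable slope effect because the AI ratio saturates in the ramp
  amplitude (halving a linear ramp moves the expected AI by at most
  ≈ 0.04 for any amplitude/baseline choice). With a flat profile both
  channels vanish and the expected AI is exactly 0.5.
* **Groups** carry multipliers for activity level, sleep-run length,
  ramp slope and lifespan hazard, so age/sex/strain contrasts of known
  size can be injected.
* **Cohort artefacts**: configurable fractions of dead flies (counts
  cease at a drawn death minute) and empty tubes (all-zero traces).
  Per-tube counts are distributed over beams multinomially when
  per-beam files are written.
* **Lifespans**: Gompertz hazard a·e^{bt} per group (defaults
  a = 1.7×10⁻⁴/day, b = 0.10/day — median ≈ 60 days, a realistic
  mated-female lifespan at 25 °C), sampled by inverse transform, with
  b = 0 giving the exponential limit and a closed-form median for
  tests. Censoring is independent per subject (default 2%), applied at
  a uniform fraction of the drawn lifetime.
* **Determinism**: every fly draws from a named `SeedSequence` stream
  keyed by (strain, sex, age, fly index) with strings hashed by CRC-32
  (Python's `hash` is process-salted), so adding flies or groups never
  perturbs existing traces and identical configs give byte-identical
  files.

What the generator does **not** emulate: positional dynamics along the
tube (beam counts are exchangeable within a tube), circadian period
drift or free-running rhythms, light-sensor noise, temperature
effects, and inter-individual heterogeneity beyond the run-length and
Poisson randomness. Passing recovery tests therefore show that the
pipeline measures what this class of renewal-process data contains;
they do not validate the sleep proxy itself against video-tracked
behaviour.

## Validation experiments and problem sizes

The calibration module re-runs the package's statistics on simulated
null or known-truth data: log-rank and ANOVA type-I error (2,000
replicates each, two groups of 30 / six cells of 10), Dunnett
family-wise error with k = 3 nulls against unadjusted testing (2,000
replicates, 2×10⁴ Monte-Carlo draws per replicate), night bout-length
recovery and flat-profile AI at the study scale (32 flies × 2
recording days), AI monotonicity across three ramp slopes, Cox
recovery of a true log-hazard-ratio of log 2 at n = 500, power for a
halved anticipation ramp (100 replicates of a 2-age × 2-sex, n = 32
cohort), and uniformity of the interaction LR p-value under a null
6-group cohort (500 replicates of 60 subjects per group; smaller
groups show the classical finite-sample LR inflation, which is a
property of partial-likelihood asymptotics, not of this
implementation — verified against an independent fitter to 10⁻⁶).
Bout-length recovery is asserted under a flat intensity profile
because the wake-anticipation coupling intentionally shortens pre-dawn
sleep runs under the full profile; under the full profile the measured
bout length is instead compared with the generator's realised
ground-truth run mean.

## Numerical choices and degenerate inputs

* Missing values (undefined AI, bout length with zero bouts) propagate
  as NaN and are omitted from day averages and group statistics.
* The Cox log-likelihood is computed with a shift-invariant overflow
  guard; step-halving tolerances are relative to |log L|; a singular
  information matrix (e.g. complete separation) raises a fit error
  rather than returning garbage.
* An all-censored Kaplan–Meier input yields a flat curve at 1 with an
  undefined median rather than an error.
* Zero residual variance leaves ANOVA F statistics NaN (flagged in the
  table); empty design cells are an error naming the cell.
* Ties in the log-rank risk sets use the d(n−d)/(n−1) variance with
  n = 1 terms skipped.

## Limitations

The pipeline scores sleep from beam counts, inheriting the known
overestimation of sleep relative to video tracking; multi-beam
monitors mitigate but do not remove this. The Dunnett Monte Carlo
gives adjusted p-values with ~0.001 standard error at the default
draw count, which is adequate for the 0.05/0.01/0.001 star thresholds
but not for reporting extreme p-values precisely. The survival module
fits proportional-hazards models only; crossing hazards (which
'steeper' versus 'shallower' strain curves can produce) are summarised
but not modelled.
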