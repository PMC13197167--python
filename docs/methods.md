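# Methods

This note documents the models, defaults and numerical choices of
`beechpheno`: the generative model behind the synthetic populations, the
event-extraction and cleaning rules, the statistical layer, and the known
estimator-level caveats.  Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Generative model

Each simulated tree belongs to one treatment group of one of the two
experiments (ten groups of 26–27 trees, n = 267, for the leafing × summer
cooling experiment; 36 ambient controls plus eight chamber groups of 18,
n = 180, for the pre-/post-solstice diel experiment).  Its true event dates
are linear:

    true_event = base + slope · (leaf_out − reference)
               + treatment_shift + bud_type_offset + ε,   ε ~ N(0, sd_individual)

with ε drawn independently per event (per bud for bud set; once per tree for
senescence).  The advancing effect of earlier development (ESD) is encoded by
the positive `slope`; cooling treatments act as direct day-shifts (LST);
there is no thermal-time or dose–response submodel, since the underlying
experiments provide effect sizes, not a temperature–response curve.

### Parameters, units, defaults

| parameter | default | why |
|---|---|---|
| `base_budset_doy` | 232 (exp 1), 272 (exp 2) | mid of each bud measurement window |
| `base_senescence_doy` | 300 | late October, mid of the SPAD window |
| `esd_slope` | 0.24 d/d | the experiments' estimated bud-set sensitivity |
| `senescence_slope` | 0.22 d/d | estimated senescence sensitivity |
| `treatment_shifts` | per-label days | the estimated per-group effects (delays positive); unreported extreme-cooling values set slightly below the moderate ones |
| `senescence_shifts` | per-label days | reported values where printed; otherwise 0.65 × the bud shift (senescence responses were weaker), with the two sign-flipped groups reproduced |
| `bud_type_offset_exp1/2` | −1.1 / −9.4 d | lateral minus apical, as estimated |
| `leafout_doy_early/late` | N(118, 4) / N(137.2, 4) | separation 19.2 d so that slope × separation reproduces the reported leafing-group contrasts (0.24·19.2 ≈ 4.6 d bud set, 0.22·19.2 ≈ 4.2 d senescence) |
| `sd_individual` | 7.0 d | not reported anywhere; chosen so the simulated populations reproduce the reported uncertainty scale (±2 SE ≈ 2.6 d for 27-vs-27 contrasts, ≈ 1.3 d for the whole-population leafing contrast) and an ICC ≈ 0.26 jointly — an assumption, not a measured value |
| `sd_measurement_bud` | 0.2 mm | calliper placement/re-measurement error; the instrument resolution itself is 0.01 mm |
| `sd_measurement_spad` | 2.0 SPAD | typical leaf-to-leaf meter repeatability |
| `outlier_rate` | 0.01 per tree × date | occasional bad measurement sessions |
| `growth_window_days` | 60 | 5→95% span of the logistic bud growth |
| `chl_peak_mean/sd` | 85 / 4 µg/g | healthy mid-summer beech foliage, inside the calibration's attainable range (≤ 92.35) |
| `chl_floor` | 5 µg/g | residual chlorophyll after decline; keeps SPAD inversion defined |
| `senescence_scale_days` | 6 | sigmoid time scale, a 10–90% decline over ≈ 26 days |

Measurement schedules mirror the experiments: weekly bud measurements
(days 185–304 for experiment 1, 237–307 for experiment 2) and a SPAD schedule
that is monthly in summer, fortnightly in September and weekly from October to
mid-December, including day 341 (7 December), which carries an injected
upward artifact so the date-exclusion cleaning rule has something real to do.

### Measurement curves

Bud growth is logistic in time.  The 90%-of-own-maximum rule only constrains
the curve near its plateau, so any monotone saturating family would serve;
the logistic is used because its 90%-crossing has a closed form.  The
midpoint is solved so the *continuous* crossing of 0.9 × (value at the last
scheduled day) equals the true date, then two fixed-point shifts align the
*linearly interpolated* crossing with the truth (residual error < 0.1 d at
weekly sampling; the extraction tolerance used in tests is 0.5 d).
Chlorophyll follows a plateau-then-sigmoid decline with the analogous
alignment (< 0.1 d; tolerance 1 d).  Chlorophyll maps back to SPAD on the
increasing branch of the quadratic calibration (the root below the vertex at
SPAD ≈ 202.6); nine leaves per tree and date read the curve with independent
Gaussian noise, clipped to the meter's [0, 100].

Injected outliers displace whole tree × date sessions (all nine leaves
together, as a mis-read or damaged crown would) to a target 5–7 IQR beyond
their treatment × date group's quartiles *in chlorophyll space* — the space
the cleaning operates in — and carry ground-truth labels.  Sessions where no
such target fits the attainable chlorophyll range (mid-decline dates, where
the group spread rivals the whole range) are left untouched, because a
displacement clipped at the meter bounds would not be detectable even in
principle.

### What the generator does and does not emulate

It emulates: both experimental designs and group sizes, arrested spring
development (two leaf-out distributions), saturating bud growth, sigmoidal
chlorophyll decline, realistic measurement schedules, leaf-level replication,
measurement noise, session-level outliers, and the 7-December artifact.

It does not emulate: temperature time series or any dose–response mechanism
(effects are injected directly as day-shifts), block or microsite effects
(the `block` column is decorative), crown-position gradients in SPAD,
within-season remeasurement correlation, non-Gaussian individual variation,
or mortality/missingness other than QC removal.  Passing tests therefore
demonstrate that the *estimators* recover known structure through the full
measurement-extraction-cleaning chain — not that the biological model of the
real experiments is correct.

## Event extraction

- **Bud set** = first upward interpolated crossing of 0.9 × max observed
  length.  Equality at a knot returns the knot.  A series starting at or
  above threshold (including the all-equal degenerate case, where max = min
  leaves the crossing undefined) is left-censored at its first day.
- **Senescence** = last downward interpolated crossing of 0.5 × peak
  chlorophyll, so transient dips do not trigger the event; a trajectory never
  falling below threshold is right-censored with no date.  Censored events
  carry flags, never fabricated dates, and are excluded from model fits.
- Trajectories are the raw interpolated series: no smoothing, no
  extrapolation, global maximum over all observations.  Day-of-year is
  real-valued and 1-based; all events fall in one calendar year.
- **Growth metrics** follow the study's literal definitions: min length = the
  first measured length; max length = the first *measured* value strictly
  exceeding 90% of the final (last) measured length — which coincides with
  the maximum for monotone series but is kept distinct from the bud-set
  threshold; absolute = max − min (mm), relative = (1 − min/max) × 100.
- **Leaf aggregation** defaults to convert-each-leaf-then-average, because
  the SPAD→chlorophyll calibration is a leaf-level relation.  The
  average-then-convert order is exposed for sensitivity analysis; the two
  differ by the Jensen gap of the concave quadratic (≈ 0.0029 × the SPAD
  variance among leaves).

## Cleaning

Order of operations: drop excluded dates (default: day 341) → aggregate
leaves to tree-level chlorophyll → flag values beyond Q1 − 1.5 IQR / Q3 +
1.5 IQR within each treatment × measurement-date group → drop trees with more
than one flagged value.  Quartiles use linear interpolation between order
statistics (numpy default, R type 7); the convention is configurable, as is a
leaf-level cleaning mode (the study's phrase "individual chlorophyll
measurements" is read as per-individual-tree by default).  Groups smaller
than four values pass unfiltered.  Cleaning only removes rows; retained
values are never altered, and no imputation is performed.

Two caveats, both measured by the test suite:

1. **Idempotence is partial.**  The single-pass filter is the study's
   procedure and the default.  An iterated variant (`iterate=True`) recomputes
   fences on survivors until stable and is idempotent at the value level, but
   the tree-dropping step can never be made idempotent cheaply: dropping a
   tree removes its inlier rows too, which shifts the group quartiles seen by
   any second pass.  Iterating the whole chain to a fixed point removes
   25–38% of trees under default conditions — clearly the wrong trade — so
   the chain applies tree-dropping once.
2. **The fences eat biological tails.**  During the chlorophyll decline,
   within-group cross-sections are heavy-tailed (trees differ by ~7 d in
   timing on a 6-day decline scale), so the 1.5 × IQR rule removes ~3–4% of
   tree-date values and drops ~13% of trees at defaults — mostly genuinely
   early or late senescing individuals, not errors.  On labeled synthetic
   outliers the filter's recall is 1.00 with a false-positive rate ≈ 0.03.

## Statistical layer

- **Treatment contrasts**: OLS with treatment (categorical) + bud type for
  bud set; treatment alone for senescence.  Experiment 1 is fitted per
  leafing group so every coefficient is relative to the *matched* control;
  experiment 2 pools its three control groups into one 72-tree control when a
  one-way control ANOVA is non-significant (α = 0.05; pooling can be forced
  on or off).  Intervals are reported as estimate ± 2 SE — the study's
  convention, kept verbatim rather than 1.96 SE — with two-sided p-values
  from the coefficient t-test.  Tables carry both sign conventions (raw
  delay-positive coefficients and figure-style advance-positive).  No
  multiple-testing correction is applied anywhere.
- **Leaf-out sensitivity**: random-intercept model (REML) of event date on
  leaf-out date (+ bud type for bud set) with the full design treatment
  factor as the random effect.  Using the full factor matters: July cooling
  affects late-leafing trees ~3 days more than early-leafing ones, and with
  any coarser grouping that interaction leaks into the slope (≈ +0.05 d/d).
  With the full factor the slope is identified from within-group leaf-out
  variation and recovers the injected value (bias < 0.01 d/d, ~95% coverage
  of ±2 SE over 200 replicates).  A singular fit falls back to OLS with the
  treatment as fixed covariate, which is exact when the random variance is 0.
  Mixed-model p-values use the residual-df approximation.
- **Variance partitioning**: commonality analysis over {leaf-out, summer
  cooling treatment (timing × level, 5 levels), bud type}.  All seven
  non-empty subset models are fitted, their adjusted R² recorded, and the
  unique/pairwise/triple components obtained by solving the 7 × 7
  inclusion–exclusion system; residual = 1 − adjusted R² of the full model,
  so the components sum to one to machine precision.  Shared components may
  be legitimately negative (adjusted-R² arithmetic).  The solver is verified
  against closed-form commonality formulas and against `vegan::varpart`.
- **ICC**: one-way ANOVA method of moments over the design treatment groups;
  V_W = mean square within, V_T = max(0, (MS_between − MS_within)/n₀) with n₀
  the standard average group size, ICC = V_T/(V_T + V_W).
- **Coupling**: estimated marginal means per treatment (model predictions
  averaged over a balanced bud-type grid), all unordered within-experiment
  pairwise differences (45 + 21 = 66), directional agreement between the two
  responses, and the adjusted R² of senescence differences regressed on
  bud-set differences.

## Estimator-level caveats the pipeline itself exhibits

These are properties of the study's estimators under the simulated
conditions, reproduced (not patched) by the package:

- The noisy-maximum threshold biases extracted bud-set dates late by
  ~1–2 days (the threshold is 0.9 × the *maximum of noisy observations*),
  with a mild dependence on where the event falls in the window.  Contrasts
  cancel almost all of it (residual differential ≲ 0.2 d).
- The marginal late-vs-early leafing contrast is not a pure ESD measurement:
  its expectation includes the size-weighted difference in mean treatment
  shifts between leafing groups (+0.94 d at defaults, driven by the July
  interaction), so the pipeline reports ≈ 5.5 d where the injected ESD
  separation alone would give 4.6 d.
- The fitted senescence sensitivity attenuates (≈ 0.15 d/d for an injected
  0.22) because the IQR cleaning preferentially removes trees in the
  within-treatment timing tails — selection on the response shrinks a
  regression slope.  Bud set, which receives no cleaning, round-trips its
  slope.  Group-mean contrasts are unaffected (the truncation is roughly
  symmetric within groups).

## Problem sizes and tolerances used by the tests

Round-trip and oracle-equivalence checks use 100 + 100 random truths per
family (tolerances 0.5 d bud / 1.0 d chlorophyll for recovery; 0.01 d against
a 0.001-day grid search).  Parameter recovery runs 200 full
simulate–measure–extract–fit replicates of both experiments (bud set only,
~2 minutes) asserting mean bias < 0.5 d (slope < 0.03 d/d) and 2 SE coverage
in [0.89, 0.995].  The commonality solver is checked against brute-force
enumeration on 50 random datasets at 1e-10.  `scripts/acceptance.py` averages
20 replicate populations, leaving ~0.3 d Monte-Carlo error on reported
effects.

## Known limitations

- No dose–response model: treatments are day-shifts, so the package cannot
  extrapolate to unobserved temperature regimes.
- The compensatory point itself is not modelled (it is an inferred conceptual
  node, not a measurable event); the package quantifies its *signatures* —
  sign reversals of cooling effects across months and leafing groups.
- Senescence curves are never fitted parametrically; extraction is pure
  interpolation, as in the study.
- The Zenodo-deposit adapter is a documented stub: the deposit's internal
  layout is unknown until downloaded, after which it should reduce to column
  renaming/reshaping onto the package's CSV schemas.
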