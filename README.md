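# beechpheno

Event extraction and statistical inference for trans-solstice cooling
experiments on European beech (*Fagus sylvatica*) — from raw longitudinal
bud-length and SPAD chlorophyll-meter measurements to bud-set and
leaf-senescence dates, treatment effect sizes, leaf-out sensitivity slopes,
variance partitioning, intraclass correlation, and the coupling between the
two autumn markers.  A seeded synthetic-data generator reproduces the two
experimental designs with known ground truth, so every stage of the pipeline
is testable end-to-end without the deposited field data.

## The scientific problem

Autumn phenology of temperate trees is pulled in two directions: faster
early-season development advances bud set and senescence (the *early-season
developmental*, ESD, effect), while late-season warmth delays them (the
*late-season temperature*, LST, effect, switched on as days shorten after the
summer solstice).  The experiments this package models manipulated spring
leaf-out (early- vs late-leafing trees) and applied chamber cooling before
and after the solstice, by month and by time of day, to locate the
compensatory point where the two effects balance.

The package implements the measurement-to-inference chain such a study needs:

- **Bud set**: the date a bud first reaches 90% of its own maximum measured
  length, found by linear interpolation of the raw length series
  (no smoothing, no extrapolation; ties and censoring flagged).
- **Leaf senescence**: the date tree-level chlorophyll *last* falls below 50%
  of its observed peak.  SPAD readings are converted per leaf with the beech
  calibration Chl = −0.0029·SPAD² + 1.175·SPAD + 3.8506 (µg/g fresh weight)
  and averaged over the nine leaves measured per tree and date.
- **Cleaning**: measurements from known-bad dates are dropped; values beyond
  1.5 × IQR of their treatment × date group are removed; trees losing more
  than one value are excluded entirely.
- **Inference**: OLS contrasts of each treatment against its matched control
  (± 2 SE intervals), a random-intercept mixed model for the days-per-day
  sensitivity of autumn events to leaf-out date, one-way control ANOVAs,
  commonality-analysis variance partitioning over {leaf-out, cooling
  treatment, bud type}, the ANOVA-method ICC = V_T/(V_T + V_W) over
  treatments, and directional agreement of all 66 pairwise
  estimated-marginal-mean comparisons between bud set and senescence.

## Worked example

Run the numbered analysis scripts (or the equivalent `beechpheno run` CLI):

```sh
python analysis/01_simulate.py --seed 1    # 267 + 180 trees, known truth
python analysis/02_extract_events.py       # bud-set dates + growth metrics
python analysis/03_qc.py                   # chlorophyll cleaning + senescence
python analysis/04_inference.py            # all models
```

The final script prints, for simulation seed 1 (excerpt):

```
bud_set: late-leafing delay +5.90 +/- 1.32 d (2 SE, p=7.32e-18); leaf-out sensitivity 0.189 +/- 0.140 d/d [mixed_reml]
senescence: late-leafing delay +4.71 +/- 1.55 d (2 SE, p=5.17e-09); leaf-out sensitivity 0.217 +/- 0.128 d/d [mixed_reml]
experiment 2: lateral buds set +9.04 d earlier than apical (p=1.09e-26)
experiment-2 control ANOVA (bud set): F(2,141) = 0.061, p = 0.941
ICC over treatments: 0.291 (V_T=20.0, V_W=48.8 d^2)
bud-leaf coupling: 57/66 pairwise EMM comparisons agree in direction (86%), adjusted R^2 = 0.76
```

Reading this: trees whose leaf-out was experimentally delayed set buds ~6
days later; each day of leaf-out delay postpones bud set by ~0.2 days; the
three uncooled control groups of experiment 2 are statistically
indistinguishable (so they are pooled before contrast fitting); about a
quarter of the within-experiment variance in bud set lies between treatments
(ICC), the rest between individuals; and the direction of a treatment's
effect on bud set almost always matches its effect on senescence.
`results/inference/effects.csv` holds every treatment contrast with both
sign conventions (raw delay and figure-style advance), SEs, ± 2 SE intervals
and p-values.

The CLI exposes the same stages (`beechpheno simulate | extract | qc |
analyze | run`) over documented CSV schemas, so the deposited field data can
replace the simulated tables at any stage boundary.

## Layout

    src/beechpheno/    library: design, simulate, phenometrics, qc, inference,
                       io, pipeline, cli (+ a documented adapter stub for the
                       study's Zenodo deposit)
    analysis/          numbered narrative drivers writing under results/
    scripts/           acceptance.py (headline quantities as JSON)
    tests/             pytest suite (unit, property and acceptance tests)
    docs/methods.md    model, defaults, assumptions, limitations
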