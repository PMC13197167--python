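"""Statistical layer: treatment contrasts, leaf-out sensitivity, control
ANOVAs, commonality-analysis variance partitioning, ICC, and the coupling of
bud-set and senescence responses.

Conventions follow the study: ordinary least squares with treatment and bud
type as predictors for bud set (treatment alone for senescence); effect sizes
against the *matched* control (experiment 1: early treatments vs the
early-leafing control, late vs late); intervals reported as estimate +/- 2 SE;
a random-intercept mixed model (REML) for the sensitivity of event dates to
leaf-out date, with the summer cooling treatment as the random effect; no
multiple-testing correction.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf

from . import design

log = logging.getLogger(__name__)


@dataclass
class EffectEstimate:
    """A treatment contrast in days.  ``estimate`` is the raw coefficient
    (positive = later event, i.e. delay); ``advance`` carries the figure-style
    sign convention (positive = advancement).  Interval = estimate -/+ 2 SE."""

    contrast_label: str
    response: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n_treated: int
    n_control: int

    @property
    def advance(self) -> float:
        return -self.estimate


@dataclass
class SensitivitySlope:
    response: str
    slope: float  # days of event delay per day of leaf-out delay
    se: float
    p_value: float
    random_effect_variance: float
    method: str = "mixed_reml"  # or "ols_fallback"


@dataclass
class AnovaResult:
    F: float
    df1: int
    df2: int
    p_value: float


@dataclass
class VarPartResult:
    """Commonality decomposition of adjusted R^2 over three predictor sets.

    Unique + shared + residual sums to 1 by construction; shared components
    may be negative (adjusted-R^2 arithmetic).
    """

    unique_fractions: dict
    shared_fractions: dict
    residual_fraction: float
    total_adjusted_r2: float


@dataclass
class ICCResult:
    v_between: float
    v_within: float
    icc: float


@dataclass
class CouplingResult:
    n_pairs: int
    n_agree: int
    fraction_agree: float
    adjusted_r2: float
    pair_table: pd.DataFrame = field(repr=False, default=None)


def _usable(events: pd.DataFrame, response: str) -> pd.DataFrame:
    """Uncensored events of one response type."""
    out = events.loc[
        (events["event"] == response)
        & (events["censoring_flag"] == "none")
        & events["doy"].notna()
    ].copy()
    return out


def _merge_meta(events: pd.DataFrame, trees: pd.DataFrame) -> pd.DataFrame:
    df = events.merge(
        trees[["tree_id", "experiment", "treatment_id", "leafing_group",
               "leaf_out_doy"]],
        on="tree_id", how="inner",
    )
    is_exp1 = df["experiment"] == 1
    df["cooling"] = df["treatment_id"]
    df.loc[is_exp1, "cooling"] = df.loc[is_exp1, "treatment_id"].map(design.cooling_of)
    return df


def _coef_effects(result, data, factor, reference, response, label_fmt,
                  n_of) -> list[EffectEstimate]:
    effects = []
    prefix = f"C({factor}, Treatment(reference='{reference}'))[T."
    for name in result.params.index:
        if not name.startswith(prefix):
            continue
        level = name[len(prefix):-1]
        est = float(result.params[name])
        se = float(result.bse[name])
        p = float(result.pvalues[name])
        effects.append(EffectEstimate(
            contrast_label=label_fmt(level), response=response,
            estimate=est, se=se, ci_low=est - 2.0 * se, ci_high=est + 2.0 * se,
            p_value=p, n_treated=n_of(level), n_control=n_of(reference),
        ))
    return effects


def fit_treatment_model(
    events: pd.DataFrame,
    trees: pd.DataFrame,
    response: str,
    experiment: int,
    pool_controls: str = "auto",
    control_alpha: float = 0.05,
) -> list[EffectEstimate]:
    """OLS treatment contrasts against the matched control.

    Bud set uses treatment + bud type as predictors; senescence uses treatment
    alone.  Experiment 1 is fitted per leafing group so every coefficient is
    relative to that group's own ambient control.  Experiment 2 merges its
    three control groups into one 72-tree control when a one-way control ANOVA
    is non-significant (``pool_controls='auto'``; 'always'/'never' force it).
    """
    df = _merge_meta(_usable(events, response), trees)
    df = df.loc[df["experiment"] == experiment]
    if df.empty:
        raise ValueError(f"no usable {response} events for experiment {experiment}")
    with_bud = response == "bud_set"
    effects: list[EffectEstimate] = []

    if experiment == 1:
        for group in design.LEAFING_GROUPS:
            sub = df.loc[df["leafing_group"] == group]
            if "control" not in set(sub["cooling"]):
                raise ValueError(f"missing matched control for leafing group {group}")
            formula = "doy ~ C(cooling, Treatment(reference='control'))"
            if with_bud:
                formula += " + C(bud_type)"
            result = smf.ols(formula, data=sub).fit()
            counts = sub.groupby("cooling")["tree_id"].nunique()
            effects.extend(_coef_effects(
                result, sub, "cooling", "control", response,
                lambda lv, g=group: f"{lv}_{g}", lambda lv: int(counts.get(lv, 0)),
            ))
    elif experiment == 2:
        sub = df.copy()
        if pool_controls not in ("auto", "always", "never"):
            raise ValueError("pool_controls must be auto/always/never")
        do_pool = pool_controls == "always"
        if pool_controls == "auto":
            anova = anova_controls(events, trees, design.EXP2_CONTROL_GROUPS, response)
            do_pool = not (anova.p_value < control_alpha)
            log.info("control ANOVA (%s): F=%.3f p=%.3f -> pooling %s",
                     response, anova.F, anova.p_value, do_pool)
        ref = design.POOLED_CONTROL_LABEL if do_pool else "ambient_control"
        sub["treatment"] = sub["treatment_id"]
        if do_pool:
            sub.loc[sub["treatment"].isin(design.EXP2_CONTROL_GROUPS),
                    "treatment"] = design.POOLED_CONTROL_LABEL
        if ref not in set(sub["treatment"]):
            raise ValueError("missing control treatment in experiment 2")
        formula = f"doy ~ C(treatment, Treatment(reference='{ref}'))"
        if with_bud:
            formula += " + C(bud_type)"
        result = smf.ols(formula, data=sub).fit()
        counts = sub.groupby("treatment")["tree_id"].nunique()
        effects.extend(_coef_effects(
            result, sub, "treatment", ref, response,
            lambda lv: lv, lambda lv: int(counts.get(lv, 0)),
        ))
    else:
        raise ValueError(f"unknown experiment: {experiment}")
    return effects


def fit_leafing_contrast(
    events: pd.DataFrame, trees: pd.DataFrame, response: str
) -> EffectEstimate:
    """Across-treatment contrast of late- vs early-leafing trees (experiment 1).

    OLS of event date on leafing group (+ bud type for bud set); the
    coefficient is the mean delay of the late-leafing group in days.
    """
    df = _merge_meta(_usable(events, response), trees)
    df = df.loc[df["experiment"] == 1]
    formula = "doy ~ C(leafing_group, Treatment(reference='early'))"
    if response == "bud_set":
        formula += " + C(bud_type)"
    result = smf.ols(formula, data=df).fit()
    name = "C(leafing_group, Treatment(reference='early'))[T.late]"
    est, se = float(result.params[name]), float(result.bse[name])
    counts = df.groupby("leafing_group")["tree_id"].nunique()
    return EffectEstimate(
        contrast_label="late_leafing", response=response, estimate=est, se=se,
        ci_low=est - 2 * se, ci_high=est + 2 * se,
        p_value=float(result.pvalues[name]),
        n_treated=int(counts.get("late", 0)), n_control=int(counts.get("early", 0)),
    )


def bud_type_effect(
    events: pd.DataFrame, trees: pd.DataFrame, experiment: int
) -> EffectEstimate:
    """Lateral-vs-apical bud-set contrast across all treatments of one
    experiment (negative estimate = lateral buds set earlier)."""
    df = _merge_meta(_usable(events, "bud_set"), trees)
    df = df.loc[df["experiment"] == experiment]
    result = smf.ols(
        "doy ~ C(bud_type, Treatment(reference='apical')) + C(treatment_id)",
        data=df,
    ).fit()
    name = "C(bud_type, Treatment(reference='apical'))[T.lateral]"
    est, se = float(result.params[name]), float(result.bse[name])
    n = int(df["tree_id"].nunique())
    return EffectEstimate(
        contrast_label="lateral_vs_apical", response="bud_set", estimate=est,
        se=se, ci_low=est - 2 * se, ci_high=est + 2 * se,
        p_value=float(result.pvalues[name]), n_treated=n, n_control=n,
    )


def fit_mixed_sensitivity(
    events: pd.DataFrame, trees: pd.DataFrame, response: str, experiment: int = 1
) -> SensitivitySlope:
    """Sensitivity of event timing to leaf-out date (days per day).

    Random-intercept model fitted by REML: event date ~ leaf-out date (+ bud
    type for bud set), with the temperature treatment group as the random
    effect.  The treatment factor is the full design factor (the ten groups of
    experiment 1), so treatment-by-leafing interactions are absorbed by the
    intercepts and the slope is identified from within-group leaf-out
    variation.  A singular or non-converged fit falls back to OLS with the
    treatment as a fixed categorical covariate (warned), which is exact when
    the random variance is zero.
    """
    df = _merge_meta(_usable(events, response), trees)
    df = df.loc[df["experiment"] == experiment]
    groups = df["treatment_id"]
    if groups.nunique() < 3:
        raise ValueError("need >= 3 random-effect groups")
    fixed = "doy ~ leaf_out_doy"
    if response == "bud_set":
        fixed += " + C(bud_type)"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(fixed, data=df, groups=groups)
            result = model.fit(reml=True)
        re_var = float(result.cov_re.iloc[0, 0])
        slope = float(result.params["leaf_out_doy"])
        se = float(result.bse["leaf_out_doy"])
        p = float(result.pvalues["leaf_out_doy"])
        singular = (not result.converged) or not np.isfinite(se) or se == 0.0
    except (np.linalg.LinAlgError, ValueError):
        singular = True
    if singular:
        log.warning("mixed model singular/non-converged; falling back to fixed"
                    " effects for %s", response)
        result = smf.ols(fixed + " + C(treatment_id)", data=df).fit()
        slope = float(result.params["leaf_out_doy"])
        se = float(result.bse["leaf_out_doy"])
        p = float(result.pvalues["leaf_out_doy"])
        return SensitivitySlope(response, slope, se, p, 0.0, "ols_fallback")
    return SensitivitySlope(response, slope, se, p, re_var, "mixed_reml")


def anova_controls(
    events: pd.DataFrame, trees: pd.DataFrame, control_groups, response: str
) -> AnovaResult:
    """Classical one-way ANOVA of event dates across control groups."""
    df = _merge_meta(_usable(events, response), trees)
    samples = []
    for g in control_groups:
        vals = df.loc[df["treatment_id"] == g, "doy"].to_numpy(dtype=float)
        if len(vals) < 2:
            raise ValueError(f"control group {g} has n < 2")
        samples.append(vals)
    if len(samples) < 2:
        raise ValueError("need >= 2 control groups")
    k = len(samples)
    n_total = sum(len(s) for s in samples)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat = scipy.stats.f_oneway(*samples)
    f = float(stat.statistic)
    p = float(stat.pvalue)
    if not np.isfinite(f):
        log.warning("degenerate ANOVA (zero within-group variance, equal means)")
    return AnovaResult(f, k - 1, n_total - k, p)


def adjusted_r2(formula: str, data: pd.DataFrame) -> float:
    result = smf.ols(formula, data=data).fit()
    if np.isnan(result.rsquared_adj):
        raise ValueError(f"rank-deficient subset model: {formula}")
    return float(result.rsquared_adj)


def variance_partition(
    data: pd.DataFrame, response: str, predictor_sets: dict[str, list[str]]
) -> VarPartResult:
    """Commonality analysis over three predictor sets.

    Fits all seven non-empty subset models, records each adjusted R^2, and
    solves the inclusion-exclusion system for the three unique, three
    pairwise-shared and one triple-shared component.  The residual fraction is
    1 minus the full model's adjusted R^2, so all components sum to one.
    """
    names = list(predictor_sets)
    if len(names) != 3 or any(not v for v in predictor_sets.values()):
        raise ValueError("exactly three non-empty predictor sets required")
    subsets = [tuple(c) for r in (1, 2, 3) for c in itertools.combinations(names, r)]
    r2 = {}
    for sub in subsets:
        terms = [t for name in sub for t in predictor_sets[name]]
        r2[sub] = adjusted_r2(f"{response} ~ " + " + ".join(terms), data)
    # component c_S contributes to R2(T) iff S intersects T
    m = np.array([[1.0 if set(s) & set(t) else 0.0 for s in subsets]
                  for t in subsets])
    comps = np.linalg.solve(m, np.array([r2[t] for t in subsets]))
    by_subset = dict(zip(subsets, comps))
    total = r2[tuple(names)]
    return VarPartResult(
        unique_fractions={n: float(by_subset[(n,)]) for n in names},
        shared_fractions={
            "+".join(s): float(by_subset[s]) for s in subsets if len(s) > 1
        },
        residual_fraction=float(1.0 - total),
        total_adjusted_r2=float(total),
    )


def icc(values, groups) -> ICCResult:
    """Intraclass correlation via the one-way ANOVA method of moments.

    V_W is the pooled within-group variance (mean square within); V_T is
    (MS_between - MS_within) / n0, truncated at zero, with n0 the standard
    average group size; ICC = V_T / (V_T + V_W).
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float),
                       "g": np.asarray(groups)})
    sizes = df.groupby("g").size()
    k = len(sizes)
    if k < 2:
        raise ValueError("need >= 2 groups")
    if (sizes < 2).any():
        raise ValueError("every group needs n >= 2")
    n = len(df)
    grand = df["y"].mean()
    means = df.groupby("g")["y"].mean()
    ssb = float((sizes * (means - grand) ** 2).sum())
    ssw = float(((df["y"] - df["g"].map(means)) ** 2).sum())
    msb = ssb / (k - 1)
    msw = ssw / (n - k)
    n0 = (n - float((sizes**2).sum()) / n) / (k - 1)
    v_t = max(0.0, (msb - msw) / n0)
    denom = v_t + msw
    value = v_t / denom if denom > 0 else 0.0
    return ICCResult(v_between=v_t, v_within=msw, icc=value)


def treatment_emms(
    events: pd.DataFrame, trees: pd.DataFrame, response: str, experiment: int,
    pool_controls: bool = True,
) -> dict[str, float]:
    """Estimated marginal means per treatment (averaged over bud types).

    A single OLS on the full treatment factor (10 levels in experiment 1;
    7 in experiment 2 after control pooling) predicted on a balanced
    treatment x bud-type grid.
    """
    df = _merge_meta(_usable(events, response), trees)
    df = df.loc[df["experiment"] == experiment].copy()
    df["treatment"] = df["treatment_id"]
    if experiment == 2 and pool_controls:
        df.loc[df["treatment"].isin(design.EXP2_CONTROL_GROUPS),
               "treatment"] = design.POOLED_CONTROL_LABEL
    with_bud = response == "bud_set"
    formula = "doy ~ C(treatment)" + (" + C(bud_type)" if with_bud else "")
    result = smf.ols(formula, data=df).fit()
    levels = sorted(df["treatment"].unique())
    if with_bud:
        grid = pd.DataFrame(
            [(t, b) for t in levels for b in design.BUD_TYPES],
            columns=["treatment", "bud_type"],
        )
        pred = result.predict(grid)
        grid["emm"] = pred
        emm = grid.groupby("treatment")["emm"].mean()
    else:
        grid = pd.DataFrame({"treatment": levels})
        emm = pd.Series(result.predict(grid).to_numpy(), index=levels)
    return {t: float(emm[t]) for t in levels}


def emm_coupling(
    bud_emms: dict[int, dict[str, float]],
    senescence_emms: dict[int, dict[str, float]],
) -> CouplingResult:
    """Directional agreement of bud-set and senescence treatment responses.

    All unordered pairwise EMM differences within each experiment (45 pairs
    for the 10 groups of experiment 1, 21 for the 7 of experiment 2 after
    control pooling = 66) are compared between the two responses: agreement
    means the same sign; also reports the adjusted R^2 of the senescence
    differences regressed on the bud-set differences.
    """
    rows = []
    for exp in sorted(bud_emms):
        b, s = bud_emms[exp], senescence_emms.get(exp)
        if s is None or set(b) != set(s):
            raise ValueError(
                f"experiment {exp}: treatments differ between responses"
            )
        for t1, t2 in itertools.combinations(sorted(b), 2):
            rows.append(dict(
                experiment=exp, pair=f"{t1} vs {t2}",
                d_bud=b[t1] - b[t2], d_senescence=s[t1] - s[t2],
            ))
    pairs = pd.DataFrame(rows)
    agree = np.sign(pairs["d_bud"]) == np.sign(pairs["d_senescence"])
    fit = smf.ols("d_senescence ~ d_bud", data=pairs).fit()
    return CouplingResult(
        n_pairs=len(pairs), n_agree=int(agree.sum()),
        fraction_agree=float(agree.mean()),
        adjusted_r2=float(fit.rsquared_adj), pair_table=pairs,
    )


def effects_to_frame(effects: list[EffectEstimate]) -> pd.DataFrame:
    """Long-format effects table with both sign conventions."""
    return pd.DataFrame([
        dict(contrast_label=e.contrast_label, response=e.response,
             estimate=e.estimate, advance=e.advance, se=e.se,
             ci_low=e.ci_low, ci_high=e.ci_high, p_value=e.p_value,
             n_treated=e.n_treated, n_control=e.n_control)
        for e in effects
    ])
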