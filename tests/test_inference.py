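"""Statistical layer: contrasts, ANOVA, variance partitioning, ICC, coupling."""

import itertools
import json
import subprocess

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from beechpheno import design
from beechpheno.inference import (
    anova_controls,
    emm_coupling,
    fit_mixed_sensitivity,
    fit_treatment_model,
    icc,
    treatment_emms,
    variance_partition,
)
from beechpheno.simulate import SimConfig, simulate_population


def truth_as_events(trees: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Recast ground-truth dates as an uncensored events table, bypassing the
    measurement layer so the statistical machinery is tested in isolation."""
    bud = truth.rename(columns={"true_budset_doy": "doy"})[
        ["tree_id", "bud_type", "doy"]].copy()
    bud["event"] = "bud_set"
    sen = truth.drop_duplicates("tree_id").rename(
        columns={"true_senescence_doy": "doy"})[["tree_id", "doy"]].copy()
    sen["event"] = "senescence"
    sen["bud_type"] = None
    out = pd.concat([bud, sen], ignore_index=True)
    out["threshold_value"] = np.nan
    out["censoring_flag"] = "none"
    return out


def _two_group_events():
    trees = pd.DataFrame(
        {"tree_id": ["a", "b", "c", "d"], "experiment": 2,
         "treatment_id": ["ambient_control"] * 2 + ["pre_day"] * 2,
         "leafing_group": "none", "leaf_out_doy": 118.0, "block": 1}
    )
    events = pd.DataFrame(
        {"tree_id": ["a", "b", "c", "d"], "bud_type": None,
         "event": "senescence", "doy": [10.0, 10.0, 14.0, 14.0],
         "threshold_value": np.nan, "censoring_flag": "none"}
    )
    return events, trees


# ----------------------------------------------------------- treatment models
def test_two_group_difference_exact():
    events, trees = _two_group_events()
    effects = fit_treatment_model(events, trees, "senescence", 2,
                                  pool_controls="never")
    (eff,) = effects
    assert eff.estimate == pytest.approx(4.0, abs=1e-10)
    assert eff.se == pytest.approx(0.0, abs=1e-8)
    assert eff.n_treated == 2 and eff.n_control == 2


def test_null_effects_rarely_exceed_two_se():
    """With zero injected treatment effects the estimated contrasts should be
    inside +/- 2 SE for ~95% of treatment x seed combinations."""
    zero = {k: 0.0 for k in SimConfig().treatment_shifts}
    inside = total = 0
    for seed in range(25):
        cfg = SimConfig(seed=seed, treatment_shifts=dict(zero),
                        senescence_shifts=dict(zero))
        trees, truth = simulate_population(cfg)
        events = truth_as_events(trees, truth)
        for eff in fit_treatment_model(events, trees, "bud_set", 1):
            inside += abs(eff.estimate) < 2 * eff.se
            total += 1
    assert inside / total >= 0.90


def test_matched_control_required():
    events, trees = _two_group_events()
    trees["experiment"] = 1
    trees["treatment_id"] = ["july_moderate_early"] * 2 + ["july_moderate_late"] * 2
    trees["leafing_group"] = ["early"] * 2 + ["late"] * 2
    with pytest.raises(ValueError, match="control"):
        fit_treatment_model(events, trees, "senescence", 1)


# -------------------------------------------------------------- sensitivity
def test_noiseless_slope_recovered_exactly():
    zero = {k: 0.0 for k in SimConfig().treatment_shifts}
    cfg = SimConfig(
        seed=0, esd_slope=0.24, senescence_slope=0.22, sd_individual=0.0,
        treatment_shifts=dict(zero), senescence_shifts=dict(zero),
    )
    trees, truth = simulate_population(cfg)
    events = truth_as_events(trees, truth)
    slope = fit_mixed_sensitivity(events, trees, "bud_set", experiment=1)
    assert slope.slope == pytest.approx(0.24, abs=1e-6)
    sen = fit_mixed_sensitivity(events, trees, "senescence", experiment=1)
    assert sen.slope == pytest.approx(0.22, abs=1e-6)


def test_zero_slope_centred_on_zero():
    zero = {k: 0.0 for k in SimConfig().treatment_shifts}
    ests = []
    for seed in range(10):
        cfg = SimConfig(seed=seed, esd_slope=0.0, treatment_shifts=dict(zero),
                        senescence_shifts=dict(zero))
        trees, truth = simulate_population(cfg)
        slope = fit_mixed_sensitivity(truth_as_events(trees, truth), trees,
                                      "bud_set", experiment=1)
        ests.append(slope.slope)
    assert abs(np.mean(ests)) < 0.05


def test_sensitivity_needs_three_groups():
    events, trees = _two_group_events()
    with pytest.raises(ValueError, match="3 random-effect groups"):
        fit_mixed_sensitivity(events, trees, "senescence", experiment=2)


# --------------------------------------------------------------------- ANOVA
def _anova_events(groups: dict):
    rows_t, rows_e = [], []
    for g, vals in groups.items():
        for i, v in enumerate(vals):
            tid = f"{g}_{i}"
            rows_t.append(dict(tree_id=tid, experiment=2, treatment_id=g,
                               leafing_group="none", leaf_out_doy=118.0, block=1))
            rows_e.append(dict(tree_id=tid, bud_type=None, event="senescence",
                               doy=float(v), threshold_value=np.nan,
                               censoring_flag="none"))
    return pd.DataFrame(rows_e), pd.DataFrame(rows_t)


def test_anova_hand_example():
    # hand table for {1,2,3} vs {4,5,6}: means 2 and 5, grand mean 3.5,
    # SSB = 3*1.5^2 + 3*1.5^2 = 13.5 on 1 df; SSW = 4 on 4 df, MSW = 1
    events, trees = _anova_events({"g1": [1, 2, 3], "g2": [4, 5, 6]})
    res = anova_controls(events, trees, ["g1", "g2"], "senescence")
    assert res.F == pytest.approx(13.5, abs=1e-10)
    assert (res.df1, res.df2) == (1, 4)


def test_anova_identical_groups_f_zero_p_one():
    events, trees = _anova_events(
        {"g1": [1, 2, 3], "g2": [1, 2, 3], "g3": [1, 2, 3]})
    res = anova_controls(events, trees, ["g1", "g2", "g3"], "senescence")
    assert res.F == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0, abs=1e-12)


def test_anova_degenerate_equal_constant_groups_reports_nan():
    events, trees = _anova_events({"g1": [5, 5], "g2": [5, 5]})
    res = anova_controls(events, trees, ["g1", "g2"], "senescence")
    assert np.isnan(res.F)


def test_null_control_anova_p_values_uniform():
    """With no chamber effect the control ANOVA p-values follow U(0,1)
    (Kolmogorov-Smirnov not rejecting at alpha = 0.01 over 500 seeds)."""
    pvals = []
    for seed in range(500):
        cfg = SimConfig(seed=20_000 + seed, n_trees_exp1=40, n_trees_exp2=50)
        trees, truth = simulate_population(cfg)
        events = truth_as_events(trees, truth)
        res = anova_controls(events, trees, design.EXP2_CONTROL_GROUPS,
                             "senescence")
        pvals.append(res.p_value)
    assert scipy.stats.kstest(pvals, "uniform").pvalue > 0.01


# --------------------------------------------------------- variance partition
def _commonality_oracle(r2):
    """Closed-form commonality coefficients for three predictor sets, written
    independently of the linear-system solver."""
    a, b, c = "A", "B", "C"
    u = {
        a: r2[("A", "B", "C")] - r2[("B", "C")],
        b: r2[("A", "B", "C")] - r2[("A", "C")],
        c: r2[("A", "B", "C")] - r2[("A", "B")],
    }
    s = {
        ("A", "B"): r2[("A", "C")] + r2[("B", "C")] - r2[("C",)] - r2[("A", "B", "C")],
        ("A", "C"): r2[("A", "B")] + r2[("B", "C")] - r2[("B",)] - r2[("A", "B", "C")],
        ("B", "C"): r2[("A", "B")] + r2[("A", "C")] - r2[("A",)] - r2[("A", "B", "C")],
        ("A", "B", "C"): (r2[("A",)] + r2[("B",)] + r2[("C",)]
                          - r2[("A", "B")] - r2[("A", "C")] - r2[("B", "C")]
                          + r2[("A", "B", "C")]),
    }
    return u, s


def test_varpart_matches_bruteforce_oracle_on_random_data():
    from beechpheno.inference import adjusted_r2

    rng = np.random.default_rng(123)
    for _ in range(50):
        n = int(rng.integers(25, 60))
        df = pd.DataFrame(rng.normal(size=(n, 4)), columns=["y", "x1", "x2", "x3"])
        df["y"] += rng.normal() * df["x1"] + rng.normal() * df["x2"]
        sets = {"A": ["x1"], "B": ["x2"], "C": ["x3"]}
        vp = variance_partition(df, "y", sets)
        r2 = {}
        for r in (1, 2, 3):
            for combo in itertools.combinations("ABC", r):
                terms = [t for nm in combo for t in sets[nm]]
                r2[combo] = adjusted_r2("y ~ " + " + ".join(terms), df)
        u, s = _commonality_oracle(r2)
        for k in "ABC":
            assert vp.unique_fractions[k] == pytest.approx(u[k], abs=1e-10)
        assert vp.shared_fractions["A+B"] == pytest.approx(s[("A", "B")], abs=1e-10)
        assert vp.shared_fractions["A+C"] == pytest.approx(s[("A", "C")], abs=1e-10)
        assert vp.shared_fractions["B+C"] == pytest.approx(s[("B", "C")], abs=1e-10)
        assert vp.shared_fractions["A+B+C"] == pytest.approx(
            s[("A", "B", "C")], abs=1e-10)
        total = (sum(vp.unique_fractions.values())
                 + sum(vp.shared_fractions.values()) + vp.residual_fraction)
        assert total == pytest.approx(1.0, abs=1e-9)


def test_varpart_pure_signal_attributes_everything_to_one_set():
    rng = np.random.default_rng(7)
    n = 200
    df = pd.DataFrame({
        "y": 0.0, "leafout": rng.normal(size=n),
        "trt": rng.choice(list("pqr"), n), "bud": rng.choice(["ap", "la"], n),
    })
    df["y"] = 2.0 * df["leafout"]  # response generated from leaf-out alone
    vp = variance_partition(
        df, "y", {"leafout": ["leafout"], "treatment": ["C(trt)"],
                  "bud_type": ["C(bud)"]})
    assert vp.unique_fractions["leafout"] == pytest.approx(1.0, abs=0.01)
    assert vp.total_adjusted_r2 == pytest.approx(1.0, abs=1e-9)
    for k, v in vp.shared_fractions.items():
        assert abs(v) < 0.01, k


def test_varpart_orthogonal_predictors_have_no_commonality():
    # balanced 2x2x2 factorial, effects additive: shared components vanish
    rows = []
    rng = np.random.default_rng(99)
    for x1 in (-1.0, 1.0):
        for x2 in (-1.0, 1.0):
            for x3 in (-1.0, 1.0):
                for _ in range(25):
                    rows.append(dict(
                        x1=x1, x2=x2, x3=x3,
                        y=1.5 * x1 + 1.0 * x2 + 0.5 * x3 + rng.normal(0, 0.7)))
    df = pd.DataFrame(rows)
    vp = variance_partition(df, "y", {"A": ["x1"], "B": ["x2"], "C": ["x3"]})
    for k, v in vp.shared_fractions.items():
        assert abs(v) < 0.02, k


def test_varpart_agrees_with_vegan(tmp_path):
    """Independent cross-check of the commonality solver against vegan's
    varpart on one random dataset."""
    rng = np.random.default_rng(0)
    n = 40
    df = pd.DataFrame(rng.normal(size=(n, 4)), columns=["y", "x1", "x2", "x3"])
    df["y"] = 0.8 * df["x1"] + 0.4 * df["x2"] + rng.normal(size=n)
    csv = tmp_path / "d.csv"
    df.to_csv(csv, index=False)
    rcode = (
        'suppressMessages(library(vegan));'
        f'd <- read.csv("{csv}");'
        'v <- varpart(d$y, ~x1, ~x2, ~x3, data=d);'
        'cat(jsonlite::toJSON(v$part$indfract$Adj.R.square, digits=12))'
    )
    out = subprocess.run(["Rscript", "-e", rcode], capture_output=True,
                         text=True, check=True)
    vegan = json.loads(out.stdout)  # [a,b,c, d=AB, e=BC, f=AC, g=ABC, resid]
    vp = variance_partition(df, "y", {"A": ["x1"], "B": ["x2"], "C": ["x3"]})
    mine = [vp.unique_fractions["A"], vp.unique_fractions["B"],
            vp.unique_fractions["C"], vp.shared_fractions["A+B"],
            vp.shared_fractions["B+C"], vp.shared_fractions["A+C"],
            vp.shared_fractions["A+B+C"], vp.residual_fraction]
    assert np.allclose(sorted(mine), sorted(vegan), atol=1e-6)


# ------------------------------------------------------------------------ ICC
def test_icc_equal_variance_components_give_half():
    # constructed so V_T == V_W exactly: d^2 = 1.5 a^2 with a = 2
    d = np.sqrt(6.0)
    res = icc([0.0, 2.0, d, d + 2.0], ["g1", "g1", "g2", "g2"])
    assert res.icc == pytest.approx(0.5, abs=1e-12)


def test_icc_identical_group_means_is_zero():
    res = icc([1.0, 3.0, 1.0, 3.0], ["g1", "g1", "g2", "g2"])
    assert res.icc == 0.0
    assert res.v_between == 0.0


def test_icc_zero_within_variance_is_one():
    res = icc([0, 0, 10, 10, 20, 20], ["a", "a", "b", "b", "c", "c"])
    assert res.v_within == 0.0
    assert res.icc == 1.0


def test_icc_translation_and_scale_behaviour():
    rng = np.random.default_rng(3)
    vals = rng.normal(0, 1, 30) + np.repeat([0, 2, 4], 10)
    groups = np.repeat(["a", "b", "c"], 10)
    base = icc(vals, groups)
    shifted = icc(vals + 100.0, groups)
    scaled = icc(vals * 3.0, groups)
    assert shifted.icc == pytest.approx(base.icc, abs=1e-12)
    assert scaled.icc == pytest.approx(base.icc, abs=1e-9)


def test_icc_single_group_rejected():
    with pytest.raises(ValueError):
        icc([1.0, 2.0], ["g", "g"])


# ------------------------------------------------------------------- coupling
def test_emm_pair_count_is_66_on_the_two_designs():
    cfg = SimConfig(seed=4)
    trees, truth = simulate_population(cfg)
    events = truth_as_events(trees, truth)
    bud = {e: treatment_emms(events, trees, "bud_set", e) for e in (1, 2)}
    sen = {e: treatment_emms(events, trees, "senescence", e) for e in (1, 2)}
    assert len(bud[1]) == 10 and len(bud[2]) == 7
    res = emm_coupling(bud, sen)
    assert res.n_pairs == 45 + 21 == 66


def test_coupling_identical_and_flipped_effects():
    bud = {1: {"a": 0.0, "b": 1.0, "c": 3.0, "d": -2.0}}
    same = emm_coupling(bud, {1: dict(bud[1])})
    assert same.fraction_agree == 1.0
    assert same.adjusted_r2 == pytest.approx(1.0, abs=1e-12)
    flipped = emm_coupling(bud, {1: {k: -v for k, v in bud[1].items()}})
    assert flipped.fraction_agree == 0.0


def test_coupling_rejects_mismatched_treatments():
    with pytest.raises(ValueError, match="differ"):
        emm_coupling({1: {"a": 0.0, "b": 1.0}}, {1: {"a": 0.0, "x": 1.0}})
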