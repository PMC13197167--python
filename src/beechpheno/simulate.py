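"""Seeded synthetic populations with the structure of both cooling experiments.

The generator embodies the conceptual model behind the study: autumn events
are pulled earlier by faster early-season development (ESD effect, encoded as
a positive slope of event date on leaf-out date) and shifted by summer cooling
treatments (LST effect, encoded as per-treatment day shifts whose defaults
mirror the experiments' estimated effects).  Each tree's true event date is

    true = base + slope * (leaf_out - reference) + treatment_shift
           + bud_type_offset + individual_effect,   individual ~ N(0, sd)

Bud growth follows a logistic curve parameterised so that its noiseless
90%-of-maximum crossing equals the true bud-set date; chlorophyll follows a
plateau-then-sigmoidal decline whose 50%-of-peak crossing equals the true
senescence date, mapped back to SPAD on the calibration's increasing branch
and read on nine leaves per tree per date.  Everything is deterministic under
a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import design
from .phenometrics import CHL_MAX, chl_to_spad

# Bud-set day shifts (days; positive = later event) whose defaults mirror the
# estimated treatment effects of the two experiments.
DEFAULT_TREATMENT_SHIFTS = {
    # experiment 1 (early/late = leafing group)
    "control_early": 0.0, "control_late": 0.0,
    "july_moderate_early": 1.4, "july_moderate_late": 4.8,
    "july_extreme_early": 1.0, "july_extreme_late": 4.0,
    "august_moderate_early": -4.5, "august_moderate_late": -4.4,
    "august_extreme_early": -1.9, "august_extreme_late": -4.0,
    # experiment 2
    "ambient_control": 0.0, "pre_chamber_control": 0.0,
    "post_chamber_control": 0.0,
    "pre_day": 0.1, "pre_night": 4.2, "pre_full_day": 4.1,
    "post_day": -5.3, "post_night": 3.8, "post_full_day": -5.2,
}

# Senescence responses were weaker than bud-set responses overall, and of
# opposite sign in two groups (early-leafing extreme August; post-solstice
# full-day cooling).  Unreported shifts default to 0.65x the bud shift.
DEFAULT_SENESCENCE_SHIFTS = {
    "control_early": 0.0, "control_late": 0.0,
    "july_moderate_early": 0.9, "july_moderate_late": 3.1,
    "july_extreme_early": 0.65, "july_extreme_late": 2.6,
    "august_moderate_early": -2.9, "august_moderate_late": -2.9,
    "august_extreme_early": 1.77, "august_extreme_late": -2.6,
    "ambient_control": 0.0, "pre_chamber_control": 0.0,
    "post_chamber_control": 0.0,
    "pre_day": 0.1, "pre_night": 2.7, "pre_full_day": 2.7,
    "post_day": -3.4, "post_night": 2.5, "post_full_day": 1.66,
}

#: Weekly bud measurement schedule, 4 July to 2 November (experiment 1).
DEFAULT_BUD_SCHEDULE_EXP1 = tuple(range(185, 305, 7))
#: Weekly bud measurement schedule, 25 August to 3 November (experiment 2).
DEFAULT_BUD_SCHEDULE_EXP2 = tuple(range(237, 308, 7))
#: SPAD schedule: monthly in summer, fortnightly in September, weekly from
#: October to mid-December (includes 7 December = day 341).
DEFAULT_SPAD_SCHEDULE = (
    166, 196, 227, 244, 258, 272, 279, 286, 293, 300,
    307, 314, 321, 328, 335, 341, 349,
)


@dataclass
class SimConfig:
    """Study conditions for the synthetic populations.

    Effect sizes (slopes, shifts, bud-type offsets) default to the values the
    experiments estimated; dispersion parameters are documented assumptions
    (the study reports only that within-treatment variance is large).
    """

    seed: int = 0
    n_trees_exp1: int = 267
    n_trees_exp2: int = 180
    base_budset_doy: float = 232.0          # experiment 1 (~20 Aug)
    base_budset_doy_exp2: float = 272.0     # experiment 2 (~end Sept)
    base_senescence_doy: float = 300.0      # (~late Oct)
    esd_slope: float = 0.24                 # days bud-set delay / day leaf-out delay
    senescence_slope: float = 0.22
    treatment_shifts: dict = field(
        default_factory=lambda: dict(DEFAULT_TREATMENT_SHIFTS))
    senescence_shifts: dict = field(
        default_factory=lambda: dict(DEFAULT_SENESCENCE_SHIFTS))
    bud_type_offset_exp1: float = -1.1      # lateral minus apical, days
    bud_type_offset_exp2: float = -9.4
    sd_individual: float = 7.0              # tree-level SD of event dates, days
    sd_measurement_bud: float = 0.2         # mm
    sd_measurement_spad: float = 2.0        # SPAD units per leaf reading
    outlier_rate: float = 0.01              # per tree x SPAD date session
    bud_schedule: tuple = DEFAULT_BUD_SCHEDULE_EXP1
    bud_schedule_exp2: tuple = DEFAULT_BUD_SCHEDULE_EXP2
    spad_schedule: tuple = DEFAULT_SPAD_SCHEDULE
    leafout_doy_early: tuple = (118.0, 4.0)  # (mean, sd)
    leafout_doy_late: tuple = (137.2, 4.0)
    growth_window_days: float = 60.0        # 5% -> 95% span of bud growth
    bud_final_length_mean: float = 18.0     # mm
    bud_final_length_sd: float = 3.0
    chl_peak_mean: float = 85.0             # ug/g fresh weight
    chl_peak_sd: float = 4.0
    chl_floor: float = 5.0                  # residual chlorophyll after decline
    senescence_scale_days: float = 6.0      # sigmoid time scale of the decline
    #: SPAD inflation applied on anomalous dates (emulates the unreliable
    #: 7-December readings the cleaning step exists to remove).
    anomalous_spad_doys: dict = field(default_factory=lambda: {341: 20.0})

    def validate(self) -> None:
        sds = (
            self.sd_individual, self.sd_measurement_bud, self.sd_measurement_spad,
            self.leafout_doy_early[1], self.leafout_doy_late[1],
            self.bud_final_length_sd, self.chl_peak_sd,
        )
        if any(s < 0 for s in sds):
            raise ValueError("all standard deviations must be >= 0")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ValueError("outlier_rate must be in [0, 1]")
        for sched in (self.bud_schedule, self.bud_schedule_exp2, self.spad_schedule):
            if np.any(np.diff(sched) <= 0):
                raise ValueError("measurement schedules must be strictly increasing")
        design.exp1_group_sizes(self.n_trees_exp1)
        design.exp2_group_sizes(self.n_trees_exp2)
        labels = set(self.treatment_shifts)
        needed = set(design.EXP1_TREATMENTS) | set(design.EXP2_TREATMENTS)
        missing = needed - labels
        if missing:
            raise ValueError(f"treatment_shifts missing labels: {sorted(missing)}")
        unknown = labels - needed
        if unknown:
            raise ValueError(f"unknown treatment labels: {sorted(unknown)}")
        if self.chl_peak_mean >= CHL_MAX:
            raise ValueError(
                f"chl_peak_mean must be attainable for SPAD in [0, 100] (< {CHL_MAX:.4f})"
            )
        if not self.chl_floor < 0.5 * self.chl_peak_mean:
            raise ValueError("chl_floor must lie below half the peak")

    def noiseless(self) -> "SimConfig":
        """Copy with all measurement noise, outliers and artifacts removed
        (individual effects are part of the recorded truth and stay)."""
        return replace(
            self, sd_measurement_bud=0.0, sd_measurement_spad=0.0,
            outlier_rate=0.0, anomalous_spad_doys={},
        )


def _logistic_rate(window_days: float) -> float:
    """Logistic rate k such that 5% -> 95% of growth spans ``window_days``."""
    return 2.0 * math.log(19.0) / window_days


def budset_logistic_midpoint(
    true_budset_doy: float, t_last: float, k: float
) -> float:
    """Midpoint t0 of a logistic growth curve A/(1+exp(-k(t-t0))) whose
    continuous 90%-of-observed-maximum crossing equals ``true_budset_doy``.

    The observed maximum of the noiseless curve is its value at the last
    measurement day, so the crossing condition is
    L(true) = 0.9 * L(t_last); solving gives a closed form.  Requires the
    true date to precede ``t_last`` by more than ln(10/9)/k days.
    """
    delta = t_last - true_budset_doy
    denom = 0.9 * math.exp(k * delta) - 1.0
    if denom <= 0:
        raise ValueError(
            f"true bud-set {true_budset_doy} too close to the window end {t_last}"
        )
    v = 0.1 / denom
    return t_last + math.log(v) / k


def simulate_bud_series(
    true_budset_doy: float,
    config: SimConfig,
    schedule=None,
    final_length: float | None = None,
    rng: np.random.Generator | None = None,
):
    """Sample a logistic bud-growth curve at the measurement schedule.

    Returns ``(doys, lengths_mm)``.  With zero measurement noise the
    90%-of-maximum extractor recovers ``true_budset_doy`` to within the linear
    interpolation error of the schedule (well under half a day at weekly
    spacing).  Lengths are floored at the 0.01 mm calliper resolution.
    """
    sched = np.asarray(config.bud_schedule if schedule is None else schedule,
                       dtype=float)
    if not sched[0] < true_budset_doy < sched[-1]:
        raise ValueError(
            f"true bud-set {true_budset_doy} outside schedule "
            f"[{sched[0]}, {sched[-1]}]"
        )
    k = _logistic_rate(config.growth_window_days)
    t0 = budset_logistic_midpoint(true_budset_doy, sched[-1], k)
    amplitude = config.bud_final_length_mean if final_length is None else final_length
    # the closed form matches the continuous crossing; two fixed-point shifts
    # make the *linearly interpolated* crossing match the true date
    from .phenometrics import BUDSET_FRACTION, _first_upward_crossing
    for _ in range(2):
        vals = 1.0 / (1.0 + np.exp(-k * (sched - t0)))
        crossing, flag = _first_upward_crossing(
            sched, vals, BUDSET_FRACTION * vals.max())
        if flag != "none":
            break
        t0 += true_budset_doy - crossing
    lengths = amplitude / (1.0 + np.exp(-k * (sched - t0)))
    if config.sd_measurement_bud > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        lengths = lengths + rng.normal(0.0, config.sd_measurement_bud, len(sched))
    return sched, np.maximum(lengths, 0.01)


def senescence_sigmoid_midpoint(
    true_senescence_doy: float, t_first: float, peak: float, floor: float,
    scale: float,
) -> float:
    """Midpoint m of C(t) = floor + (peak-floor)/(1+exp((t-m)/scale)) whose
    last 50%-of-observed-peak downward crossing equals the true date.

    The observed peak is the curve's value at the first measurement day, which
    feeds back into the threshold, so m is found by root bracketing.
    """

    def crossing(m: float) -> float:
        obs_peak = floor + (peak - floor) / (1.0 + math.exp((t_first - m) / scale))
        tau = 0.5 * obs_peak
        if tau <= floor:
            return math.inf
        return m + scale * math.log((peak - tau) / (tau - floor))

    lo, hi = true_senescence_doy - 60.0, true_senescence_doy + 60.0
    return brentq(lambda m: crossing(m) - true_senescence_doy, lo, hi, xtol=1e-10)


def simulate_chl_curve(
    true_senescence_doy: float, config: SimConfig, peak: float | None = None,
    schedule=None,
):
    """Noiseless tree-level chlorophyll trajectory (plateau, then sigmoidal
    decline) whose extracted senescence date equals the true one."""
    sched = np.asarray(config.spad_schedule if schedule is None else schedule,
                       dtype=float)
    if not sched[0] < true_senescence_doy < sched[-1]:
        raise ValueError(
            f"true senescence {true_senescence_doy} outside schedule "
            f"[{sched[0]}, {sched[-1]}]"
        )
    p = config.chl_peak_mean if peak is None else peak
    if not config.chl_floor < p <= CHL_MAX:
        raise ValueError("peak chlorophyll not attainable for SPAD in [0, 100]")
    m = senescence_sigmoid_midpoint(
        true_senescence_doy, sched[0], p, config.chl_floor,
        config.senescence_scale_days,
    )
    from .phenometrics import SENESCENCE_FRACTION, _last_downward_crossing

    def curve(mid):
        return config.chl_floor + (p - config.chl_floor) / (
            1.0 + np.exp((sched - mid) / config.senescence_scale_days)
        )

    # align the interpolated 50%-of-peak crossing with the true date
    for _ in range(2):
        vals = curve(m)
        crossing, flag = _last_downward_crossing(
            sched, vals, SENESCENCE_FRACTION * vals.max())
        if flag != "none":
            break
        m += true_senescence_doy - crossing
    return sched, curve(m)


def simulate_spad_series(
    true_senescence_doy: float,
    config: SimConfig,
    peak: float | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Nine leaf-level SPAD replicates per date for one tree.

    The tree's chlorophyll curve is mapped back to SPAD on the calibration's
    increasing branch; each of nine leaves (three per crown position) reads it
    with Normal noise, clipped to the meter range.  Anomalous dates configured
    in ``anomalous_spad_doys`` get inflated readings (the artifact the
    date-exclusion cleaning rule removes).
    """
    sched, chl = simulate_chl_curve(true_senescence_doy, config, peak)
    base_spad = chl_to_spad(chl)
    rows = {"doy": [], "leaf_position": [], "spad": []}
    if rng is None:
        rng = np.random.default_rng(config.seed)
    noise = (
        rng.normal(0.0, config.sd_measurement_spad, (len(sched), 9))
        if config.sd_measurement_spad > 0
        else np.zeros((len(sched), 9))
    )
    positions = [f"{p}_{i}" for p in ("top", "middle", "bottom") for i in (1, 2, 3)]
    for j, (d, s) in enumerate(zip(sched, base_spad)):
        inflate = config.anomalous_spad_doys.get(int(d), 0.0)
        vals = np.clip(s + inflate + noise[j], 0.0, 100.0)
        rows["doy"].extend([d] * 9)
        rows["leaf_position"].extend(positions)
        rows["spad"].extend(vals)
    return pd.DataFrame(rows)


def simulate_population(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tree metadata and true phenology for both experiments.

    Returns ``(trees, truth)``: trees with columns (tree_id, experiment,
    treatment_id, leafing_group, leaf_out_doy, block); truth in long format
    (tree_id, bud_type, true_budset_doy, true_senescence_doy).  True dates are
    kept strictly inside the measurement windows.  Deterministic under the
    configured seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    tree_rows, truth_rows = [], []

    def leafout_params(group: str):
        return (config.leafout_doy_early if group != "late"
                else config.leafout_doy_late)

    specs = []
    sizes1 = design.exp1_group_sizes(config.n_trees_exp1)
    for t in design.EXP1_TREATMENTS:
        specs.extend((1, t, design.leafing_of(t)) for _ in range(sizes1[t]))
    sizes2 = design.exp2_group_sizes(config.n_trees_exp2)
    for t in design.EXP2_TREATMENTS:
        specs.extend((2, t, "none") for _ in range(sizes2[t]))

    ref1 = 0.5 * (config.leafout_doy_early[0] + config.leafout_doy_late[0])
    ref2 = config.leafout_doy_early[0]
    bud_windows = {
        1: (config.bud_schedule[0] + 3.0, config.bud_schedule[-1] - 3.0),
        2: (config.bud_schedule_exp2[0] + 3.0, config.bud_schedule_exp2[-1] - 3.0),
    }
    sen_window = (config.spad_schedule[0] + 10.0, config.spad_schedule[-1] - 5.0)

    counters = {1: 0, 2: 0}
    for exp, treatment, group in specs:
        counters[exp] += 1
        tree_id = f"E{exp}_T{counters[exp]:03d}"
        mean_lo, sd_lo = leafout_params(group)
        leaf_out = mean_lo + (rng.normal(0.0, sd_lo) if sd_lo > 0 else 0.0)
        # individual variation is drawn per event (per bud for bud set, per
        # tree for senescence): event dates of one tree vary independently
        if config.sd_individual:
            e_bud = {b: rng.normal(0.0, config.sd_individual)
                     for b in design.BUD_TYPES}
            e_sen = rng.normal(0.0, config.sd_individual)
        else:
            e_bud = {b: 0.0 for b in design.BUD_TYPES}
            e_sen = 0.0
        block = int(rng.integers(1, 7))
        base_bud = config.base_budset_doy if exp == 1 else config.base_budset_doy_exp2
        ref = ref1 if exp == 1 else ref2
        slope_term = config.esd_slope * (leaf_out - ref)
        shift = config.treatment_shifts[treatment]
        offset = (config.bud_type_offset_exp1 if exp == 1
                  else config.bud_type_offset_exp2)
        lo_b, hi_b = bud_windows[exp]
        budset = {
            "apical": float(np.clip(
                base_bud + slope_term + shift + e_bud["apical"], lo_b, hi_b)),
            "lateral": float(np.clip(
                base_bud + slope_term + shift + offset + e_bud["lateral"],
                lo_b, hi_b)),
        }
        sen = float(np.clip(
            config.base_senescence_doy
            + config.senescence_slope * (leaf_out - ref)
            + config.senescence_shifts[treatment] + e_sen,
            *sen_window,
        ))
        tree_rows.append(dict(
            tree_id=tree_id, experiment=exp, treatment_id=treatment,
            leafing_group=group, leaf_out_doy=float(leaf_out), block=block,
        ))
        for bud_type in design.BUD_TYPES:
            truth_rows.append(dict(
                tree_id=tree_id, bud_type=bud_type,
                true_budset_doy=budset[bud_type], true_senescence_doy=sen,
            ))
    return pd.DataFrame(tree_rows), pd.DataFrame(truth_rows)


def generate_bud_measurements(
    trees: pd.DataFrame, truth: pd.DataFrame, config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Bud-length tables for every (tree, bud type) in the population."""
    exp_of = trees.set_index("tree_id")["experiment"]
    frames = []
    for row in truth.itertuples(index=False):
        exp = int(exp_of[row.tree_id])
        sched = config.bud_schedule if exp == 1 else config.bud_schedule_exp2
        amp = max(2.0, config.bud_final_length_mean
                  + (rng.normal(0.0, config.bud_final_length_sd)
                     if config.bud_final_length_sd > 0 else 0.0))
        doys, lengths = simulate_bud_series(
            row.true_budset_doy, config, schedule=sched, final_length=amp, rng=rng,
        )
        frames.append(pd.DataFrame({
            "tree_id": row.tree_id, "bud_type": row.bud_type,
            "doy": doys, "length_mm": lengths,
        }))
    return pd.concat(frames, ignore_index=True)


def generate_spad_measurements(
    trees: pd.DataFrame, truth: pd.DataFrame, config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Leaf-level SPAD tables for every tree in the population."""
    sen = truth.drop_duplicates("tree_id").set_index("tree_id")["true_senescence_doy"]
    frames = []
    for tree_id in trees["tree_id"]:
        peak = float(np.clip(
            config.chl_peak_mean
            + (rng.normal(0.0, config.chl_peak_sd) if config.chl_peak_sd > 0 else 0.0),
            2.0 * config.chl_floor + 1.0, CHL_MAX - 0.5,
        ))
        df = simulate_spad_series(float(sen[tree_id]), config, peak=peak, rng=rng)
        df.insert(0, "tree_id", tree_id)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def inject_outliers(
    spad_df: pd.DataFrame, trees: pd.DataFrame, config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Displace a random fraction of tree x date SPAD sessions far outside
    their treatment x date group.

    The unit of contamination is a whole measurement session (all nine leaves
    of one tree on one date, emulating e.g. a mis-read or damaged crown), so
    the displacement survives leaf averaging.  Displacements are constructed
    in chlorophyll space -- the space the cleaning rule operates in -- by
    moving the session's mean 5-7 interquartile ranges beyond its treatment x
    date group's quartiles (comfortably past the >= 3x IQR displacement
    contract), then mapping back to SPAD.  Sessions where no such target fits
    the attainable chlorophyll range (mid-decline dates, where the group
    spread rivals the whole range) are left untouched: a clipped displacement
    would break the contract that makes the labels usable as cleaning ground
    truth.  Labels of the injected sessions are returned for
    sensitivity/specificity tests.
    """
    if not 0.0 <= config.outlier_rate <= 1.0:
        raise ValueError("outlier_rate must be in [0, 1]")
    labels = pd.DataFrame(columns=["tree_id", "doy"])
    if config.outlier_rate == 0.0 or spad_df.empty:
        return spad_df.copy(), labels
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    from .phenometrics import CHL_MIN, spad_to_chl

    out = spad_df.copy().reset_index(drop=True)
    treatment = trees.set_index("tree_id")["treatment_id"]
    out["_treatment"] = out["tree_id"].map(treatment)
    out["_chl"] = spad_to_chl(out["spad"].to_numpy())
    chl_means = out.groupby(["_treatment", "doy", "tree_id"])["_chl"].mean()
    spad_means = out.groupby(["_treatment", "doy", "tree_id"])["spad"].mean()
    label_rows = []
    sessions = out.groupby(["tree_id", "doy"], sort=True).indices
    for (tree_id, doy), idx in sessions.items():
        if rng.random() >= config.outlier_rate:
            continue
        if int(doy) in config.anomalous_spad_doys:
            continue  # that date carries its own (date-excluded) artifact
        trt = treatment[tree_id]
        group_vals = chl_means.loc[trt, doy].to_numpy()
        q1, q3 = np.percentile(group_vals, [25.0, 75.0])
        scale = max(q3 - q1, 1.0)  # ug/g
        u = rng.uniform(5.0, 7.0)
        target_down = q1 - u * scale
        target_up = q3 + u * scale
        if target_down >= CHL_MIN + 0.5:
            target = target_down  # damaged/browning leaves read low
        elif target_up <= CHL_MAX - 0.5:
            target = target_up
        else:
            continue  # no detectable displacement fits the attainable range
        offset = chl_to_spad(target) - float(spad_means.loc[trt, doy, tree_id])
        out.loc[idx, "spad"] = np.clip(out.loc[idx, "spad"] + offset, 0.0, 100.0)
        label_rows.append(dict(tree_id=tree_id, doy=float(doy)))
    out = out.drop(columns="_chl")
    out = out.drop(columns="_treatment")
    if label_rows:
        labels = pd.DataFrame(label_rows)
    return out, labels


def simulate_dataset(config: SimConfig) -> dict[str, pd.DataFrame]:
    """Full synthetic dataset: trees, truth, bud and SPAD measurements and
    outlier labels, deterministically from ``config.seed``."""
    config.validate()
    trees, truth = simulate_population(config)
    rng = np.random.default_rng(config.seed + 10_000)
    bud = generate_bud_measurements(trees, truth, config, rng)
    spad = generate_spad_measurements(trees, truth, config, rng)
    spad, outliers = inject_outliers(spad, trees, config, rng)
    return {"trees": trees, "truth": truth, "bud_measurements": bud,
            "spad_measurements": spad, "outlier_labels": outliers}
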