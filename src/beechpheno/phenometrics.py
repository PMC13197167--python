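"""Phenological event extraction from longitudinal measurement series.

Bud set is the date a bud first reaches 90% of its own maximum measured
length; leaf senescence is the date tree-level chlorophyll *last* falls below
50% of its observed peak.  Both dates are located on the linearly interpolated
trajectory of the raw measurements -- no smoothing, no extrapolation.  SPAD
meter readings are converted to total chlorophyll (ug/g fresh weight) with an
empirical quadratic calibration for Fagus sylvatica leaves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import BUD_TYPES

#: Bud set threshold as a fraction of a bud's own maximum measured length.
BUDSET_FRACTION = 0.9
#: Senescence threshold as a fraction of the observed peak chlorophyll.
SENESCENCE_FRACTION = 0.5

#: Chl = a*SPAD^2 + b*SPAD + c  (ug/g fresh weight), beech-leaf calibration.
CHL_A, CHL_B, CHL_C = -0.0029, 1.175, 3.8506

SPAD_MIN, SPAD_MAX = 0.0, 100.0
#: Chlorophyll range attainable on the increasing branch of the calibration
#: with SPAD in [0, 100].
CHL_MIN = CHL_C
CHL_MAX = CHL_A * SPAD_MAX**2 + CHL_B * SPAD_MAX + CHL_C  # 92.3506

LEAF_POSITIONS = ("top", "middle", "bottom")
AGGREGATION_ORDERS = ("convert_then_mean", "mean_then_convert")


def spad_to_chl(spad):
    """Convert SPAD readings to total chlorophyll (ug/g fresh weight).

    The calibration is strictly increasing on [0, 100] (its derivative
    1.175 - 0.0058*SPAD stays positive up to SPAD ~ 202.6); readings outside
    the meter's [0, 100] range are a domain error.
    """
    arr = np.asarray(spad, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr < SPAD_MIN) or np.any(arr > SPAD_MAX):
        raise ValueError(f"SPAD outside [{SPAD_MIN}, {SPAD_MAX}]")
    out = CHL_A * arr**2 + CHL_B * arr + CHL_C
    return float(out) if np.isscalar(spad) else out


def chl_to_spad(chl):
    """Invert the calibration on its increasing branch (SPAD in [0, 100]).

    Of the quadratic's two roots the smaller one lies where the conversion is
    increasing; chlorophyll outside [3.8506, 92.3506] has no SPAD preimage in
    the meter range and raises ``ValueError``.
    """
    arr = np.asarray(chl, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr < CHL_MIN - 1e-12) or np.any(
        arr > CHL_MAX + 1e-12
    ):
        raise ValueError(
            f"chlorophyll not attainable for SPAD in [0, 100]: "
            f"valid range is [{CHL_MIN}, {CHL_MAX:.4f}] ug/g"
        )
    disc = CHL_B**2 - 4.0 * CHL_A * (CHL_C - arr)
    out = (-CHL_B + np.sqrt(disc)) / (2.0 * CHL_A)
    out = np.clip(out, SPAD_MIN, SPAD_MAX)
    return float(out) if np.isscalar(chl) else out


def linear_interpolate(doys, values, doy):
    """Piecewise-linear interpolation, exact at knots; extrapolation is an error."""
    doys = np.asarray(doys, dtype=float)
    values = np.asarray(values, dtype=float)
    q = np.asarray(doy, dtype=float)
    if np.any(q < doys[0]) or np.any(q > doys[-1]):
        raise ValueError(
            f"doy outside observation span [{doys[0]}, {doys[-1]}]: extrapolation refused"
        )
    out = np.interp(q, doys, values)
    return float(out) if np.isscalar(doy) else out


def _check_series(doys, values, min_obs=2):
    doys = np.asarray(doys, dtype=float)
    values = np.asarray(values, dtype=float)
    if doys.ndim != 1 or doys.shape != values.shape:
        raise ValueError("doys and values must be 1-d arrays of equal length")
    if len(doys) < min_obs:
        raise ValueError(f"need at least {min_obs} observations, got {len(doys)}")
    if np.any(np.diff(doys) <= 0):
        raise ValueError("observation days must be strictly increasing")
    if np.any(~np.isfinite(values)):
        raise ValueError("values must be finite")
    return doys, values


@dataclass
class BudSeries:
    """Repeated length measurements (mm) of one tagged bud."""

    tree_id: str
    bud_type: str
    doy: np.ndarray
    length_mm: np.ndarray

    def __post_init__(self):
        if self.bud_type not in BUD_TYPES:
            raise ValueError(f"bud_type must be one of {BUD_TYPES}")
        self.doy, self.length_mm = _check_series(self.doy, self.length_mm)
        if np.any(self.length_mm <= 0):
            raise ValueError("bud lengths must be positive")


@dataclass
class ChlSeries:
    """Tree-level chlorophyll trajectory (ug/g fresh weight)."""

    tree_id: str
    doy: np.ndarray
    chl: np.ndarray

    def __post_init__(self):
        self.doy, self.chl = _check_series(self.doy, self.chl)


@dataclass
class SpadSeries:
    """Leaf-level SPAD readings of one tree (nine leaves per date)."""

    tree_id: str
    doy: np.ndarray
    leaf_position: np.ndarray
    spad: np.ndarray

    def __post_init__(self):
        self.doy = np.asarray(self.doy, dtype=float)
        self.leaf_position = np.asarray(self.leaf_position)
        self.spad = np.asarray(self.spad, dtype=float)
        if not (len(self.doy) == len(self.leaf_position) == len(self.spad)):
            raise ValueError("doy, leaf_position and spad must align")
        if np.any(self.spad < SPAD_MIN) or np.any(self.spad > SPAD_MAX):
            raise ValueError("SPAD outside [0, 100]")


@dataclass
class PhenoEvent:
    """An extracted bud-set or senescence date with its threshold provenance.

    ``doy`` is a fractional 1-based calendar day-of-year, or ``None`` for a
    right-censored trajectory (threshold never crossed).
    """

    tree_id: str
    event: str  # "bud_set" | "senescence"
    doy: float | None
    threshold_value: float
    censoring_flag: str = "none"  # "none" | "left" | "right"
    bud_type: str | None = None


@dataclass
class GrowthMetrics:
    """Seasonal bud growth summaries.

    ``min_length`` is the first measured length; ``max_length`` is the first
    measured value strictly exceeding 90% of the final (last) measured length;
    absolute growth = max - min (mm); relative growth = (1 - min/max) * 100.
    """

    tree_id: str
    bud_type: str
    min_length: float
    max_length: float
    absolute: float
    relative: float


def _first_upward_crossing(doys, values, threshold):
    """Doy of the first interpolated upward crossing of ``threshold``.

    Returns ``(doy, flag)``; flag 'left' if the series starts at or above the
    threshold, ``(None, 'right')`` if the threshold is never reached.
    """
    if values[0] >= threshold:
        return float(doys[0]), "left"
    for i in range(len(doys) - 1):
        lo, hi = values[i], values[i + 1]
        if lo < threshold <= hi:
            frac = (threshold - lo) / (hi - lo)
            return float(doys[i] + frac * (doys[i + 1] - doys[i])), "none"
    return None, "right"


def _last_downward_crossing(doys, values, threshold):
    """Doy of the last interpolated downward crossing of ``threshold``.

    Returns ``(None, 'right')`` when the trajectory never falls below it.
    """
    crossing = None
    for i in range(len(doys) - 1):
        lo, hi = values[i], values[i + 1]
        if lo > threshold >= hi:
            frac = (lo - threshold) / (lo - hi)
            crossing = float(doys[i] + frac * (doys[i + 1] - doys[i]))
    if crossing is None:
        return None, "right"
    return crossing, "none"


def bud_set_doy(series: BudSeries) -> PhenoEvent:
    """Date the bud first reaches 90% of its own maximum measured length.

    A series that starts at or above the threshold (including the degenerate
    all-equal case, where max = min makes the crossing undefined) is
    left-censored at its first observation day.
    """
    threshold = BUDSET_FRACTION * float(np.max(series.length_mm))
    if np.max(series.length_mm) == np.min(series.length_mm):
        return PhenoEvent(
            series.tree_id, "bud_set", float(series.doy[0]), threshold,
            "left", series.bud_type,
        )
    doy, flag = _first_upward_crossing(series.doy, series.length_mm, threshold)
    # max >= threshold always, so an upward crossing (or left censoring) exists
    return PhenoEvent(series.tree_id, "bud_set", doy, threshold, flag, series.bud_type)


def senescence_doy(series: ChlSeries) -> PhenoEvent:
    """Date chlorophyll *last* falls below 50% of its observed peak.

    Taking the last downward crossing means transient dips (e.g. drought) do
    not trigger senescence.  A trajectory that never falls below the threshold
    is right-censored with no date.
    """
    threshold = SENESCENCE_FRACTION * float(np.max(series.chl))
    doy, flag = _last_downward_crossing(series.doy, series.chl, threshold)
    return PhenoEvent(series.tree_id, "senescence", doy, threshold, flag)


def growth_metrics(series: BudSeries) -> GrowthMetrics:
    """Absolute and relative seasonal bud growth.

    min length = first measured length; max length = the measured length when
    the bud first surpassed 90% of its final (last measured) length.  The last
    value always exceeds 90% of itself, so a qualifying measurement exists.
    """
    lengths = series.length_mm
    min_length = float(lengths[0])
    final = float(lengths[-1])
    above = np.nonzero(lengths > BUDSET_FRACTION * final)[0]
    max_length = float(lengths[above[0]])
    if max_length == 0:
        raise ValueError("max length is zero; relative growth undefined")
    absolute = max_length - min_length
    relative = (1.0 - min_length / max_length) * 100.0
    return GrowthMetrics(
        series.tree_id, series.bud_type, min_length, max_length, absolute, relative
    )


def aggregate_leaves(
    spad_df: pd.DataFrame, order: str = "convert_then_mean"
) -> pd.DataFrame:
    """Aggregate leaf-level SPAD to a tree-level chlorophyll trajectory.

    ``convert_then_mean`` (default) converts each leaf reading to chlorophyll
    and averages per tree per date; ``mean_then_convert`` averages SPAD first.
    Because the calibration is concave the two orders differ by a Jensen gap;
    the per-leaf conversion is the default since the calibration is a
    leaf-level relation.

    Parameters
    ----------
    spad_df : DataFrame with columns tree_id, doy, spad (leaf_position ignored).
    """
    if order not in AGGREGATION_ORDERS:
        raise ValueError(f"order must be one of {AGGREGATION_ORDERS}")
    if spad_df.empty:
        raise ValueError("no SPAD measurements to aggregate")
    df = spad_df.copy()
    if order == "convert_then_mean":
        df["chl"] = spad_to_chl(df["spad"].to_numpy())
        out = df.groupby(["tree_id", "doy"], as_index=False)["chl"].mean()
    else:
        out = df.groupby(["tree_id", "doy"], as_index=False)["spad"].mean()
        out["chl"] = spad_to_chl(out.pop("spad").to_numpy())
    return out.sort_values(["tree_id", "doy"], ignore_index=True)


def extract_bud_events(bud_df: pd.DataFrame) -> pd.DataFrame:
    """Bud-set dates for every (tree, bud type) series in a measurement table.

    Expects columns tree_id, bud_type, doy, length_mm; returns the events
    table (tree_id, bud_type, event, doy, threshold_value, censoring_flag).
    """
    rows = []
    for (tree_id, bud_type), grp in bud_df.groupby(["tree_id", "bud_type"], sort=True):
        grp = grp.sort_values("doy")
        series = BudSeries(
            str(tree_id), str(bud_type),
            grp["doy"].to_numpy(), grp["length_mm"].to_numpy(),
        )
        ev = bud_set_doy(series)
        rows.append(
            dict(tree_id=ev.tree_id, bud_type=ev.bud_type, event=ev.event,
                 doy=ev.doy, threshold_value=ev.threshold_value,
                 censoring_flag=ev.censoring_flag)
        )
    return pd.DataFrame(rows)


def extract_senescence_events(chl_df: pd.DataFrame) -> pd.DataFrame:
    """Senescence dates for every tree-level chlorophyll trajectory."""
    rows = []
    for tree_id, grp in chl_df.groupby("tree_id", sort=True):
        grp = grp.sort_values("doy")
        if len(grp) < 2:
            continue
        series = ChlSeries(str(tree_id), grp["doy"].to_numpy(), grp["chl"].to_numpy())
        ev = senescence_doy(series)
        rows.append(
            dict(tree_id=ev.tree_id, bud_type=None, event=ev.event, doy=ev.doy,
                 threshold_value=ev.threshold_value, censoring_flag=ev.censoring_flag)
        )
    return pd.DataFrame(rows)


def extract_growth_metrics(bud_df: pd.DataFrame) -> pd.DataFrame:
    """Growth summaries for every (tree, bud type) series."""
    rows = []
    for (tree_id, bud_type), grp in bud_df.groupby(["tree_id", "bud_type"], sort=True):
        grp = grp.sort_values("doy")
        series = BudSeries(
            str(tree_id), str(bud_type),
            grp["doy"].to_numpy(), grp["length_mm"].to_numpy(),
        )
        gm = growth_metrics(series)
        rows.append(
            dict(tree_id=gm.tree_id, bud_type=gm.bud_type, min_length=gm.min_length,
                 max_length=gm.max_length, absolute_mm=gm.absolute,
                 relative_pct=gm.relative)
        )
    return pd.DataFrame(rows)
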