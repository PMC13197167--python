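"""Chlorophyll data cleaning applied before senescence extraction.

Three rules, applied in order: (1) drop whole measurement dates known to be
unreliable (in the study, 7 December = day 341, where readings were
unreasonably high); (2) within each treatment x measurement-date group, remove
values beyond the Tukey fences (more than 1.5x the interquartile range below
the lower or above the upper quartile); (3) completely drop any tree that lost
more than one data point to rule (2).  Bud-length series receive no cleaning.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

FLAG_COLUMNS = ["tree_id", "doy", "reason", "group_key"]

#: Day-of-year of 7 December in a non-leap year.
DEFAULT_EXCLUDED_DOYS = (341,)

IQR_FACTOR = 1.5
#: Minimum group size for quartiles to be meaningful; smaller groups pass.
MIN_GROUP_SIZE = 4


def _empty_flags() -> pd.DataFrame:
    return pd.DataFrame(columns=FLAG_COLUMNS)


def drop_dates(df: pd.DataFrame, excluded_doys) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove all observations taken on the excluded days-of-year.

    Returns the filtered table and one ``excluded_date`` flag per removed row.
    """
    excluded = set(float(d) for d in excluded_doys)
    if not excluded or df.empty:
        return df.copy(), _empty_flags()
    mask = df["doy"].astype(float).isin(excluded)
    flags = pd.DataFrame(
        {
            "tree_id": df.loc[mask, "tree_id"].to_numpy(),
            "doy": df.loc[mask, "doy"].to_numpy(dtype=float),
            "reason": "excluded_date",
            "group_key": [f"doy={d:g}" for d in df.loc[mask, "doy"]],
        }
    )
    return df.loc[~mask].copy(), flags


def tukey_fences(values: np.ndarray, quartile_method: str = "linear"):
    """Lower and upper Tukey fences (Q1 - 1.5*IQR, Q3 + 1.5*IQR)."""
    q1, q3 = np.percentile(values, [25.0, 75.0], method=quartile_method)
    iqr = q3 - q1
    return q1 - IQR_FACTOR * iqr, q3 + IQR_FACTOR * iqr


def _iqr_flag_positions(
    values: np.ndarray, quartile_method: str, iterate: bool
) -> np.ndarray:
    """Positions of values beyond their group's Tukey fences.

    The default single pass is the study's procedure.  With ``iterate`` the
    fences are recomputed on the surviving values until nothing new is
    flagged, which makes the filter idempotent (a second application removes
    nothing) at the cost of removing noticeably more of the heavy-tailed
    mid-decline cross-sections.
    """
    flagged = np.zeros(len(values), dtype=bool)
    while (~flagged).sum() >= MIN_GROUP_SIZE:
        keep = ~flagged
        lo, hi = tukey_fences(values[keep], quartile_method)
        bad = keep & ((values < lo) | (values > hi))
        if not bad.any():
            break
        flagged |= bad
        if not iterate:
            break
    return np.nonzero(flagged)[0]


def iqr_filter(
    df: pd.DataFrame,
    value_col: str,
    group_cols=("treatment_id", "doy"),
    quartile_method: str = "linear",
    iterate: bool = False,
) -> pd.DataFrame:
    """Flag values beyond the Tukey fences of their treatment x date group.

    Quartiles use linear interpolation between order statistics (numpy's
    default, R type 7) unless another ``quartile_method`` is configured.
    Groups smaller than four values pass untouched (logged).
    """
    flags = []
    for key, grp in df.groupby(list(group_cols), sort=True):
        vals = grp[value_col].to_numpy(dtype=float)
        key_str = ":".join(str(k) for k in (key if isinstance(key, tuple) else (key,)))
        if len(vals) < MIN_GROUP_SIZE:
            log.info("iqr_filter: group %s has n=%d < %d, skipped",
                     key_str, len(vals), MIN_GROUP_SIZE)
            continue
        for idx in _iqr_flag_positions(vals, quartile_method, iterate):
            row = grp.iloc[int(idx)]
            flags.append(
                dict(tree_id=row["tree_id"], doy=float(row["doy"]),
                     reason="iqr_outlier", group_key=key_str)
            )
    out = pd.DataFrame(flags, columns=FLAG_COLUMNS)
    return out


def drop_trees(flags: pd.DataFrame, max_removed: int = 1) -> list[str]:
    """Trees whose ``iqr_outlier`` flag count exceeds ``max_removed``.

    The study rule: a tree with *more than one* data point removed by the IQR
    filter is excluded entirely from senescence extraction.
    """
    if flags.empty:
        return []
    counts = (
        flags.loc[flags["reason"] == "iqr_outlier"].groupby("tree_id").size()
    )
    return sorted(counts.index[counts > max_removed].tolist())


def run_qc_chain(
    spad_df: pd.DataFrame,
    trees_df: pd.DataFrame,
    excluded_doys=DEFAULT_EXCLUDED_DOYS,
    aggregation_order: str = "convert_then_mean",
    level: str = "tree",
    quartile_method: str = "linear",
    max_removed: int = 1,
    iqr_iterate: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full cleaning chain for SPAD data, returning (clean chl table, flags).

    Order of operations: drop excluded dates -> aggregate leaves to tree-level
    chlorophyll -> IQR filter within treatment x date -> drop trees with more
    than ``max_removed`` flagged points.  With ``level='leaf'`` the IQR filter
    instead runs on leaf-level converted chlorophyll before aggregation (the
    study's wording, "individual chlorophyll measurements", is read as
    per-individual-tree by default, but both readings are supported).
    """
    from .phenometrics import aggregate_leaves, spad_to_chl

    if level not in ("tree", "leaf"):
        raise ValueError("level must be 'tree' or 'leaf'")

    kept, date_flags = drop_dates(spad_df, excluded_doys)
    treatment = trees_df.set_index("tree_id")["treatment_id"]

    if level == "tree":
        chl = aggregate_leaves(kept, order=aggregation_order)
        chl["treatment_id"] = chl["tree_id"].map(treatment)
        iqr_flags = iqr_filter(chl, "chl", ("treatment_id", "doy"), quartile_method,
                               iterate=iqr_iterate)
        dropped = drop_trees(iqr_flags, max_removed)
        removed = set(zip(iqr_flags["tree_id"], iqr_flags["doy"]))
        keep_mask = [
            (t not in dropped) and ((t, d) not in removed)
            for t, d in zip(chl["tree_id"], chl["doy"])
        ]
        clean = chl.loc[keep_mask, ["tree_id", "doy", "chl"]].reset_index(drop=True)
    else:
        leaf = kept.reset_index(drop=True).copy()
        leaf["chl"] = spad_to_chl(leaf["spad"].to_numpy())
        leaf["treatment_id"] = leaf["tree_id"].map(treatment)
        bad_mask = np.zeros(len(leaf), dtype=bool)
        for _, grp in leaf.groupby(["treatment_id", "doy"], sort=True):
            vals = grp["chl"].to_numpy(dtype=float)
            if len(vals) < MIN_GROUP_SIZE:
                continue
            pos = _iqr_flag_positions(vals, quartile_method, iqr_iterate)
            bad_mask[grp.index[pos]] = True
        iqr_flags = pd.DataFrame(
            {
                "tree_id": leaf.loc[bad_mask, "tree_id"].to_numpy(),
                "doy": leaf.loc[bad_mask, "doy"].to_numpy(dtype=float),
                "reason": "iqr_outlier",
                "group_key": [
                    f"{t}:{d:g}"
                    for t, d in zip(leaf.loc[bad_mask, "treatment_id"],
                                    leaf.loc[bad_mask, "doy"])
                ],
            },
            columns=FLAG_COLUMNS,
        )
        dropped = drop_trees(iqr_flags, max_removed)
        keep = ~bad_mask & ~leaf["tree_id"].isin(dropped).to_numpy()
        clean = aggregate_leaves(
            leaf.loc[keep, ["tree_id", "doy", "spad"]], order=aggregation_order
        )

    tree_flags = pd.DataFrame(
        [dict(tree_id=t, doy=np.nan, reason="tree_dropped", group_key="")
         for t in dropped],
        columns=FLAG_COLUMNS,
    )
    flags = pd.concat([date_flags, iqr_flags, tree_flags], ignore_index=True)
    log.info(
        "QC: %d date-excluded rows, %d IQR outliers, %d trees dropped",
        len(date_flags), len(iqr_flags), len(tree_flags),
    )
    return clean, flags
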