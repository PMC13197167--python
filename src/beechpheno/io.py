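"""CSV schemas shared by every pipeline stage.

All tables are UTF-8 CSVs with mandatory headers and '.' decimals, so real
deposited data can replace simulated data at any stage boundary.  Validation
errors name the offending file rows (1-based, counting the header as line 1).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """An input table violates its schema; the message names the rows."""


SCHEMAS = {
    "trees": ["tree_id", "experiment", "treatment_id", "leafing_group",
              "leaf_out_doy", "block"],
    "bud_measurements": ["tree_id", "bud_type", "doy", "length_mm"],
    "spad_measurements": ["tree_id", "leaf_position", "doy", "spad"],
    "truth": ["tree_id", "bud_type", "true_budset_doy", "true_senescence_doy"],
    "outlier_labels": ["tree_id", "doy"],
    "events": ["tree_id", "bud_type", "event", "doy", "threshold_value",
               "censoring_flag"],
    "growth_metrics": ["tree_id", "bud_type", "min_length", "max_length",
                       "absolute_mm", "relative_pct"],
    "qc_flags": ["tree_id", "doy", "reason", "group_key"],
    "effects": ["contrast_label", "response", "estimate", "advance", "se",
                "ci_low", "ci_high", "p_value", "n_treated", "n_control"],
}


def _rows(mask) -> str:
    """File line numbers (header = line 1) of the offending rows."""
    idx = np.nonzero(np.asarray(mask))[0] + 2
    shown = ", ".join(map(str, idx[:10]))
    more = f" (+{len(idx) - 10} more)" if len(idx) > 10 else ""
    return shown + more


def _require_columns(df: pd.DataFrame, table: str, path) -> None:
    missing = [c for c in SCHEMAS[table] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")


def read_table(path, table: str) -> pd.DataFrame:
    """Read and validate one of the pipeline's CSV tables."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, table, path)
    if table == "bud_measurements":
        bad = ~(pd.to_numeric(df["length_mm"], errors="coerce") > 0)
        if bad.any():
            raise SchemaError(
                f"{path}: non-positive or non-numeric length_mm at rows {_rows(bad)}"
            )
    if table == "spad_measurements":
        vals = pd.to_numeric(df["spad"], errors="coerce")
        bad = ~((vals >= 0) & (vals <= 100))
        if bad.any():
            raise SchemaError(f"{path}: SPAD outside [0, 100] at rows {_rows(bad)}")
    if table == "trees":
        bad = ~df["experiment"].isin([1, 2])
        if bad.any():
            raise SchemaError(f"{path}: experiment must be 1 or 2 at rows {_rows(bad)}")
        if df["tree_id"].duplicated().any():
            dup = df["tree_id"].duplicated()
            raise SchemaError(f"{path}: duplicate tree_id at rows {_rows(dup)}")
    if table in ("bud_measurements", "spad_measurements"):
        bad = pd.to_numeric(df["doy"], errors="coerce").isna()
        if bad.any():
            raise SchemaError(f"{path}: non-numeric doy at rows {_rows(bad)}")
    return df


def write_table(df: pd.DataFrame, path, table: str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = [c for c in SCHEMAS[table] if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    df.to_csv(path, index=False, columns=cols + extra)
    return path
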