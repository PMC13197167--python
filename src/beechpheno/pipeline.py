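"""Orchestration: simulate -> extract -> qc -> analyze -> report.

Every stage reads and writes the CSV contracts in :mod:`beechpheno.io`, so
real deposited data can replace simulated data at any boundary.  The full run
is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import design, inference, io, qc
from .phenometrics import (
    extract_bud_events,
    extract_growth_metrics,
    extract_senescence_events,
)
from .simulate import SimConfig, simulate_dataset

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline options.  Exactly one of ``simulate``/``input_dir`` is active."""

    output_dir: Path
    simulate: bool = True
    sim_config: SimConfig = field(default_factory=SimConfig)
    input_dir: Path | None = None
    excluded_doys: tuple = qc.DEFAULT_EXCLUDED_DOYS
    aggregation_order: str = "convert_then_mean"
    qc_level: str = "tree"
    quartile_method: str = "linear"
    pool_controls: str = "auto"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.simulate == (self.input_dir is not None):
            raise ValueError("exactly one of simulate / input_dir must be active")


@dataclass
class RunReport:
    output_dir: Path
    n_trees: dict
    n_events: dict
    n_censored: dict
    qc_counts: dict
    effects: pd.DataFrame
    leafing: dict
    slopes: dict
    control_anova: dict
    varpart: dict
    icc: dict
    coupling: dict


def _load_inputs(cfg: RunConfig):
    if cfg.simulate:
        sim = SimConfig(**{**asdict_simconfig(cfg.sim_config), "seed": cfg.seed})
        data = simulate_dataset(sim)
        out = Path(cfg.output_dir)
        for name in ("trees", "truth", "bud_measurements", "spad_measurements",
                     "outlier_labels"):
            io.write_table(data[name], out / f"{name}.csv", _table_of(name))
        return data["trees"], data["bud_measurements"], data["spad_measurements"]
    indir = Path(cfg.input_dir)
    trees = io.read_table(indir / "trees.csv", "trees")
    bud = io.read_table(indir / "bud_measurements.csv", "bud_measurements")
    spad = io.read_table(indir / "spad_measurements.csv", "spad_measurements")
    return trees, bud, spad


def _table_of(name: str) -> str:
    return name if name in io.SCHEMAS else "truth"


def asdict_simconfig(sim: SimConfig) -> dict:
    d = asdict(sim)
    return d


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Run every stage and write all outputs plus ``report.md``."""
    cfg.validate()
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    trees, bud, spad = _load_inputs(cfg)

    # --- extraction -------------------------------------------------------
    bud_events = extract_bud_events(bud)
    growth = extract_growth_metrics(bud)

    # --- chlorophyll QC then senescence extraction ------------------------
    chl, flags = qc.run_qc_chain(
        spad, trees, excluded_doys=cfg.excluded_doys,
        aggregation_order=cfg.aggregation_order, level=cfg.qc_level,
        quartile_method=cfg.quartile_method,
    )
    sen_events = extract_senescence_events(chl)
    events = pd.concat([bud_events, sen_events], ignore_index=True)

    io.write_table(events, out / "events.csv", "events")
    io.write_table(growth, out / "growth_metrics.csv", "growth_metrics")
    io.write_table(flags, out / "qc_flags.csv", "qc_flags")

    # --- inference ---------------------------------------------------------
    effects = []
    for experiment in (1, 2):
        for response in ("bud_set", "senescence"):
            effects.extend(inference.fit_treatment_model(
                events, trees, response, experiment, pool_controls=cfg.pool_controls,
            ))
    effects_df = inference.effects_to_frame(effects)
    io.write_table(effects_df, out / "effects.csv", "effects")

    leafing = {
        r: inference.fit_leafing_contrast(events, trees, r)
        for r in ("bud_set", "senescence")
    }
    slopes = {
        r: inference.fit_mixed_sensitivity(events, trees, r, experiment=1)
        for r in ("bud_set", "senescence")
    }
    control_anova = {
        r: inference.anova_controls(events, trees, design.EXP2_CONTROL_GROUPS, r)
        for r in ("bud_set", "senescence")
    }

    exp1_bud = inference._merge_meta(
        inference._usable(events, "bud_set"), trees)
    exp1_bud = exp1_bud.loc[exp1_bud["experiment"] == 1]
    varpart = inference.variance_partition(
        exp1_bud, "doy",
        {"leafout": ["leaf_out_doy"], "treatment": ["C(cooling)"],
         "bud_type": ["C(bud_type)"]},
    )
    icc_res = inference.icc(exp1_bud["doy"], exp1_bud["treatment_id"])

    bud_emms = {e: inference.treatment_emms(events, trees, "bud_set", e)
                for e in (1, 2)}
    sen_emms = {e: inference.treatment_emms(events, trees, "senescence", e)
                for e in (1, 2)}
    coupling = inference.emm_coupling(bud_emms, sen_emms)

    # --- summaries ---------------------------------------------------------
    n_trees = trees.groupby("treatment_id")["tree_id"].nunique().to_dict()
    n_events = events.groupby("event")["doy"].count().to_dict()
    n_censored = (
        events.loc[events["censoring_flag"] != "none"]
        .groupby(["event", "censoring_flag"]).size().to_dict()
    )
    qc_counts = flags.groupby("reason").size().to_dict()

    report = RunReport(
        output_dir=out,
        n_trees=n_trees,
        n_events={k: int(v) for k, v in n_events.items()},
        n_censored={f"{a}/{b}": int(v) for (a, b), v in n_censored.items()},
        qc_counts={k: int(v) for k, v in qc_counts.items()},
        effects=effects_df,
        leafing={r: vars_of(e) for r, e in leafing.items()},
        slopes={r: dict(slope=s.slope, se=s.se, p_value=s.p_value,
                        random_effect_variance=s.random_effect_variance,
                        method=s.method) for r, s in slopes.items()},
        control_anova={r: dict(F=a.F, df1=a.df1, df2=a.df2, p_value=a.p_value)
                       for r, a in control_anova.items()},
        varpart=dict(unique=varpart.unique_fractions,
                     shared=varpart.shared_fractions,
                     residual=varpart.residual_fraction,
                     total_adjusted_r2=varpart.total_adjusted_r2),
        icc=dict(v_between=icc_res.v_between, v_within=icc_res.v_within,
                 icc=icc_res.icc),
        coupling=dict(n_pairs=coupling.n_pairs, n_agree=coupling.n_agree,
                      fraction_agree=coupling.fraction_agree,
                      adjusted_r2=coupling.adjusted_r2),
    )

    for name in ("varpart", "icc", "coupling"):
        with open(out / f"{name}.json", "w") as fh:
            json.dump(getattr(report, name), fh, indent=2, sort_keys=True)
    (out / "report.md").write_text(render_report(report))
    return report


def vars_of(e: inference.EffectEstimate) -> dict:
    return dict(estimate=e.estimate, se=e.se, ci_low=e.ci_low, ci_high=e.ci_high,
                p_value=e.p_value, n_treated=e.n_treated, n_control=e.n_control)


def render_report(r: RunReport) -> str:
    """Deterministic markdown summary of one pipeline run."""
    lines = ["# Pipeline report", ""]
    lines += ["## Trees per treatment", ""]
    for k in sorted(r.n_trees):
        lines.append(f"- {k}: {r.n_trees[k]}")
    lines += ["", "## Events", ""]
    for k in sorted(r.n_events):
        lines.append(f"- {k}: {r.n_events[k]} dated")
    for k in sorted(r.n_censored):
        lines.append(f"- censored {k}: {r.n_censored[k]}")
    lines += ["", "## QC removals", ""]
    for k in sorted(r.qc_counts):
        lines.append(f"- {k}: {r.qc_counts[k]}")
    lines += ["", "## Treatment effects (days; estimate > 0 = delay)", ""]
    lines.append(r.effects.round(4).to_string(index=False))
    lines += ["", "## Leafing-group contrast (experiment 1)", ""]
    for resp, d in r.leafing.items():
        lines.append(
            f"- {resp}: {d['estimate']:+.2f} +/- {2 * d['se']:.2f} d (2 SE), "
            f"p = {d['p_value']:.3g}"
        )
    lines += ["", "## Leaf-out sensitivity (experiment 1)", ""]
    for resp, d in r.slopes.items():
        lines.append(
            f"- {resp}: {d['slope']:.3f} +/- {2 * d['se']:.3f} d/d (2 SE), "
            f"random-effect var {d['random_effect_variance']:.2f} [{d['method']}]"
        )
    lines += ["", "## Experiment-2 control ANOVA", ""]
    for resp, d in r.control_anova.items():
        lines.append(
            f"- {resp}: F({d['df1']},{d['df2']}) = {d['F']:.3f}, p = {d['p_value']:.3f}"
        )
    lines += ["", "## Variance partitioning of bud set (experiment 1)", ""]
    for k, v in sorted(r.varpart["unique"].items()):
        lines.append(f"- unique {k}: {100 * v:.1f}%")
    for k, v in sorted(r.varpart["shared"].items()):
        lines.append(f"- shared {k}: {100 * v:.1f}%")
    lines.append(f"- residual: {100 * r.varpart['residual']:.1f}%")
    lines += ["", "## ICC of bud set over treatments (experiment 1)", ""]
    lines.append(
        f"- V_T = {r.icc['v_between']:.2f} d^2, V_W = {r.icc['v_within']:.2f} d^2, "
        f"ICC = {r.icc['icc']:.3f}"
    )
    lines += ["", "## Bud-leaf coupling", ""]
    c = r.coupling
    lines.append(
        f"- {c['n_agree']}/{c['n_pairs']} pairwise EMM comparisons agree in "
        f"direction ({100 * c['fraction_agree']:.0f}%), adjusted R^2 = "
        f"{c['adjusted_r2']:.2f}"
    )
    return "\n".join(lines) + "\n"
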