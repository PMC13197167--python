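"""Experimental designs of the two beech cooling experiments.

Experiment 1 (2023, n = 267): two leafing groups -- "early" (ambient spring)
and "late" (spring development arrested by chamber cooling, 2/7 degC night/day,
4 April to 24 May) -- crossed with five summer cooling regimes: ambient
control, July moderate (8-13 degC), July extreme (2-7 degC), August moderate,
August extreme.  Ten treatment groups of 26-27 trees.

Experiment 2 (2022, n = 180): one ambient control of 36 trees plus eight
chamber treatments of 18 trees each: {pre-, post-solstice} x {chamber control
(20/20 degC), day cooling (8/20), night cooling (20/8), full-day cooling
(8/8)}.
"""

from __future__ import annotations

LEAFING_GROUPS = ("early", "late")
BUD_TYPES = ("apical", "lateral")

EXP1_COOLINGS = (
    "control",
    "july_moderate",
    "july_extreme",
    "august_moderate",
    "august_extreme",
)

#: Treatment groups of experiment 1 in the numbering of the design table
#: (1 = early control, 2 = late control, ..., 10 = late August-extreme).
EXP1_TREATMENTS = tuple(
    f"{cooling}_{group}" for cooling in EXP1_COOLINGS for group in LEAFING_GROUPS
)

EXP2_TREATMENTS = (
    "ambient_control",
    "pre_chamber_control",
    "pre_day",
    "pre_night",
    "pre_full_day",
    "post_chamber_control",
    "post_day",
    "post_night",
    "post_full_day",
)

#: The three experiment-2 groups that saw no cooling; pooled into a single
#: 72-tree control when a one-way ANOVA finds no difference between them.
EXP2_CONTROL_GROUPS = (
    "ambient_control",
    "pre_chamber_control",
    "post_chamber_control",
)

POOLED_CONTROL_LABEL = "control"


def cooling_of(treatment: str) -> str:
    """Summer cooling regime of an experiment-1 treatment label."""
    for group in LEAFING_GROUPS:
        suffix = f"_{group}"
        if treatment.endswith(suffix):
            return treatment[: -len(suffix)]
    raise ValueError(f"not an experiment-1 treatment label: {treatment!r}")


def leafing_of(treatment: str) -> str:
    """Leafing group (early/late) of an experiment-1 treatment label."""
    for group in LEAFING_GROUPS:
        if treatment.endswith(f"_{group}"):
            return group
    raise ValueError(f"not an experiment-1 treatment label: {treatment!r}")


def exp1_group_sizes(n_trees: int) -> dict[str, int]:
    """Split ``n_trees`` over the ten experiment-1 groups as evenly as possible.

    For the study population of 267 this yields seven groups of 27 and three
    of 26 (26 <= n <= 27 per group).
    """
    k = len(EXP1_TREATMENTS)
    base, extra = divmod(n_trees, k)
    if base < 2:
        raise ValueError(f"too few trees for {k} groups: {n_trees}")
    return {
        t: base + (1 if i < extra else 0) for i, t in enumerate(EXP1_TREATMENTS)
    }


def exp2_group_sizes(n_trees: int) -> dict[str, int]:
    """Split ``n_trees`` into one ambient control (1/5 of trees) and eight
    equal chamber groups.  For the study population of 180: 36 + 8 x 18."""
    n_ambient = n_trees // 5
    rest, extra = divmod(n_trees - n_ambient, 8)
    if rest < 2 or n_ambient < 2:
        raise ValueError(f"too few trees for the experiment-2 design: {n_trees}")
    sizes = {"ambient_control": n_ambient}
    chamber = [t for t in EXP2_TREATMENTS if t != "ambient_control"]
    for i, t in enumerate(chamber):
        sizes[t] = rest + (1 if i < extra else 0)
    return sizes
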