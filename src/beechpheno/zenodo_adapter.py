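"""Adapter stub for the study's deposited data (Zenodo 10.5281/zenodo.19368812).

The deposit's internal file layout is unknown until downloaded, so this module
documents the intended mapping only: a thin renaming/reshaping layer from the
deposit's column names to the internal CSV schemas of :mod:`beechpheno.io`
(trees, bud_measurements, spad_measurements).  Once the deposit is inspected,
``load_deposit`` should:

1. read the deposit's tree metadata and rename its identifier, experiment,
   treatment, leafing-group and leaf-out columns to the ``trees`` schema
   (treatment labels mapped onto :data:`beechpheno.design.EXP1_TREATMENTS` /
   ``EXP2_TREATMENTS``);
2. melt its bud-length table to long format (tree_id, bud_type, doy,
   length_mm), converting calendar dates to 1-based day-of-year;
3. melt its SPAD table to (tree_id, leaf_position, doy, spad).

No computation belongs here; every downstream stage then runs unchanged on
the real data.
"""

from __future__ import annotations

from pathlib import Path

ZENODO_DOI = "10.5281/zenodo.19368812"


def load_deposit(path: str | Path):
    """Map the Zenodo deposit at ``path`` onto the internal CSV schemas.

    Not implemented: requires inspecting the deposit's file layout.
    """
    raise NotImplementedError(
        f"adapter for Zenodo deposit {ZENODO_DOI} requires the downloaded "
        "deposit; see module docstring for the intended mapping"
    )
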