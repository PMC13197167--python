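#!/usr/bin/env python
"""Clean the SPAD data and extract leaf-senescence dates.

Applies the cleaning chain (drop 7-December readings, convert SPAD to
chlorophyll and average the nine leaves per tree, remove values beyond the
1.5 x IQR fences of their treatment x date group, drop trees losing more than
one value), then extracts each tree's last downward crossing of 50% of peak
chlorophyll.
"""

import argparse
from pathlib import Path

from beechpheno import io
from beechpheno.phenometrics import extract_senescence_events
from beechpheno.qc import run_qc_chain


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in", dest="indir", type=Path, default=Path("results/sim"))
    ap.add_argument("--out", type=Path, default=Path("results/qc"))
    args = ap.parse_args()

    trees = io.read_table(args.indir / "trees.csv", "trees")
    spad = io.read_table(args.indir / "spad_measurements.csv", "spad_measurements")
    chl, flags = run_qc_chain(spad, trees)
    events = extract_senescence_events(chl)
    io.write_table(events, args.out / "senescence_events.csv", "events")
    io.write_table(flags, args.out / "qc_flags.csv", "qc_flags")

    counts = flags.groupby("reason").size().to_dict()
    print(f"QC removals: {counts}")
    dated = events["censoring_flag"].eq("none").sum()
    print(f"{dated} dated senescence events "
          f"(median day-of-year {events['doy'].median():.1f})")
    print(f"tables written to {args.out}/")


if __name__ == "__main__":
    main()
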