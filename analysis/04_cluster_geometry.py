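#!/usr/bin/env python
"""Cluster spans and decorsin-to-hirudin gaps for all three assemblies.

All six published cluster "total length" values reproduce exactly from
the printed coordinates (max(end) - min(start) + 1).  The three
published gap figures are mutually inconsistent: the zheng figure
matches the nearest-envelope-edge distance, the guan figure matches the
Hman_DV1-to-Hman_TH distance, and the liu figure matches neither
convention; the report flags each.  Only the narrative range of about
120-140 kb is consistent across assemblies.
"""

from pathlib import Path

import pandas as pd

from hirusplice.cluster_geometry import table1_report
from hirusplice.gene_model import GENOME_SOURCES

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    frames = []
    for source in GENOME_SOURCES:
        frame = table1_report(source).to_frame()
        frame.insert(0, "source", source)
        frames.append(frame)
    df = pd.concat(frames, ignore_index=True)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "cluster_geometry.tsv", sep="\t", index=False)
    totals = df[df["item"] == "total length (bp)"]
    print(totals[["source", "section", "computed", "published", "agree"]].to_string(index=False))
    gaps = df[df.section == "gap"]
    print()
    print(gaps[["source", "item", "computed", "published", "agree"]].to_string(index=False))
    print(f"\nall spans agree: {totals.agree.all()}")
    print(f"wrote {OUT / 'cluster_geometry.tsv'}")


if __name__ == "__main__":
    main()
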