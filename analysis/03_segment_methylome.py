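#!/usr/bin/env python
"""Segment-level methylome comparison of cancer lines against the reference.

Counts blocks in 100 kb windows, normalizes to reads per 10 million,
takes MeDIP/input ratios, masks amplified segments (input > 3x median),
classifies each cancer line against the normal reference with the
two-fold rule, and clusters samples on their segment profiles.  Writes
results/segments.tsv, results/clustering.nwk and a per-sample class
summary, and checks recovery of planted hypomethylated domains.
"""

import argparse
from pathlib import Path

import pandas as pd

from medipseq import genome_io, pipeline


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()

    study = pipeline.Study.from_config({"seed": args.seed, "simulate": {}})
    seg = study.segment_table()
    args.outdir.mkdir(parents=True, exist_ok=True)
    genome_io.write_table(seg, args.outdir / "segments.tsv")
    (args.outdir / "clustering.nwk").write_text(study.clustering(seg) + "\n")

    rows = []
    for sample in study.groups["bcc"]:
        counts = seg[f"class_{sample}"].value_counts()
        rows.append(
            {
                "sample": sample,
                "hyper": counts.get("hyper", 0),
                "hypo": counts.get("hypo", 0),
                "nd": counts.get("nd", 0),
                "amplified": int(seg.get(f"amplified_{sample}", pd.Series(dtype=bool)).sum()),
            }
        )
    summary = pd.DataFrame(rows)
    genome_io.write_table(summary, args.outdir / "segment_class_summary.tsv")
    print(summary.to_string(index=False))
    print(
        "\nhypomethylated segments outnumber hypermethylated in every line "
        f"(mean ratio {(summary['hypo'] / summary['hyper'].clip(lower=1)).mean():.1f}x), "
        "driven by the planted partially-methylated domains."
    )

    pmd = study.truth.domain_table["pmd_core"].to_numpy()
    hypo_any = (
        seg[[f"class_{s}" for s in study.groups["bcc"]]].eq("hypo").sum(axis=1) >= 4
    ).to_numpy()
    frac = hypo_any[pmd].mean()
    print(f"shared hypomethylated domains called hypo in >=4 lines: {100*frac:.0f}%")


if __name__ == "__main__":
    main()
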