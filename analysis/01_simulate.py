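#!/usr/bin/env python
"""Generate the default synthetic MeDIP-seq study and write its inputs.

Produces a 2 x 5 Mb toy genome (CpG-depleted background, promoter and
intergenic CpG islands, ordinary and satellite-like repeats, 200 genes
with three gene-dense cluster loci per chromosome pair), one normal
reference, eight cancer lines (two without input libraries), an EMT
control/treated pair, expression for six cancer lines, and full ground
truth.  All files go to results/simulated_study/.
"""

import argparse
from pathlib import Path

from medipseq.simulate import SimulationConfig, simulate_study, write_study


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=Path("results/simulated_study"))
    args = parser.parse_args()

    config = SimulationConfig(seed=args.seed)
    study = simulate_study(config)
    paths = write_study(study, args.outdir)

    islands = study.truth.island_table
    print(f"genome: {study.genome.total_length/1e6:.1f} Mb, "
          f"{len(study.sim_genome.genes)} genes, {len(islands)} CpG islands")
    print("island categories:", islands["category"].value_counts().to_dict())
    print(f"CpG sites: {len(study.truth.cpg_sites)}")
    for sample, reads in study.medip_reads.items():
        print(f"  MeDIP {sample}: {len(reads)} reads")
    print(f"input libraries: {sorted(study.input_reads)}")
    print(f"wrote {len(paths)} files under {args.outdir}")


if __name__ == "__main__":
    main()
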