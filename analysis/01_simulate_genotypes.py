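#!/usr/bin/env python
"""Simulate one contact map per cohesin-cycle genotype, plus annotations.

Writes, under results/simdata/: a raw triplet contact map per genotype, the
shared chrom-sizes file, the CTCF-like site list (BED), the primary loop
list (BEDPE), and a ground-truth JSON per genotype.  All genotypes share the
same anchor layout so downstream comparisons see only the planted
architecture differences and count noise.
"""

import argparse
from pathlib import Path

from loopscreen import aggregates as ag
from loopscreen import matrixcore as mc
from loopscreen import simdata as sd


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/simdata"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    for name in sd.GENOTYPES:
        cm, sites, loops, truth = sd.simulate_genotype(name, seed=args.seed)
        mc.write_contacts(cm, args.out / f"{name}.contacts.tsv")
        truth.to_json(args.out / f"{name}.truth.json")
        print(f"{name:>14}: {cm.total:>12.0f} contacts, "
              f"stripe L = {truth.stripe_len / 1e6:.1f} Mb")
    with open(args.out / "chrom.sizes", "w") as fh:
        fh.write(f"{cm.chrom}\t{cm.genome.length(cm.chrom)}\n")
    ag.write_loops(loops, args.out / "loops.bedpe")
    ag.write_anchors(sites, args.out / "sites.bed")
    print(f"{len(loops)} primary loops, {len(sites)} CTCF-like sites "
          f"-> {args.out}")


if __name__ == "__main__":
    main()
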