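#!/usr/bin/env python
"""Aggregate stripe analysis across genotypes with LOESS quantification.

Reads the simulated maps from 01_simulate_genotypes.py, runs the standard
processing chain (ICE balancing, scaling to 1e8 contacts), extracts
expected-normalized aggregate stripe maps around the top CTCF-like sites,
fits the 5'/3' profiles with LOESS (95% CI), and additionally estimates the
stripe decay length per genotype from replicate maps.  Writes a summary
table and per-genotype profile TSVs under results/stripes/.

Finding (defaults): the mean 3' stripe enrichment over 1-3 Mb and the
estimated decay length both follow the planted genotype ordering
dHDAC8 < WT < dESCO1 < dWAPL < dESCO1_dWAPL, with the PDS5A knockouts in
the long-stripe regime.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from loopscreen import aggregates as ag
from loopscreen import matrixcore as mc
from loopscreen import simdata as sd


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--sim", type=Path, default=Path("results/simdata"))
    ap.add_argument("--out", type=Path, default=Path("results/stripes"))
    ap.add_argument("--n-reps", type=int, default=8,
                    help="replicate maps pooled for the decay-length fit")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    genome = mc.read_chrom_sizes(args.sim / "chrom.sizes", 100_000)
    sites = ag.select_top_sites(ag.read_anchors(args.sim / "sites.bed"))
    rows = []
    for name in sd.GENOTYPES:
        cm = mc.read_contacts(args.sim / f"{name}.contacts.tsv", genome,
                              genome.chrom_names[0])
        scaled = mc.scale_to_total(mc.ice_normalize(cm)[0])
        agg, p5, p3 = ag.aggregate_stripes(scaled, sites)
        fit = ag.fit_local_polynomial(p3.distances, p3.values)
        np.savetxt(args.out / f"{name}.stripe3.tsv",
                   np.column_stack([p3.distances, p3.values, fit.fitted,
                                    fit.ci_half]),
                   delimiter="\t", header="distance_bp\tmean_oe\tloess\tci95_half")
        params = sd.genotype_preset(name, seed=args.seed)
        L_hat = sd.recover_stripe_decay(params, n_reps=args.n_reps,
                                        seed=args.seed)
        rows.append({
            "genotype": name,
            "stripe3_mean_1_3mb": p3.mean_over(1e6, 3e6),
            "stripe5_mean_1_3mb": p5.mean_over(1e6, 3e6),
            "decay_length_planted_mb": sd.GENOTYPES[name][0] / 1e6,
            "decay_length_estimated_mb": L_hat / 1e6,
            "n_sites": p3.n_used,
        })
    table = pd.DataFrame(rows)
    table.to_csv(args.out / "stripe_summary.tsv", sep="\t", index=False,
                 float_format="%.4f")
    print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    core = table.set_index("genotype").loc[
        ["dHDAC8", "WT", "dESCO1", "dWAPL", "dESCO1_dWAPL"],
        "stripe3_mean_1_3mb"]
    print("\nplanted ordering recovered:",
          bool((core.diff().dropna() > 0).all()))


if __name__ == "__main__":
    main()
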