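#!/usr/bin/env python
"""Pairwise Fst between sites and f4 admixture contrasts on the gradient cohort.

Fst uses the Weir-Cockerham ratio-of-sums estimator on the autosomes; f4
contrasts each site against the first two panel ancestries with the
simulated ancestral frequencies standing in as the outgroup.
"""

import argparse
from pathlib import Path

import numpy as np

from deltaadmix.config import RunConfig
from deltaadmix.genio import read_panel_frequencies, read_ped_map
from deltaadmix.pipeline import stage_popstats, stage_qc


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    out = args.outdir / "gradient"
    cfg = RunConfig.from_yaml(out / "config.yaml")
    geno = read_ped_map(out / "cohort.ped", out / "cohort.map")
    geno = stage_qc(cfg, out, geno)
    panel = read_panel_frequencies(out / "panel.tsv")
    keep = [i for i, s in enumerate(panel.snp_ids)
            if s in set(geno.snps["snp_id"])]
    panel = panel.subset(keep)
    ancestral = np.loadtxt(out / "ancestral_freqs.txt")[keep]

    fst, f4_table = stage_popstats(cfg, out, geno, panel, ancestral=ancestral)
    print("pairwise Fst (clamped):")
    print(fst.to_frame().round(4).to_string())
    if len(f4_table):
        print("\nf4(Ancestral, site, KS, EU):")
        print(f4_table[["site", "f4", "se", "z", "interpretation"]]
              .round(5).to_string(index=False))


if __name__ == "__main__":
    main()
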