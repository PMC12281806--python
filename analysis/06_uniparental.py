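#!/usr/bin/env python
"""MT / autosome / Y ancestry concordance on the study cohort.

Tallies the ancestry associated with mitochondrial and Y haplogroups,
compares them with the mean autosomal proportions, and flags each ancestry
as female- or male-leaning. A female-biased ancestry should show
f_MT > f_auto > f_Y; a male-biased one the reverse.
"""

import argparse
from pathlib import Path

import pandas as pd

from deltaadmix.config import RunConfig
from deltaadmix.genio import read_haplogroup_table
from deltaadmix.pipeline import stage_uniparental


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    out = args.outdir / "study"
    cfg = RunConfig.from_yaml(out / "config.yaml")
    haps = read_haplogroup_table(out / "haplogroups.tsv")
    q = pd.read_csv(out / "ancestry_estimates.tsv", sep="\t")
    q = q[q.scope == "auto:mean"]
    labels = [c[2:] for c in q.columns if c.startswith("q_")]
    means = pd.Series({lab: q[f"q_{lab}"].mean() for lab in labels})
    comp = stage_uniparental(cfg, out, haps, means, labels)
    print(comp.round(3).to_string(index=False))
    for r in comp.itertuples(index=False):
        print(f"  {r.ancestry}: MT {r.f_mt:.3f} / auto {r.f_auto:.3f} / "
              f"Y {r.f_y:.3f} -> {r.flag}")


if __name__ == "__main__":
    main()
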