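#!/usr/bin/env python
"""ΔAdmix sex-bias analysis on the study cohort.

Builds the X-length matched autosomal SNP sets, re-runs the supervised EM on
the matched subsets and the X, and bootstraps the per-site and pooled ΔAdmix
ratios. Prints the pooled table: the KS-like ancestry should come out
positive (female-biased) and the EU-like ancestry negative (male-biased),
with 95% CIs excluding zero.
"""

import argparse
from pathlib import Path

import pandas as pd

from deltaadmix.ancestry import average_autosomal_q, estimate_cohort_q
from deltaadmix.config import RunConfig
from deltaadmix.genio import read_panel_frequencies, read_ped_map
from deltaadmix.pipeline import stage_qc, stage_sexbias


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    out = args.outdir / "study"
    cfg = RunConfig.from_yaml(out / "config.yaml")
    geno = read_ped_map(out / "cohort.ped", out / "cohort.map")
    geno = stage_qc(cfg, out, geno)
    panel = read_panel_frequencies(out / "panel.tsv")
    keep = [i for i, s in enumerate(panel.snp_ids)
            if s in set(geno.snps["snp_id"])]
    panel = panel.subset(keep)

    runs = [estimate_cohort_q(geno, panel, scope=c) for c in geno.autosomes()]
    auto_mean = average_autosomal_q(runs)
    order = {iid: i for i, iid in enumerate(geno.individuals["individual_id"])}
    auto_mean.sort(key=lambda v: order[v.individual_id])

    table = stage_sexbias(cfg, out, geno, panel, auto_mean)
    pooled = table[table.site == "POOLED"]
    print(pooled.to_string(index=False))
    for r in pooled.itertuples(index=False):
        direction = ("female-biased" if r.delta_admix > 0 else "male-biased")
        sig = "significant" if r.significant else "not significant"
        print(f"  {r.ancestry}: ΔAdmix = {r.delta_admix:+.4f} "
              f"[{r.ci_low:+.4f}, {r.ci_high:+.4f}] -> {direction}, {sig}")


if __name__ == "__main__":
    main()
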