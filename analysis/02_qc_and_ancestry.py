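#!/usr/bin/env python
"""Quality-filter the simulated cohorts and estimate ancestry proportions.

Reads the PED/MAP written by 01_simulate_cohort.py, applies the missingness
and HWE filters, runs the supervised EM per chromosome (autosomes and X) and
writes per-individual ancestry estimates plus the autosomal mean.
"""

import argparse
from pathlib import Path

from deltaadmix.config import RunConfig
from deltaadmix.genio import read_panel_frequencies, read_ped_map
from deltaadmix.pipeline import stage_estimate, stage_qc


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    for name in ("study", "gradient"):
        out = args.outdir / name
        cfg = RunConfig.from_yaml(out / "config.yaml")
        geno = read_ped_map(out / "cohort.ped", out / "cohort.map")
        geno = stage_qc(cfg, out, geno)
        panel = read_panel_frequencies(out / "panel.tsv")
        keep = [i for i, s in enumerate(panel.snp_ids)
                if s in set(geno.snps["snp_id"])]
        panel = panel.subset(keep)
        per_chrom, x_vectors, auto_mean = stage_estimate(cfg, out, geno, panel)
        mean_q = sum(v.q for v in auto_mean) / len(auto_mean)
        pretty = ", ".join(
            f"{lab}={q:.3f}" for lab, q in zip(panel.labels, mean_q)
        )
        print(f"{name}: QC kept {geno.n_ind} ind / {geno.n_snp} SNPs; "
              f"cohort mean autosomal ancestry: {pretty}")


if __name__ == "__main__":
    main()
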