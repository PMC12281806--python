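"""End-to-end driver: simulate -> QC -> ancestry EM -> ΔAdmix -> popstats ->
geography -> uniparental, with a manifest recording seeds and file digests.

Each stage is an importable function taking the RunConfig and the run
directory, so the numbered analysis drivers, the CLI and the tests all share
one code path. Any stage failure is re-raised as PipelineStageError naming
the stage; outputs written before the failure are preserved.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ancestry import average_autosomal_q, estimate_cohort_q, q_matrix, vectors_to_frame
from .config import RunConfig, stage_seed
from .genio import (
    X_CHROM,
    GenotypeMatrix,
    PanelFrequencies,
    qc_filter,
    read_ped_map,
    read_site_table,
    write_ped_map,
    write_panel_frequencies,
)
from .geo import (
    fit_cline,
    geographic_distance_matrix,
    leave_one_out_clines,
    mantel_test,
    site_mean_ancestry,
)
from .popstats import f4_statistic, fst_matrix, population_frequencies
from .sexbias import build_matched_autosomal_sets, per_site_and_pooled, results_frame
from .simdata import (
    ContributionConfig,
    default_chromosomes,
    haplogroup_table_from_truth,
    simulate_admixed_cohort,
    simulate_genetic_map,
    simulate_panel_frequencies,
    site_table_from_configs,
)
from .uniparental import tally_marker_ancestry, three_marker_comparison

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _seed_int(master_seed: int, stage: str) -> int:
    return int(stage_seed(master_seed, stage).generate_state(1)[0] % (2**31 - 1))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: RunConfig, outdir: Path):
    sim = cfg.simulate
    seed = _seed_int(cfg.seed, "simulate")
    if sim.chromosomes is not None:
        chroms = [(str(c), float(l), int(n)) for c, l, n in sim.chromosomes]
    else:
        chroms = default_chromosomes(sim.n_snps_autosomal, sim.n_snps_x)
    panel = simulate_panel_frequencies(
        K=sim.K,
        n_snps=sum(n for _, _, n in chroms),
        fst_drift=sim.fst_drift,
        seed=seed,
        labels=cfg.ancestries,
    )
    gmap = simulate_genetic_map(chroms, seed=seed + 1)
    configs = [
        ContributionConfig(
            site_name=s.name,
            n_individuals=s.n_individuals,
            f_female=np.asarray(s.f_female),
            f_male=np.asarray(s.f_male),
            dirichlet_concentration=sim.dirichlet_concentration,
            latitude=s.latitude,
            longitude=s.longitude,
        )
        for s in sim.sites
    ]
    geno, truth = simulate_admixed_cohort(
        panel,
        gmap,
        configs,
        sex_ratio=sim.sex_ratio,
        seed=seed + 2,
        missing_rate=sim.missing_rate,
    )
    write_ped_map(geno, outdir / "cohort")
    write_panel_frequencies(panel, outdir / "panel.tsv")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    site_table_from_configs(configs).to_csv(outdir / "sites.csv", index=False)
    haplogroup_table_from_truth(truth).to_csv(
        outdir / "haplogroups.tsv", sep="\t", index=False
    )
    # ancestral frequencies double as an outgroup-like population for f4
    np.savetxt(outdir / "ancestral_freqs.txt", panel.ancestral)
    return geno, panel, truth


def stage_qc(cfg: RunConfig, outdir: Path, geno: GenotypeMatrix) -> GenotypeMatrix:
    out, report = qc_filter(
        geno,
        ind_miss_max=cfg.qc.ind_miss_max,
        snp_miss_max=cfg.qc.snp_miss_max,
        hwe_alpha=cfg.qc.hwe_alpha,
    )
    report.to_json(outdir / "qc_report.json")
    return out


def stage_estimate(cfg: RunConfig, outdir: Path, geno: GenotypeMatrix,
                   panel: PanelFrequencies):
    """Supervised EM per chromosome (autosomes and X) + the autosomal mean."""
    per_chrom = {}
    for chrom in geno.autosomes():
        per_chrom[chrom] = estimate_cohort_q(geno, panel, scope=chrom)
    x_vectors = estimate_cohort_q(geno, panel, scope=X_CHROM)
    auto_mean = average_autosomal_q(list(per_chrom.values()))
    # align auto_mean to cohort order
    order = {iid: i for i, iid in enumerate(geno.individuals["individual_id"])}
    auto_mean.sort(key=lambda v: order[v.individual_id])

    frames = [vectors_to_frame(v) for v in per_chrom.values()]
    frames.append(vectors_to_frame(x_vectors))
    frames.append(vectors_to_frame(auto_mean))
    pd.concat(frames, ignore_index=True).to_csv(
        outdir / "ancestry_estimates.tsv", sep="\t", index=False
    )
    return per_chrom, x_vectors, auto_mean


def stage_sexbias(cfg: RunConfig, outdir: Path, geno: GenotypeMatrix,
                  panel: PanelFrequencies, auto_mean):
    """Matched-set ΔAdmix with bootstrap CIs, per site and pooled."""
    seed = _seed_int(cfg.seed, "sexbias")
    kwargs = {}
    if cfg.sexbias.trim_chroms is not None:
        kwargs["trim_chroms"] = tuple(cfg.sexbias.trim_chroms)
    if cfg.sexbias.whole_chroms is not None:
        kwargs["whole_chroms"] = tuple(cfg.sexbias.whole_chroms)
    matched = build_matched_autosomal_sets(geno, trim_cm=cfg.sexbias.trim_cm,
                                           seed=seed, **kwargs)
    # per-chromosome EM on the matched (downsampled) autosomal subsets
    subset_vectors = []
    for chrom, idx in matched.subsets.items():
        subset_vectors.append(
            estimate_cohort_q(geno, panel, scope=chrom, snp_idx=idx)
        )
    x_vectors = estimate_cohort_q(geno, panel, scope=X_CHROM,
                                  snp_idx=matched.x_indices)
    _, q_x = q_matrix(x_vectors)
    q_subsets = np.stack([q_matrix(v)[1] for v in subset_vectors], axis=1)
    _, f_total = q_matrix(auto_mean)
    sexes = geno.individuals["sex"].to_numpy()
    sites = geno.individuals["site"].to_numpy()

    table = per_site_and_pooled(
        q_x,
        q_subsets,
        sexes,
        sites,
        f_total_ind=f_total,
        labels=list(panel.labels),
        n_boot=cfg.sexbias.n_boot,
        seed=seed + 1,
        alpha=cfg.sexbias.alpha,
    )
    table.to_csv(outdir / "sexbias.tsv", sep="\t", index=False)
    return table


def stage_popstats(cfg: RunConfig, outdir: Path, geno: GenotypeMatrix,
                   panel: PanelFrequencies, ancestral: np.ndarray | None = None):
    """Pairwise site Fst (autosomes) and f4 contrasts against the panel."""
    auto_idx = np.flatnonzero(~geno.is_x)
    auto = geno.subset(snp_idx=auto_idx)
    fst = fst_matrix(auto)
    fst.to_frame().to_csv(outdir / "fst_matrix.tsv", sep="\t")
    pd.DataFrame(fst.raw, index=fst.labels, columns=fst.labels).to_csv(
        outdir / "fst_matrix_raw.tsv", sep="\t"
    )

    f4_rows = []
    if ancestral is not None and panel.K >= 2:
        outgroup = ancestral[auto_idx]
        p1 = panel.freqs[auto_idx, 0]
        p2 = panel.freqs[auto_idx, 1]
        for site in pd.unique(geno.individuals["site"]):
            mask = (geno.individuals["site"] == site).to_numpy()
            test = population_frequencies(auto, mask)
            res = f4_statistic(
                outgroup, test, p1, p2,
                labels=("Ancestral", str(site), panel.labels[0], panel.labels[1]),
            )
            f4_rows.append(
                {
                    "site": site,
                    "pop1": panel.labels[0],
                    "pop2": panel.labels[1],
                    "f4": res.f4,
                    "se": res.se,
                    "z": res.z,
                    "n_blocks": res.n_blocks,
                    "n_snps": res.n_snps,
                    "interpretation": res.interpretation,
                }
            )
    f4_table = pd.DataFrame(f4_rows)
    f4_table.to_csv(outdir / "f4_contrasts.tsv", sep="\t", index=False)
    return fst, f4_table


def stage_geo(cfg: RunConfig, outdir: Path, geno: GenotypeMatrix, auto_mean,
              site_table: pd.DataFrame, fst):
    """Site ancestry means, lat/lon clines (+ leave-one-out), Mantel test."""
    seed = _seed_int(cfg.seed, "geo")
    ids, q = q_matrix(auto_mean)
    labels = auto_mean[0].labels
    sites = geno.individuals.set_index("individual_id").loc[ids, "site"].to_numpy()
    means = site_mean_ancestry(q, sites, labels, min_n=cfg.geo.min_n)
    means.to_csv(outdir / "site_mean_ancestry.tsv", sep="\t")

    st = site_table[site_table["site"].isin(means.index)].reset_index(drop=True)
    cline_rows, loo_frames = [], []
    if len(means) >= 3:
        for lab in labels:
            for axis in ("latitude", "longitude"):
                coords = st.set_index("site").loc[means.index, axis]
                fit = fit_cline(means[lab], coords, axis, ancestry=lab)
                cline_rows.append(fit.__dict__)
                if len(means) >= 4:
                    loo_frames.append(
                        leave_one_out_clines(means, st, lab, axis)
                    )
    pd.DataFrame(cline_rows).to_csv(outdir / "clines.tsv", sep="\t", index=False)
    if loo_frames:
        pd.concat(loo_frames, ignore_index=True).to_csv(
            outdir / "clines_leave_one_out.tsv", sep="\t", index=False
        )

    mantel = None
    fst_sites = [s for s in fst.labels if s in set(means.index)]
    if len(fst_sites) >= 3:
        pos = [fst.labels.index(s) for s in fst_sites]
        D_gen = fst.raw[np.ix_(pos, pos)]
        st_m = st.set_index("site").loc[fst_sites].reset_index()
        D_geo = geographic_distance_matrix(st_m)
        mantel = mantel_test(D_gen, D_geo, n_perm=cfg.geo.n_perm, seed=seed)
        Path(outdir / "mantel.json").write_text(
            json.dumps(mantel.__dict__, indent=2) + "\n"
        )
    return means, pd.DataFrame(cline_rows), mantel


def stage_uniparental(cfg: RunConfig, outdir: Path, haps: pd.DataFrame,
                      means_all: pd.DataFrame, labels: list[str]):
    mt = tally_marker_ancestry(haps, "MT", labels)
    y = tally_marker_ancestry(haps, "Y", labels)
    auto = {lab: float(means_all[lab]) for lab in labels}
    comp = three_marker_comparison(mt, auto, y, labels)
    comp.to_csv(outdir / "uniparental_comparison.tsv", sep="\t", index=False)
    return comp


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute every stage on a synthetic cohort; returns the run directory."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")

    stage = "simulate"
    try:
        geno, panel, truth = stage_simulate(cfg, outdir)
        ancestral = panel.ancestral

        stage = "qc"
        geno = stage_qc(cfg, outdir, geno)
        keep = set(geno.snps["snp_id"])
        panel_idx = np.flatnonzero(np.isin(panel.snp_ids, list(keep)))
        panel = panel.subset(panel_idx)
        ancestral = ancestral[panel_idx]

        stage = "estimate"
        per_chrom, x_vectors, auto_mean = stage_estimate(cfg, outdir, geno, panel)

        stage = "sexbias"
        stage_sexbias(cfg, outdir, geno, panel, auto_mean)

        stage = "popstats"
        # ancestral aligned to the QC'd panel rows, which match geno SNP order
        fst, _ = stage_popstats(cfg, outdir, geno, panel,
                                ancestral=np.asarray(ancestral))

        stage = "geo"
        site_table = read_site_table(outdir / "sites.csv")
        means, clines, mantel = stage_geo(cfg, outdir, geno, auto_mean,
                                          site_table, fst)

        stage = "uniparental"
        from .genio import read_haplogroup_table

        haps = read_haplogroup_table(outdir / "haplogroups.tsv")
        ids, q = q_matrix(auto_mean)
        overall = {lab: float(q[:, k].mean())
                   for k, lab in enumerate(auto_mean[0].labels)}
        stage_uniparental(cfg, outdir, haps, pd.Series(overall),
                          list(auto_mean[0].labels))
    except Exception as e:  # noqa: BLE001 - stage attribution is the point
        raise PipelineStageError(stage, e) from e

    manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "master_seed": cfg.seed,
        "stage_seeds": {s: _seed_int(cfg.seed, s) for s in
                        ("simulate", "sexbias", "geo")},
        "files": {
            p.name: _digest(p)
            for p in sorted(outdir.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return outdir
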