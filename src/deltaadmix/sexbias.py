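"""X-vs-autosome sex-biased admixture: matched SNP sets, ΔAdmix, bootstrap CIs.

A source population that contributed predominantly through women leaves more
of its ancestry on the X chromosome (which spends two thirds of its history
in females) than on the autosomes. The sex-bias statistic per ancestry is

    dAdmix = F_total * (F_X - F_auto) / (F_X + F_auto)

where F_X is the cohort X-chromosome proportion of that ancestry (females
weighted twice, as they carry two X copies), F_auto the matched autosomal
proportion and F_total the genome-wide proportion. Positive values indicate
female-biased, negative values male-biased contribution.

To keep the X and autosomal estimates comparable, autosomal chromosomes are
trimmed to the genetic length of the X (180 cM; chromosomes already about
that length are taken whole) and each trimmed set is downsampled to exactly
the number of SNPs on the X. Confidence intervals come from a percentile
bootstrap over individuals, resampling their precomputed per-chromosome
ancestry proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import X_CHROM, GenotypeMatrix

TRIM_CHROMS = ("chr1", "chr2", "chr3", "chr4", "chr5", "chr6")
WHOLE_CHROMS = ("chr7", "chr10", "chr12")


@dataclass
class MatchedSets:
    """X SNP indices plus equally sized autosomal subsets, one per chromosome."""

    x_indices: np.ndarray
    subsets: dict[str, np.ndarray]
    trim_cm: float
    seed: object

    @property
    def n_x(self) -> int:
        return len(self.x_indices)


@dataclass
class DeltaAdmixResult:
    ancestry: str
    f_total: float
    f_x: float
    f_auto: float
    delta_admix: float
    ci_low: float
    ci_high: float
    n_boot: int
    n_individuals: int
    significant: bool
    site: str = "ALL"


def build_matched_autosomal_sets(
    geno: GenotypeMatrix,
    trim_cm: float = 180.0,
    seed=None,
    trim_chroms: tuple[str, ...] = TRIM_CHROMS,
    whole_chroms: tuple[str, ...] = WHOLE_CHROMS,
    anchor: str = "start",
) -> MatchedSets:
    """Trim long autosomes to the X's genetic length and match SNP counts.

    Chromosomes in ``trim_chroms`` are restricted to SNPs within ``trim_cm``
    of the chromosome's first mapped SNP (``anchor='center'`` trims a window
    centred on the chromosome midpoint instead); chromosomes in
    ``whole_chroms`` are taken whole. Every candidate set is then downsampled
    uniformly at random, without replacement, to the number of X SNPs.
    Deterministic given ``seed``.
    """
    cm = geno.snps["cm"].to_numpy(dtype=float)
    if not np.isfinite(cm).all() or (cm == 0).all():
        raise ValueError("genetic-map (cM) positions required for X/autosome matching")
    x_idx = geno.chrom_snp_indices(X_CHROM)
    if x_idx.size == 0:
        raise ValueError("no X-chromosome SNPs present")
    n_x = x_idx.size

    rng = np.random.default_rng(seed)
    subsets: dict[str, np.ndarray] = {}
    for chrom in tuple(trim_chroms) + tuple(whole_chroms):
        idx = geno.chrom_snp_indices(chrom)
        if idx.size == 0:
            raise ValueError(f"chromosome {chrom} absent from the dataset")
        if chrom in trim_chroms:
            pos = cm[idx]
            if anchor == "start":
                lo = pos.min()
                keep = pos <= lo + trim_cm
            elif anchor == "center":
                mid = (pos.min() + pos.max()) / 2.0
                keep = np.abs(pos - mid) <= trim_cm / 2.0
            else:
                raise ValueError(f"unknown anchor '{anchor}'")
            idx = idx[keep]
        if idx.size < n_x:
            raise ValueError(
                f"chromosome {chrom}: only {idx.size} SNPs available after "
                f"trimming, need {n_x} to match the X"
            )
        subsets[chrom] = np.sort(rng.choice(idx, size=n_x, replace=False))
    return MatchedSets(x_indices=x_idx, subsets=subsets, trim_cm=trim_cm, seed=seed)


def _sex_weights(sexes: np.ndarray) -> np.ndarray:
    sexes = np.asarray(sexes)
    unknown = ~np.isin(sexes, ("M", "F"))
    if unknown.any():
        raise ValueError("every individual needs sex M or F for X weighting")
    return np.where(sexes == "F", 2.0, 1.0)


def pooled_x_proportion(q_x: np.ndarray, sexes) -> np.ndarray:
    """Female-double-weighted cohort mean of X ancestry proportions.

    Females carry two X chromosomes and males one, so female vectors receive
    weight 2: F_X = sum_i w_i q_i / sum_i w_i.
    """
    q_x = np.atleast_2d(np.asarray(q_x, dtype=float))
    w = _sex_weights(sexes)
    return (w[:, None] * q_x).sum(axis=0) / w.sum()


def pooled_autosomal_proportion(q_subsets: np.ndarray) -> np.ndarray:
    """Mean over individuals of each individual's mean over matched subsets.

    ``q_subsets`` has shape (n_ind, n_subsets, K).
    """
    q_subsets = np.asarray(q_subsets, dtype=float)
    if q_subsets.ndim != 3 or q_subsets.shape[1] == 0:
        raise ValueError("expected (n_ind, n_subsets, K) with >=1 subset")
    return q_subsets.mean(axis=1).mean(axis=0)


def delta_admix(f_total, f_x, f_auto):
    """The X-to-autosomal difference ratio; 0 where the ancestry is absent.

    Element-wise over arrays. Negative values indicate male-biased and
    positive values female-biased contribution of the ancestry.
    """
    f_total = np.asarray(f_total, dtype=float)
    f_x = np.asarray(f_x, dtype=float)
    f_auto = np.asarray(f_auto, dtype=float)
    for name, v in (("f_total", f_total), ("f_x", f_x), ("f_auto", f_auto)):
        if ((v < 0) | (v > 1)).any():
            raise ValueError(f"{name} must lie in [0, 1]")
    denom = f_x + f_auto
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, f_total * (f_x - f_auto) / np.where(denom > 0, denom, 1.0), 0.0)
    return out if out.ndim else float(out)


def _pooled_stats(q_x, q_auto_mean, f_total_ind, w):
    f_x = (w[:, None] * q_x).sum(axis=0) / w.sum()
    f_auto = q_auto_mean.mean(axis=0)
    f_total = f_total_ind.mean(axis=0)
    return f_total, f_x, f_auto, delta_admix(f_total, f_x, f_auto)


def bootstrap_delta_admix(
    q_x: np.ndarray,
    q_auto_subsets: np.ndarray,
    sexes,
    f_total_ind: np.ndarray | None = None,
    labels: list[str] | None = None,
    n_boot: int = 10000,
    seed=None,
    alpha: float = 0.05,
    site: str = "ALL",
) -> list[DeltaAdmixResult]:
    """Percentile-bootstrap ΔAdmix per ancestry, resampling individuals.

    q_x: (n, K) per-individual X proportions; q_auto_subsets: (n, S, K)
    per-individual proportions on the S matched autosomal subsets;
    f_total_ind: (n, K) per-individual genome-wide proportions (defaults to
    the matched-subset autosomal mean). The CI is the (alpha/2, 1-alpha/2)
    percentile interval; 'significant' means the CI excludes zero.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    q_x = np.asarray(q_x, dtype=float)
    q_auto_subsets = np.asarray(q_auto_subsets, dtype=float)
    n, K = q_x.shape
    if n < 2:
        raise ValueError("need at least 2 individuals to bootstrap")
    q_auto_mean = q_auto_subsets.mean(axis=1)  # (n, K)
    if f_total_ind is None:
        f_total_ind = q_auto_mean
    f_total_ind = np.asarray(f_total_ind, dtype=float)
    w = _sex_weights(sexes)
    if labels is None:
        labels = [f"ANC{k + 1}" for k in range(K)]

    f_total, f_x, f_auto, point = _pooled_stats(q_x, q_auto_mean, f_total_ind, w)

    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, K))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        _, _, _, boots[b] = _pooled_stats(
            q_x[idx], q_auto_mean[idx], f_total_ind[idx], w[idx]
        )
    lo = np.percentile(boots, 100 * alpha / 2, axis=0)
    hi = np.percentile(boots, 100 * (1 - alpha / 2), axis=0)
    # degenerate resampling (all individuals identical) gives a zero-width CI;
    # the point estimate is inside by construction
    return [
        DeltaAdmixResult(
            ancestry=labels[k],
            f_total=float(f_total[k]),
            f_x=float(f_x[k]),
            f_auto=float(f_auto[k]),
            delta_admix=float(point[k]),
            ci_low=float(min(lo[k], point[k])),
            ci_high=float(max(hi[k], point[k])),
            n_boot=n_boot,
            n_individuals=n,
            significant=bool(lo[k] > 0 or hi[k] < 0),
            site=site,
        )
        for k in range(K)
    ]


def per_site_and_pooled(
    q_x: np.ndarray,
    q_auto_subsets: np.ndarray,
    sexes,
    sites,
    f_total_ind: np.ndarray | None = None,
    labels: list[str] | None = None,
    n_boot: int = 10000,
    seed=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """ΔAdmix per (site, ancestry) plus a pooled row per ancestry.

    The pooled point estimate is the unweighted mean of the per-site ΔAdmix
    values; its bootstrap resamples individuals within each site and averages
    the per-site replicate statistics.
    """
    sites = np.asarray(sites)
    site_names = list(pd.unique(sites))
    q_x = np.asarray(q_x, dtype=float)
    q_auto_subsets = np.asarray(q_auto_subsets, dtype=float)
    q_auto_mean = q_auto_subsets.mean(axis=1)
    if f_total_ind is None:
        f_total_ind = q_auto_mean
    f_total_ind = np.asarray(f_total_ind, dtype=float)
    w = _sex_weights(sexes)
    K = q_x.shape[1]
    if labels is None:
        labels = [f"ANC{k + 1}" for k in range(K)]

    rng = np.random.default_rng(seed)
    rows = []
    site_points = np.empty((len(site_names), K))
    site_boots = np.empty((len(site_names), n_boot, K))
    for s_i, s in enumerate(site_names):
        idx_all = np.flatnonzero(sites == s)
        if idx_all.size < 2:
            raise ValueError(f"site {s}: need at least 2 individuals")
        f_total_s, f_x_s, f_auto_s, point_s = _pooled_stats(
            q_x[idx_all], q_auto_mean[idx_all], f_total_ind[idx_all], w[idx_all]
        )
        site_points[s_i] = point_s
        for b in range(n_boot):
            idx = rng.choice(idx_all, size=idx_all.size, replace=True)
            _, _, _, site_boots[s_i, b] = _pooled_stats(
                q_x[idx], q_auto_mean[idx], f_total_ind[idx], w[idx]
            )
        lo_s = np.percentile(site_boots[s_i], 100 * alpha / 2, axis=0)
        hi_s = np.percentile(site_boots[s_i], 100 * (1 - alpha / 2), axis=0)
        for k in range(K):
            rows.append(
                DeltaAdmixResult(
                    ancestry=labels[k],
                    f_total=float(f_total_s[k]),
                    f_x=float(f_x_s[k]),
                    f_auto=float(f_auto_s[k]),
                    delta_admix=float(point_s[k]),
                    ci_low=float(min(lo_s[k], point_s[k])),
                    ci_high=float(max(hi_s[k], point_s[k])),
                    n_boot=n_boot,
                    n_individuals=int(idx_all.size),
                    significant=bool(lo_s[k] > 0 or hi_s[k] < 0),
                    site=s,
                )
            )

    pooled_point = site_points.mean(axis=0)
    pooled_boot = site_boots.mean(axis=0)  # (n_boot, K)
    lo = np.percentile(pooled_boot, 100 * alpha / 2, axis=0)
    hi = np.percentile(pooled_boot, 100 * (1 - alpha / 2), axis=0)
    for k in range(K):
        rows.append(
            DeltaAdmixResult(
                ancestry=labels[k],
                f_total=float(f_total_ind.mean(axis=0)[k]),
                f_x=float(pooled_x_proportion(q_x, sexes)[k]),
                f_auto=float(q_auto_mean.mean(axis=0)[k]),
                delta_admix=float(pooled_point[k]),
                ci_low=float(min(lo[k], pooled_point[k])),
                ci_high=float(max(hi[k], pooled_point[k])),
                n_boot=n_boot,
                n_individuals=len(sexes),
                significant=bool(lo[k] > 0 or hi[k] < 0),
                site="POOLED",
            )
        )
    return results_frame(rows)


def results_frame(results: list[DeltaAdmixResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "site": r.site,
                "ancestry": r.ancestry,
                "f_total": r.f_total,
                "f_x": r.f_x,
                "f_auto": r.f_auto,
                "delta_admix": r.delta_admix,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "n_boot": r.n_boot,
                "n_individuals": r.n_individuals,
                "significant": r.significant,
            }
            for r in results
        ]
    )
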