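"""f4 admixture contrasts with block-jackknife errors, and Weir-Cockerham Fst.

f4(A, B, C, D) is the mean over SNPs of (p_A - p_B)(p_C - p_D). Under a tree
((A,B),(C,D)) with no gene flow its expectation is zero; a significantly
negative value in the layout f4(Outgroup, Test, P1, P2) indicates gene flow
between Test and P1, a positive value gene flow between Test and P2.
Standard errors come from a weighted delete-one block jackknife over
contiguous SNP blocks, which absorbs linkage between nearby SNPs.

Pairwise Fst uses the Weir & Cockerham (1984) variance-components estimator
with the ratio-of-sums convention across SNPs (sum of a over sum of a+b+c),
matching the convention of the standard command-line tools.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix


@dataclass
class F4Result:
    pops: tuple[str, str, str, str]
    f4: float
    se: float
    z: float
    n_blocks: int
    n_snps: int
    interpretation: str


@dataclass
class FstMatrix:
    labels: list[str]
    matrix: np.ndarray        # clamped at 0
    raw: np.ndarray           # unclamped estimates
    n_pairs: np.ndarray       # SNPs used per pair

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def population_frequencies(geno: GenotypeMatrix, ind_mask) -> np.ndarray:
    """Per-SNP counted-allele sample frequency for one set of individuals.

    Ploidy-aware: males contribute a single allele on the X. SNPs with no
    observed alleles in the set are NaN.
    """
    ind_mask = np.asarray(ind_mask)
    if ind_mask.dtype != bool:
        mask = np.zeros(geno.n_ind, dtype=bool)
        mask[ind_mask] = True
        ind_mask = mask
    g = geno.genotypes[ind_mask].astype(float)
    c = geno.ploidy()[ind_mask].astype(float)
    obs = g != MISSING
    num = np.where(obs, g, 0.0).sum(axis=0)
    den = np.where(obs, c, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(den > 0, num / den, np.nan)
    return freq


def _jackknife(values: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    """Weighted delete-one block jackknife mean and SE.

    ``values`` are per-block means of the statistic's per-SNP terms;
    ``weights`` the block SNP counts. Returns (estimate, SE) where the
    estimate is the overall weighted mean and the SE follows the weighted
    jackknife variance formula (Busing et al. 1999).
    """
    g = len(values)
    n = weights.sum()
    theta_hat = float(np.sum(values * weights) / n)
    # delete-one estimates
    theta_j = (theta_hat * n - values * weights) / (n - weights)
    h = n / weights
    tau = h * theta_hat - (h - 1.0) * theta_j
    theta_dot = g * theta_hat - float(np.sum((1.0 - weights / n) * theta_j))
    var = float(np.sum((tau - theta_dot) ** 2 / (h - 1.0)) / g)
    return theta_hat, np.sqrt(var)


def f4_statistic(
    p_a,
    p_b,
    p_c,
    p_d,
    block_size_snps: int = 500,
    labels: tuple[str, str, str, str] = ("A", "B", "C", "D"),
) -> F4Result:
    """f4 from per-population allele-frequency vectors aligned over SNPs.

    SNPs with a missing (NaN) frequency in any population are excluded.
    Blocks are contiguous runs of ``block_size_snps`` usable SNPs; with fewer
    than 2 blocks the SE is undefined (NaN) and Z is NaN.
    """
    arrs = [np.asarray(p, dtype=float) for p in (p_a, p_b, p_c, p_d)]
    if len({a.shape for a in arrs}) != 1:
        raise ValueError("frequency vectors must be aligned over the same SNPs")
    usable = ~np.any([np.isnan(a) for a in arrs], axis=0)
    if not usable.any():
        raise ValueError("no SNP usable in all four populations")
    pa, pb, pc, pd_ = (a[usable] for a in arrs)
    terms = (pa - pb) * (pc - pd_)
    n = terms.size

    n_blocks = max(1, int(np.ceil(n / block_size_snps)))
    bounds = np.linspace(0, n, n_blocks + 1).astype(int)
    vals = np.array(
        [terms[bounds[i]: bounds[i + 1]].mean() for i in range(n_blocks)]
    )
    wts = np.diff(bounds).astype(float)
    if n_blocks >= 2:
        f4, se = _jackknife(vals, wts)
        z = f4 / se if se > 0 else np.nan
    else:
        f4 = float(terms.mean())
        se = np.nan
        z = np.nan

    a_lab, b_lab, c_lab, d_lab = labels
    if np.isnan(z) or abs(z) < 3:
        interp = "consistent with zero"
    elif f4 < 0:
        interp = f"gene flow between {b_lab} and {c_lab} (or {a_lab} and {d_lab})"
    else:
        interp = f"gene flow between {b_lab} and {d_lab} (or {a_lab} and {c_lab})"
    return F4Result(
        pops=tuple(labels),
        f4=float(f4),
        se=float(se),
        z=float(z),
        n_blocks=n_blocks,
        n_snps=int(n),
        interpretation=interp,
    )


def _wc_components(geno: GenotypeMatrix, mask_a, mask_b):
    """Per-SNP Weir-Cockerham (1984) a, b, c variance components, two pops."""
    comps = []
    g = geno.genotypes
    for j in range(geno.n_snp):
        ns, ps, hs = [], [], []
        for mask in (mask_a, mask_b):
            col = g[mask, j]
            col = col[col != MISSING]
            if col.size == 0:
                ns.append(0.0)
                ps.append(np.nan)
                hs.append(np.nan)
                continue
            ns.append(float(col.size))
            ps.append(float(col.mean() / 2.0))
            hs.append(float((col == 1).mean()))
        comps.append((ns, ps, hs))

    r = 2.0
    a = np.full(geno.n_snp, np.nan)
    b = np.full(geno.n_snp, np.nan)
    c = np.full(geno.n_snp, np.nan)
    for j, (ns, ps, hs) in enumerate(comps):
        n1, n2 = ns
        if n1 < 1 or n2 < 1 or (n1 + n2) < 3:
            continue
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * ps[0] + n2 * ps[1]) / (r * nbar)
        s2 = (n1 * (ps[0] - pbar) ** 2 + n2 * (ps[1] - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * hs[0] + n2 * hs[1]) / (r * nbar)
        if nbar <= 1 or nc <= 0:
            continue
        a[j] = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1.0 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0)
        )
        b[j] = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - s2 * (r - 1.0) / r
            - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c[j] = hbar / 2.0
    return a, b, c


def fst_weir_cockerham(
    geno: GenotypeMatrix, ids_a, ids_b
) -> tuple[float, int]:
    """Two-population W&C Fst, ratio-of-sums across SNPs: sum a / sum(a+b+c).

    ``ids_a`` / ``ids_b`` are individual_id lists or boolean masks. SNPs
    monomorphic in the pooled sample contribute zero to both sums. Returns
    (fst, n_snps_used); the raw (possibly negative) estimate is returned —
    matrix assembly clamps at zero.
    """

    def as_mask(ids):
        ids = np.asarray(ids)
        if ids.dtype == bool:
            return ids
        present = geno.individuals["individual_id"].isin(ids).to_numpy()
        if present.sum() != len(ids):
            raise ValueError("some individual ids not found")
        return present

    mask_a, mask_b = as_mask(ids_a), as_mask(ids_b)
    if mask_a.sum() == 0 or mask_b.sum() == 0:
        raise ValueError("each population needs at least one typed individual")
    a, b, c = _wc_components(geno, mask_a, mask_b)
    ok = ~np.isnan(a)
    if not ok.any():
        raise ValueError("no SNP with data in both populations")
    num = a[ok].sum()
    den = (a[ok] + b[ok] + c[ok]).sum()
    if den == 0:
        raise ValueError("all usable SNPs monomorphic; Fst undefined")
    return float(num / den), int(ok.sum())


def fst_matrix(geno: GenotypeMatrix, site_labels=None, min_n: int = 1) -> FstMatrix:
    """All pairwise W&C Fst between groups (default: the 'site' column)."""
    if site_labels is None:
        site_labels = geno.individuals["site"].to_numpy()
    site_labels = np.asarray(site_labels)
    groups = list(pd.unique(site_labels))
    P = len(groups)
    raw = np.zeros((P, P))
    n_pairs = np.zeros((P, P), dtype=int)
    for i in range(P):
        for j in range(i + 1, P):
            mi = site_labels == groups[i]
            mj = site_labels == groups[j]
            if mi.sum() < min_n or mj.sum() < min_n:
                raw[i, j] = raw[j, i] = np.nan
                continue
            fst, n_used = fst_weir_cockerham(geno, mi, mj)
            raw[i, j] = raw[j, i] = fst
            n_pairs[i, j] = n_pairs[j, i] = n_used
    matrix = np.where(np.isnan(raw), np.nan, np.clip(raw, 0.0, None))
    np.fill_diagonal(matrix, 0.0)
    np.fill_diagonal(raw, 0.0)
    return FstMatrix(labels=[str(g) for g in groups], matrix=matrix, raw=raw,
                     n_pairs=n_pairs)


def generations_to_years(
    generations: float, generation_time: float = 29.0, round_years: bool = False
):
    """Convert generations ago to years at the given generation time."""
    years = generations * generation_time
    return round(years) if round_years else years
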