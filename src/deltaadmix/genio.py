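"""Genotype containers, PLINK text PED/MAP I/O, tabular inputs and QC filtering.

The in-memory genotype representation is a dosage matrix: for each individual
and SNP, the number of copies of the *counted* allele (0, 1 or 2; males carry
at most 1 on the X). Missing genotypes are stored as -1. SNP and individual
metadata travel alongside as pandas DataFrames so that every downstream stage
can slice by chromosome, sex or sampling site without re-parsing files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MISSING = -1

X_CHROM = "X"

VALID_ALLELES = {"A", "C", "G", "T", "0", "1", "2", "B"}


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs counted-allele dosages with map and sample metadata.

    genotypes : int array (n_ind, n_snp), values in {0, 1, 2, MISSING};
        male X entries are in {0, 1, MISSING} after normalisation.
    snps : DataFrame with columns snp_id, chrom, cm, bp, counted_allele.
    individuals : DataFrame with columns individual_id, sex ('M'/'F'/'U'), site.
    """

    genotypes: np.ndarray
    snps: pd.DataFrame
    individuals: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int16)
        self.snps = self.snps.reset_index(drop=True)
        self.individuals = self.individuals.reset_index(drop=True)
        self.validate()

    # -- basic shape ---------------------------------------------------------
    @property
    def n_ind(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snp(self) -> int:
        return self.genotypes.shape[1]

    def validate(self) -> None:
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix")
        if len(self.snps) != self.n_snp:
            raise ValueError(
                f"SNP metadata length {len(self.snps)} != n_snp {self.n_snp}"
            )
        if len(self.individuals) != self.n_ind:
            raise ValueError(
                f"individual metadata length {len(self.individuals)} "
                f"!= n_ind {self.n_ind}"
            )
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype values outside {0,1,2,missing}")
        # hemizygosity: male X dosages never exceed 1
        male = (self.individuals["sex"] == "M").to_numpy()
        on_x = (self.snps["chrom"] == X_CHROM).to_numpy()
        if male.any() and on_x.any():
            mx = self.genotypes[np.ix_(male, on_x)]
            if (mx > 1).any():
                raise ValueError("male X genotypes must be hemizygous (0/1)")

    # -- helpers -------------------------------------------------------------
    @property
    def is_x(self) -> np.ndarray:
        return (self.snps["chrom"] == X_CHROM).to_numpy()

    def ploidy(self) -> np.ndarray:
        """Per-entry ploidy (n_ind, n_snp): 1 for males on X, else 2."""
        p = np.full((self.n_ind, self.n_snp), 2, dtype=np.int8)
        male = (self.individuals["sex"] == "M").to_numpy()
        p[np.ix_(male, self.is_x)] = 1
        return p

    def subset(self, ind_idx=None, snp_idx=None) -> "GenotypeMatrix":
        ind_idx = np.arange(self.n_ind) if ind_idx is None else np.asarray(ind_idx)
        snp_idx = np.arange(self.n_snp) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeMatrix(
            genotypes=self.genotypes[np.ix_(ind_idx, snp_idx)],
            snps=self.snps.iloc[snp_idx],
            individuals=self.individuals.iloc[ind_idx],
        )

    def chrom_snp_indices(self, chrom: str) -> np.ndarray:
        return np.flatnonzero((self.snps["chrom"] == chrom).to_numpy())

    def autosomes(self) -> list[str]:
        return [c for c in self.snps["chrom"].unique() if c != X_CHROM]


@dataclass
class PanelFrequencies:
    """Reference counted-allele frequencies: K ancestries x SNPs.

    freqs is stored (n_snp, K); labels name the ancestries; snp_ids align the
    rows to a GenotypeMatrix.
    """

    labels: list[str]
    freqs: np.ndarray
    snp_ids: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.snp_ids = np.asarray(self.snp_ids)
        if self.freqs.ndim != 2 or self.freqs.shape[1] != len(self.labels):
            raise ValueError("freqs must be (n_snp, K) matching labels")
        if len(self.snp_ids) != self.freqs.shape[0]:
            raise ValueError("snp_ids length mismatch")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("snp_ids must be unique")
        if ((self.freqs < 0) | (self.freqs > 1)).any():
            raise ValueError("panel frequencies outside [0, 1]")

    @property
    def K(self) -> int:
        return len(self.labels)

    @property
    def n_snp(self) -> int:
        return self.freqs.shape[0]

    def subset(self, snp_idx) -> "PanelFrequencies":
        snp_idx = np.asarray(snp_idx)
        return PanelFrequencies(
            labels=list(self.labels),
            freqs=self.freqs[snp_idx],
            snp_ids=self.snp_ids[snp_idx],
        )

    def clipped(self, eps: float = 1e-4) -> "PanelFrequencies":
        return PanelFrequencies(
            labels=list(self.labels),
            freqs=np.clip(self.freqs, eps, 1.0 - eps),
            snp_ids=self.snp_ids,
        )


@dataclass
class QcReport:
    individuals_removed: int
    snps_removed_missingness: int
    snps_removed_hwe: int
    n_ind_before: int
    n_snp_before: int
    n_ind_after: int
    n_snp_after: int
    ind_miss_max: float
    snp_miss_max: float
    hwe_alpha: float

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")


# ---------------------------------------------------------------------------
# PED/MAP
# ---------------------------------------------------------------------------

_SEX_TO_PED = {"M": "1", "F": "2", "U": "0"}
_PED_TO_SEX = {"1": "M", "2": "F"}


def write_ped_map(geno: GenotypeMatrix, out_prefix) -> tuple[Path, Path]:
    """Write PLINK text PED/MAP; counted allele coded 'A', the other 'B'.

    Missing dosages become "0 0"; male X hemizygotes are written as
    pseudo-homozygotes ("A A" / "B B"), the PLINK convention for haploid calls.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    ped_path = out_prefix.with_suffix(".ped")
    map_path = out_prefix.with_suffix(".map")

    with open(map_path, "w") as fh:
        for row in geno.snps.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp_id}\t{row.cm:g}\t{int(row.bp)}\n")

    code = {2: "A A", 1: "A B", 0: "B B", MISSING: "0 0"}
    hemi = {1: "A A", 0: "B B", MISSING: "0 0"}
    on_x = geno.is_x
    with open(ped_path, "w") as fh:
        for i, ind in enumerate(geno.individuals.itertuples(index=False)):
            sex = _SEX_TO_PED.get(ind.sex, "0")
            fields = [str(ind.site), str(ind.individual_id), "0", "0", sex, "-9"]
            row = geno.genotypes[i]
            male = ind.sex == "M"
            for j in range(geno.n_snp):
                g = int(row[j])
                fields.append(hemi[g] if (male and on_x[j]) else code[g])
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path


def read_ped_map(
    ped_path, map_path, counted_alleles: dict[str, str] | None = None
) -> GenotypeMatrix:
    """Read PLINK text PED/MAP into a dosage matrix.

    The counted allele per SNP is taken from `counted_alleles` (snp_id ->
    allele) when given, otherwise the alphabetically first allele observed at
    the SNP; dosage is the count of that allele. Male X heterozygote calls are
    impossible for a hemizygous locus and are set to missing with a warning.
    """
    snps = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "bp"],
        dtype={"chrom": str, "snp_id": str, "cm": float, "bp": int},
    )
    n_snp = len(snps)

    ids, sexes, sites = [], [], []
    allele_rows: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snp:
                raise ValueError(
                    f"{ped_path}: line {lineno} has {len(parts)} fields, "
                    f"expected {6 + 2 * n_snp}"
                )
            sites.append(parts[0])
            ids.append(parts[1])
            sexes.append(_PED_TO_SEX.get(parts[4], "U"))
            pair_list = []
            for j in range(n_snp):
                a, b = parts[6 + 2 * j], parts[7 + 2 * j]
                if a not in VALID_ALLELES or b not in VALID_ALLELES:
                    raise ValueError(
                        f"{ped_path}: line {lineno} SNP {snps.snp_id[j]}: "
                        f"unsupported allele symbols '{a} {b}'"
                    )
                pair_list.append((a, b))
            allele_rows.append(pair_list)

    n_ind = len(ids)
    genotypes = np.full((n_ind, n_snp), MISSING, dtype=np.int16)
    counted = []
    on_x = (snps["chrom"] == X_CHROM).to_numpy()
    n_male_x_het = 0
    all_symbols = {
        a for row in allele_rows for pair in row for a in pair if a != "0"
    }
    # pure A/B-coded files have a known two-letter alphabet, so the counted
    # allele is 'A' everywhere even at SNPs where only 'B' was observed
    ab_coded = all_symbols <= {"A", "B"}
    for j in range(n_snp):
        observed = {
            a
            for i in range(n_ind)
            for a in allele_rows[i][j]
            if a != "0"
        }
        if counted_alleles and str(snps.snp_id[j]) in counted_alleles:
            ca = counted_alleles[str(snps.snp_id[j])]
        elif ab_coded:
            ca = "A"
        else:
            ca = min(observed) if observed else "A"
        counted.append(ca)
        for i in range(n_ind):
            a, b = allele_rows[i][j]
            if a == "0" or b == "0":
                continue
            dose = int(a == ca) + int(b == ca)
            if on_x[j] and sexes[i] == "M":
                if a != b:
                    n_male_x_het += 1
                    continue  # left missing
                dose //= 2
            genotypes[i, j] = dose
    if n_male_x_het:
        logger.warning(
            "set %d heterozygous male X genotype(s) to missing", n_male_x_het
        )

    snps = snps.assign(counted_allele=counted)
    individuals = pd.DataFrame(
        {"individual_id": ids, "sex": sexes, "site": sites}
    )
    return GenotypeMatrix(genotypes=genotypes, snps=snps, individuals=individuals)


# ---------------------------------------------------------------------------
# tabular inputs
# ---------------------------------------------------------------------------


def write_panel_frequencies(panel: PanelFrequencies, path) -> None:
    df = pd.DataFrame(panel.freqs, columns=panel.labels)
    df.insert(0, "snp_id", panel.snp_ids)
    df.to_csv(path, sep="\t", index=False)


def read_panel_frequencies(path) -> PanelFrequencies:
    df = pd.read_csv(path, sep="\t")
    if "snp_id" not in df.columns or df.shape[1] < 2:
        raise ValueError("panel frequency table needs snp_id plus >=1 ancestry column")
    labels = [c for c in df.columns if c != "snp_id"]
    freqs = df[labels].to_numpy(dtype=float)
    if ((freqs < 0) | (freqs > 1)).any():
        raise ValueError("panel frequencies outside [0, 1]")
    return PanelFrequencies(labels=labels, freqs=freqs, snp_ids=df["snp_id"].to_numpy())


def read_site_table(path) -> pd.DataFrame:
    """CSV with columns site, latitude, longitude (decimal degrees)."""
    df = pd.read_csv(path)
    required = {"site", "latitude", "longitude"}
    if not required.issubset(df.columns):
        raise ValueError(f"site table must have columns {sorted(required)}")
    if df["site"].duplicated().any():
        raise ValueError("duplicate site names in site table")
    if (df["latitude"].abs() > 90).any():
        raise ValueError("latitude outside [-90, 90]")
    if (df["longitude"].abs() > 180).any():
        raise ValueError("longitude outside [-180, 180]")
    return df


def read_haplogroup_table(path) -> pd.DataFrame:
    """TSV with columns individual_id, marker (MT/Y), haplogroup, ancestry."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"individual_id", "marker", "haplogroup", "ancestry"}
    if not required.issubset(df.columns):
        raise ValueError(f"haplogroup table must have columns {sorted(required)}")
    bad = set(df["marker"].unique()) - {"MT", "Y"}
    if bad:
        raise ValueError(f"unknown marker codes: {sorted(bad)}")
    return df


# ---------------------------------------------------------------------------
# quality filtering
# ---------------------------------------------------------------------------


def hwe_chisq_pvalues(
    geno: GenotypeMatrix, min_expected: float = 5.0
) -> np.ndarray:
    """1-df chi-square HWE p-value per autosomal SNP (NaN where exempt/X).

    Observed genotype classes (hom-ref, het, hom-alt) are compared with
    Hardy-Weinberg expectations at the sample allele frequency. SNPs where any
    expected class count falls below `min_expected` are exempted (NaN): the
    chi-square approximation is unreliable there.
    """
    g = geno.genotypes
    pvals = np.full(geno.n_snp, np.nan)
    auto = ~geno.is_x
    for j in np.flatnonzero(auto):
        col = g[:, j]
        col = col[col != MISSING]
        n = col.size
        if n == 0:
            continue
        n2 = int((col == 2).sum())
        n1 = int((col == 1).sum())
        n0 = n - n1 - n2
        p = (2 * n2 + n1) / (2 * n)
        exp = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
        if (exp < min_expected).any():
            continue
        obs = np.array([n0, n1, n2])
        chi2 = float(((obs - exp) ** 2 / exp).sum())
        pvals[j] = stats.chi2.sf(chi2, df=1)
    return pvals


def qc_filter(
    geno: GenotypeMatrix,
    ind_miss_max: float = 0.15,
    snp_miss_max: float = 0.10,
    hwe_alpha: float = 1e-5,
    hwe_min_expected: float = 5.0,
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the standard per-individual / per-SNP missingness and HWE filters.

    Order is fixed: (1) drop individuals with missingness > ind_miss_max,
    (2) drop SNPs with missingness > snp_miss_max among remaining individuals,
    (3) drop autosomal SNPs failing the 1-df chi-square HWE test at
    p < hwe_alpha. Surviving genotype values are never altered.
    """
    for name, thr in (
        ("ind_miss_max", ind_miss_max),
        ("snp_miss_max", snp_miss_max),
        ("hwe_alpha", hwe_alpha),
    ):
        if not 0.0 <= thr <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")

    n_ind0, n_snp0 = geno.n_ind, geno.n_snp
    miss = geno.genotypes == MISSING

    ind_rate = miss.mean(axis=1)
    keep_ind = np.flatnonzero(ind_rate <= ind_miss_max)
    step1 = geno.subset(ind_idx=keep_ind)
    if step1.n_ind == 0:
        raise ValueError("all individuals removed by missingness filter")

    snp_rate = (step1.genotypes == MISSING).mean(axis=0)
    keep_snp = np.flatnonzero(snp_rate <= snp_miss_max)
    step2 = step1.subset(snp_idx=keep_snp)
    n_snp_miss_removed = step1.n_snp - step2.n_snp
    if step2.n_snp == 0:
        raise ValueError("all SNPs removed by missingness filter")

    pvals = hwe_chisq_pvalues(step2, min_expected=hwe_min_expected)
    fail = np.flatnonzero(~np.isnan(pvals) & (pvals < hwe_alpha))
    keep = np.setdiff1d(np.arange(step2.n_snp), fail)
    out = step2.subset(snp_idx=keep)
    if out.n_snp == 0:
        raise ValueError("all SNPs removed by HWE filter")

    report = QcReport(
        individuals_removed=n_ind0 - step1.n_ind,
        snps_removed_missingness=n_snp_miss_removed,
        snps_removed_hwe=len(fail),
        n_ind_before=n_ind0,
        n_snp_before=n_snp0,
        n_ind_after=out.n_ind,
        n_snp_after=out.n_snp,
        ind_miss_max=ind_miss_max,
        snp_miss_max=snp_miss_max,
        hwe_alpha=hwe_alpha,
    )
    return out, report
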