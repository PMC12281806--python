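"""Synthetic admixed cohorts with known sex-biased ground truth.

The generative model is the standard admixture simulation with closed-form
expectations:

* Reference-panel allele frequencies follow the Balding-Nichols model: at each
  SNP an ancestral frequency p ~ U(0.05, 0.95) is drawn once, and each of the
  K source ancestries drifts away from it as Beta(p(1-F)/F, (1-p)(1-F)/F),
  where F is a per-ancestry drift parameter (an Fst against the ancestral
  population).
* Each sampling site is configured with per-ancestry female (f_f) and male
  (f_m) contribution fractions. Under one generation of equilibrium
  transmission an individual's expected autosomal ancestry is (f_f + f_m)/2
  and the expected X-chromosome ancestry is (2 f_f + f_m)/3 (two of every
  three X copies pass through females). Individual vectors are drawn from
  Dirichlet distributions centred on those expectations.
* Genotypes are binomial draws at the individual's mixed allele frequency:
  Binomial(2, .) on autosomes and female X, Binomial(1, .) for the hemizygous
  male X. Mitochondrial ancestry labels are drawn from f_f (maternal line)
  and Y labels, males only, from f_m (paternal line).

Because the expectations are closed-form, every downstream estimator (EM
ancestry proportions, the ΔAdmix sex-bias ratio, MT/Y tallies) can be tested
against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import MISSING, X_CHROM, GenotypeMatrix, PanelFrequencies

FREQ_CLIP = 1e-4

#: chromosome set mimicking the X-matching design: chr1-6 longer than 180 cM,
#: chr7/10/12 approximately X-length, X exactly 180 cM.
DEFAULT_CHROM_LENGTHS_CM = {
    "chr1": 280.0,
    "chr2": 260.0,
    "chr3": 225.0,
    "chr4": 215.0,
    "chr5": 205.0,
    "chr6": 195.0,
    "chr7": 187.0,
    "chr10": 181.0,
    "chr12": 176.0,
    X_CHROM: 180.0,
}


@dataclass
class ContributionConfig:
    """Per-site admixture scenario with sex-specific contribution fractions."""

    site_name: str
    n_individuals: int
    f_female: np.ndarray
    f_male: np.ndarray
    dirichlet_concentration: float = 30.0
    latitude: float = 0.0
    longitude: float = 0.0

    def __post_init__(self) -> None:
        self.f_female = np.asarray(self.f_female, dtype=float)
        self.f_male = np.asarray(self.f_male, dtype=float)
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be positive")
        for name, v in (("f_female", self.f_female), ("f_male", self.f_male)):
            if v.ndim != 1 or ((v < 0) | (v > 1)).any():
                raise ValueError(f"{name} must be a vector of proportions")
            if abs(v.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {v.sum()})")
        if len(self.f_female) != len(self.f_male):
            raise ValueError("f_female and f_male must have the same length")
        if not -90 <= self.latitude <= 90 or not -180 <= self.longitude <= 180:
            raise ValueError("coordinates out of range")

    @property
    def K(self) -> int:
        return len(self.f_female)

    @property
    def expected_q_auto(self) -> np.ndarray:
        """Expected autosomal ancestry: equal parental contributions."""
        return (self.f_female + self.f_male) / 2.0

    @property
    def expected_q_x(self) -> np.ndarray:
        """Expected X ancestry under equilibrium: 2/3 maternal, 1/3 paternal."""
        return (2.0 * self.f_female + self.f_male) / 3.0


def simulate_panel_frequencies(
    K: int,
    n_snps: int,
    fst_drift,
    seed,
    labels: list[str] | None = None,
) -> PanelFrequencies:
    """Balding-Nichols reference panel: K ancestries drifted from one ancestor.

    ``fst_drift`` may be a scalar or a length-K vector of per-ancestry drift
    values in (0, 1). Frequencies are clipped away from {0, 1} so that
    downstream log-likelihoods stay finite. Deterministic given ``seed``.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    fst = np.broadcast_to(np.asarray(fst_drift, dtype=float), (K,)).copy()
    if ((fst <= 0) | (fst >= 1)).any():
        raise ValueError("fst_drift values must lie in (0, 1)")
    if labels is None:
        labels = [f"ANC{k + 1}" for k in range(K)]
    if len(labels) != K:
        raise ValueError("labels length must equal K")

    rng = np.random.default_rng(seed)
    ancestral = rng.uniform(0.05, 0.95, size=n_snps)
    freqs = np.empty((n_snps, K))
    for k in range(K):
        F = fst[k]
        a = ancestral * (1.0 - F) / F
        b = (1.0 - ancestral) * (1.0 - F) / F
        freqs[:, k] = rng.beta(a, b)
    freqs = np.clip(freqs, FREQ_CLIP, 1.0 - FREQ_CLIP)
    snp_ids = np.array([f"snp{j}" for j in range(n_snps)])
    panel = PanelFrequencies(labels=list(labels), freqs=freqs, snp_ids=snp_ids)
    panel.ancestral = ancestral  # kept for outgroup-style contrasts
    return panel


def default_chromosomes(
    n_autosomal_snps: int = 6000, n_x_snps: int = 1500
) -> list[tuple[str, float, int]]:
    """Distribute SNP counts over the default chromosome set, length-weighted."""
    autosomes = {c: l for c, l in DEFAULT_CHROM_LENGTHS_CM.items() if c != X_CHROM}
    total = sum(autosomes.values())
    out = []
    assigned = 0
    items = list(autosomes.items())
    for i, (chrom, length) in enumerate(items):
        if i == len(items) - 1:
            n = n_autosomal_snps - assigned
        else:
            n = int(round(n_autosomal_snps * length / total))
        assigned += n
        out.append((chrom, length, n))
    out.append((X_CHROM, DEFAULT_CHROM_LENGTHS_CM[X_CHROM], n_x_snps))
    return out


def simulate_genetic_map(
    chromosomes: list[tuple[str, float, int]], seed
) -> pd.DataFrame:
    """Uniform-random map positions per chromosome; returns the SNP table.

    Columns: snp_id, chrom, cm, bp. cM positions are sorted uniform draws on
    [0, length]; bp positions are monotone within each chromosome.
    """
    names = [c[0] for c in chromosomes]
    if len(set(names)) != len(names):
        raise ValueError("duplicate chromosome names")
    rng = np.random.default_rng(seed)
    frames = []
    offset = 0
    for chrom, length, n in chromosomes:
        if length <= 0:
            raise ValueError(f"{chrom}: length must be positive")
        if n < 1:
            raise ValueError(f"{chrom}: n_snps must be >= 1")
        cm = np.sort(rng.uniform(0.0, length, size=n))
        # ~1 cM per Mb with jitter; cumulative so bp is strictly increasing
        gaps = np.diff(np.concatenate([[0.0], cm]))
        bp = np.cumsum(gaps * 1e6 * rng.uniform(0.5, 1.5, size=n)).astype(np.int64)
        bp = bp + np.arange(n)  # guard against exact ties
        frames.append(
            pd.DataFrame(
                {
                    "snp_id": [f"snp{offset + j}" for j in range(n)],
                    "chrom": chrom,
                    "cm": cm,
                    "bp": bp,
                }
            )
        )
        offset += n
    return pd.concat(frames, ignore_index=True)


def _dirichlet(rng: np.random.Generator, alpha: np.ndarray, size: int) -> np.ndarray:
    """Dirichlet draws tolerating exact zeros in alpha (zero stays zero)."""
    g = rng.gamma(np.broadcast_to(alpha, (size, len(alpha))))
    total = g.sum(axis=1, keepdims=True)
    # all-zero rows cannot occur for valid configs (alpha sums to c > 0)
    return g / total


def simulate_admixed_cohort(
    panel: PanelFrequencies,
    gmap: pd.DataFrame,
    configs: list[ContributionConfig],
    sex_ratio: float = 0.5,
    seed=0,
    missing_rate: float = 0.0,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Draw a multi-site cohort and its truth table from the generative model.

    Returns the GenotypeMatrix (counted allele = panel allele 'A') and a truth
    table with one row per individual: site, sex, true autosomal and X
    ancestry vectors, and the maternal (MT) and, for males, paternal (Y)
    ancestry labels. ``sex_ratio`` is the expected fraction of males.
    Deterministic given ``seed``.
    """
    if not configs:
        raise ValueError("configs must be non-empty")
    if len(gmap) != panel.n_snp:
        raise ValueError(
            f"map has {len(gmap)} SNPs but panel has {panel.n_snp}"
        )
    K = panel.K
    for cfg in configs:
        if cfg.K != K:
            raise ValueError(
                f"site {cfg.site_name}: config K={cfg.K} != panel K={K}"
            )
    if not 0.0 <= sex_ratio <= 1.0:
        raise ValueError("sex_ratio must lie in [0, 1]")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    on_x = (gmap["chrom"] == X_CHROM).to_numpy()
    P = panel.freqs  # (n_snp, K)

    geno_blocks, ind_rows, truth_rows = [], [], []
    counter = 0
    for cfg in configs:
        n = cfg.n_individuals
        sexes = np.where(rng.random(n) < sex_ratio, "M", "F")
        c = cfg.dirichlet_concentration
        q_auto = _dirichlet(rng, c * cfg.expected_q_auto, n)
        q_x = _dirichlet(rng, c * cfg.expected_q_x, n)

        # per-individual mixed allele frequency at each SNP
        dose_auto = q_auto @ P.T  # (n, n_snp)
        dose_x = q_x @ P.T
        p_mix = np.where(on_x[None, :], dose_x, dose_auto)
        ploidy = np.full((n, panel.n_snp), 2, dtype=np.int16)
        ploidy[np.ix_(sexes == "M", on_x)] = 1
        g = rng.binomial(ploidy, p_mix).astype(np.int16)
        if missing_rate > 0:
            g[rng.random(g.shape) < missing_rate] = MISSING
        geno_blocks.append(g)

        mt = rng.choice(K, size=n, p=cfg.f_female)
        y = rng.choice(K, size=n, p=cfg.f_male)
        for i in range(n):
            iid = f"ind{counter}"
            counter += 1
            ind_rows.append(
                {"individual_id": iid, "sex": sexes[i], "site": cfg.site_name}
            )
            row = {
                "individual_id": iid,
                "site": cfg.site_name,
                "sex": sexes[i],
                "mt_ancestry": panel.labels[mt[i]],
                "y_ancestry": panel.labels[y[i]] if sexes[i] == "M" else "",
            }
            for k, lab in enumerate(panel.labels):
                row[f"q_auto_{lab}"] = q_auto[i, k]
                row[f"q_x_{lab}"] = q_x[i, k]
            truth_rows.append(row)

    snps = gmap.copy().reset_index(drop=True)
    snps["counted_allele"] = "A"
    geno = GenotypeMatrix(
        genotypes=np.vstack(geno_blocks),
        snps=snps,
        individuals=pd.DataFrame(ind_rows),
    )
    truth = pd.DataFrame(truth_rows)
    return geno, truth


def truth_q(truth: pd.DataFrame, labels: list[str], scope: str) -> np.ndarray:
    """Extract (n_ind, K) true ancestry matrix; scope is 'auto' or 'x'."""
    cols = [f"q_{scope}_{lab}" for lab in labels]
    return truth[cols].to_numpy(dtype=float)


def haplogroup_table_from_truth(
    truth: pd.DataFrame, seed=0
) -> pd.DataFrame:
    """Synthesise a haplogroup assignment table consistent with the truth table.

    Haplogroup names are arbitrary synthetic identifiers (one clade per
    ancestry); what matters downstream is the haplogroup -> ancestry mapping.
    """
    rows = []
    for r in truth.itertuples(index=False):
        rows.append(
            {
                "individual_id": r.individual_id,
                "marker": "MT",
                "haplogroup": f"mt-{r.mt_ancestry}",
                "ancestry": r.mt_ancestry,
            }
        )
        if r.sex == "M" and r.y_ancestry:
            rows.append(
                {
                    "individual_id": r.individual_id,
                    "marker": "Y",
                    "haplogroup": f"y-{r.y_ancestry}",
                    "ancestry": r.y_ancestry,
                }
            )
    return pd.DataFrame(rows)


def site_table_from_configs(configs: list[ContributionConfig]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site": [c.site_name for c in configs],
            "latitude": [c.latitude for c in configs],
            "longitude": [c.longitude for c in configs],
            "n": [c.n_individuals for c in configs],
        }
    )
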