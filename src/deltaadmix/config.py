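"""Run configuration: YAML round trip and per-stage seed derivation.

All randomness in a run flows from one master seed. Each stage draws its own
child seed from a fixed (stage -> offset) table via numpy's SeedSequence, so
stages are reproducible independently of which other stages run.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

STAGE_OFFSETS = {
    "simulate": 1,
    "qc": 2,
    "estimate": 3,
    "sexbias": 4,
    "popstats": 5,
    "geo": 6,
    "uniparental": 7,
}


def stage_seed(master_seed: int, stage: str) -> np.random.SeedSequence:
    if stage not in STAGE_OFFSETS:
        raise KeyError(f"unknown stage '{stage}'")
    return np.random.SeedSequence([int(master_seed), STAGE_OFFSETS[stage]])


@dataclass
class SiteConfig:
    name: str
    n_individuals: int
    f_female: list[float]
    f_male: list[float]
    latitude: float = 0.0
    longitude: float = 0.0


@dataclass
class SimulateConfig:
    K: int = 3
    n_snps_autosomal: int = 6000
    n_snps_x: int = 1500
    fst_drift: float = 0.1
    dirichlet_concentration: float = 30.0
    sex_ratio: float = 0.5
    missing_rate: float = 0.0
    #: explicit [name, length_cM, n_snps] rows; None = length-weighted default
    chromosomes: list | None = None
    sites: list[SiteConfig] = field(default_factory=list)


@dataclass
class QcConfig:
    ind_miss_max: float = 0.15
    snp_miss_max: float = 0.10
    hwe_alpha: float = 1e-5


@dataclass
class SexbiasConfig:
    trim_cm: float = 180.0
    n_boot: int = 10000
    alpha: float = 0.05
    #: None = module defaults (chr1-6 trimmed; chr7/10/12 whole)
    trim_chroms: list | None = None
    whole_chroms: list | None = None


@dataclass
class GeoConfig:
    min_n: int = 10
    n_perm: int = 9999


@dataclass
class RunConfig:
    ancestries: list[str]
    seed: int = 0
    outdir: str = "results/run"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    qc: QcConfig = field(default_factory=QcConfig)
    sexbias: SexbiasConfig = field(default_factory=SexbiasConfig)
    geo: GeoConfig = field(default_factory=GeoConfig)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        sim = data.get("simulate", {}) or {}
        sites = [SiteConfig(**s) for s in sim.pop("sites", [])]
        return cls(
            ancestries=list(data["ancestries"]),
            seed=int(data.get("seed", 0)),
            outdir=str(data.get("outdir", "results/run")),
            simulate=SimulateConfig(sites=sites, **sim),
            qc=QcConfig(**(data.get("qc", {}) or {})),
            sexbias=SexbiasConfig(**(data.get("sexbias", {}) or {})),
            geo=GeoConfig(**(data.get("geo", {}) or {})),
        )


def default_study_config(seed: int = 0, outdir: str = "results/run") -> RunConfig:
    """The default synthetic study: 3 sites x 200 individuals, K=3.

    Contribution fractions encode one female-biased ancestry (KS-like,
    f_f=0.6 vs f_m=0.2), one male-biased ancestry (EU-like, f_f=0.2 vs
    f_m=0.6) and one unbiased ancestry, mirroring the qualitative sex-bias
    pattern the method is designed to detect. Sites sit on a west-to-east
    coordinate spread so geographic stages have non-trivial distances.
    """
    f_f = [0.6, 0.2, 0.2]
    f_m = [0.2, 0.6, 0.2]
    sites = [
        SiteConfig("SiteWest", 200, f_f, f_m, latitude=-33.9, longitude=18.6),
        SiteConfig("SiteMid", 200, f_f, f_m, latitude=-33.6, longitude=22.2),
        SiteConfig("SiteEast", 200, f_f, f_m, latitude=-32.3, longitude=24.5),
    ]
    # 6000 autosomal SNPs support three matched X-length autosomes of 2000
    # SNPs each (downsampled to the 1500 X SNPs); the long-chromosome trimming
    # path needs denser maps and is exercised separately
    chromosomes = [
        ["chr7", 187.0, 2000],
        ["chr10", 181.0, 2000],
        ["chr12", 176.0, 2000],
        ["X", 180.0, 1500],
    ]
    return RunConfig(
        ancestries=["KS", "EU", "WA"],
        seed=seed,
        outdir=outdir,
        simulate=SimulateConfig(sites=sites, chromosomes=chromosomes),
        geo=GeoConfig(min_n=10, n_perm=999),
        sexbias=SexbiasConfig(
            n_boot=2000, trim_chroms=[], whole_chroms=["chr7", "chr10", "chr12"]
        ),
    )


def gradient_study_config(
    seed: int = 0,
    outdir: str = "results/gradient",
    n_sites: int = 6,
    n_per_site: int = 60,
) -> RunConfig:
    """A multi-site scenario with a longitudinal ancestry gradient.

    The KS-like component rises and the EU-like component falls from west to
    east, giving the cline and isolation-by-distance stages a real signal to
    recover; the sex bias (f_f vs f_m) is held at the default pattern.
    """
    sites = []
    for i in range(n_sites):
        t = i / (n_sites - 1)
        ks = 0.25 + 0.4 * t
        eu = 0.55 - 0.4 * t
        wa = 1.0 - ks - eu
        # keep the female/male split biased the same way at every site
        f_f = [min(ks + 0.15, 0.9), max(eu - 0.1, 0.02), 0.0]
        f_f[2] = 1.0 - f_f[0] - f_f[1]
        f_m = [max(ks - 0.15, 0.02), min(eu + 0.1, 0.9), 0.0]
        f_m[2] = 1.0 - f_m[0] - f_m[1]
        sites.append(
            SiteConfig(
                f"site{i + 1:02d}",
                n_per_site,
                [round(v, 6) for v in f_f],
                [round(v, 6) for v in f_m],
                latitude=-34.0 + 1.8 * t,
                longitude=18.5 + 6.5 * t,
            )
        )
    chromosomes = [
        ["chr7", 187.0, 1500],
        ["chr10", 181.0, 1500],
        ["chr12", 176.0, 1500],
        ["X", 180.0, 1000],
    ]
    cfg = RunConfig(
        ancestries=["KS", "EU", "WA"],
        seed=seed,
        outdir=outdir,
        simulate=SimulateConfig(sites=sites, chromosomes=chromosomes),
        geo=GeoConfig(min_n=10, n_perm=999),
        sexbias=SexbiasConfig(
            n_boot=1000, trim_chroms=[], whole_chroms=["chr7", "chr10", "chr12"]
        ),
    )
    return cfg
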