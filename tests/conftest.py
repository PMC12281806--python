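import numpy as np
import pytest

from deltaadmix import simdata

LABELS3 = ["KS", "EU", "WA"]
F_FEMALE = np.array([0.6, 0.2, 0.2])
F_MALE = np.array([0.2, 0.6, 0.2])


@pytest.fixture(scope="session")
def small_cohort():
    """Two-site biased cohort with genotypes, sized for fast unit tests."""
    panel = simdata.simulate_panel_frequencies(
        3, 960, 0.1, seed=11, labels=LABELS3
    )
    gmap = simdata.simulate_genetic_map(
        simdata.default_chromosomes(900, 60), seed=12
    )
    configs = [
        simdata.ContributionConfig(
            "west", 40, F_FEMALE, F_MALE, latitude=-33.9, longitude=18.6
        ),
        simdata.ContributionConfig(
            "east", 40, F_FEMALE, F_MALE, latitude=-32.3, longitude=24.5
        ),
    ]
    geno, truth = simdata.simulate_admixed_cohort(
        panel, gmap, configs, seed=13
    )
    return panel, gmap, geno, truth


@pytest.fixture(scope="session")
def truth500():
    """500-individual single-site cohort; genotypes tiny (truth-only checks)."""
    panel = simdata.simulate_panel_frequencies(3, 30, 0.1, seed=21, labels=LABELS3)
    gmap = simdata.simulate_genetic_map([("chr7", 187.0, 20), ("X", 180.0, 10)],
                                        seed=22)
    cfg = simdata.ContributionConfig("only", 500, F_FEMALE, F_MALE)
    geno, truth = simdata.simulate_admixed_cohort(panel, gmap, [cfg], seed=25)
    return panel, cfg, geno, truth
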