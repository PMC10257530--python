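import numpy as np
import pandas as pd
import pytest

from methylsynergy import MethylationCallSet, SimulationTruth
from methylsynergy.simulate import generate_methylome_cohort, plant_regions


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_calls():
    """Small two-chromosome stranded call set."""
    rows = [
        ("chr1", 100, "+", 5, 5),
        ("chr1", 101, "-", 3, 7),
        ("chr1", 301, "-", 2, 8),       # orphan '-' record
        ("chr1", 500, "+", 10, 0),      # orphan '+' record
        ("chr2", 42, "+", 0, 6),
        ("chr2", 43, "-", 1, 5),
    ]
    return MethylationCallSet.from_records("toy", rows)


def make_callset(sample_id, sites, rng, coverage=20, level=0.5):
    """Unstranded call set over (chrom, pos) sites at a fixed level."""
    rows = []
    for chrom, pos in sites:
        cov = int(rng.poisson(coverage)) or 1
        m = int(rng.binomial(cov, level))
        rows.append((chrom, pos, "+", m, cov - m))
    return MethylationCallSet.from_records(sample_id, rows)


@pytest.fixture(scope="session")
def planted_cohort():
    """Session-scoped small cohort with known planted regions (2 groups used)."""
    planted = plant_regions(123, n_hypo=12, n_hyper=4, effect_range=(40, 60),
                            width=800, n_chrom=2, chrom_length=600_000)
    truth = SimulationTruth(seed=123, n_chrom=2, chrom_length=600_000,
                            n_cpgs=6_000, planted_dmrs=planted)
    cohort, truth = generate_methylome_cohort(truth)
    return cohort, truth
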