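import numpy as np
import pandas as pd
import pytest

import walleyeped as w


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete simulated dataset shared across tests."""
    cfg = w.SimConfig(n_adults=200, n_loci=80, seed=1)
    truth, meta, gm = w.simulate_population(cfg)
    return cfg, truth, meta, gm


@pytest.fixture(scope="session")
def clean_sim():
    """Error-free, fully sampled dataset: every parent of every sampled
    offspring is itself genotyped, no missing data."""
    cfg = w.SimConfig(
        n_adults=150,
        n_loci=300,
        genotyping_error_rate=0.0,
        missing_rate=0.0,
        contamination_fraction=0.0,
        duplicate_fraction=0.0,
        adult_capture_prob=1.0,
        juvenile_capture_prob=1.0,
        age1_capture_prob=0.0,
        adult_capture_years=(2017, 2018, 2019, 2020),
        unknown_sex_fraction=0.0,
        seed=7,
    )
    truth, meta, gm = w.simulate_population(cfg)
    return cfg, truth, meta, gm


def truth_assignments(truth, meta):
    """Assignments as if parentage were perfect: the true pedigree restricted
    to offspring sampled as age-0."""
    ped = truth.pedigree.copy()
    sampled = set(meta[meta.stage == "age0"].fish_id)
    ped = ped[ped.offspring_id.isin(sampled)].copy()
    ped["stage"] = "age0"
    return ped


@pytest.fixture(scope="session")
def truth_table(small_sim):
    """Success table built from truth-based assignments on the small sim."""
    _, truth, meta, _ = small_sim
    return w.build_success_table(meta, truth_assignments(truth, meta))


@pytest.fixture()
def tiny_gm():
    """Hand-built 5-sample x 5-locus matrix with known per-locus stats."""
    calls = np.array(
        [
            # L0     L1   L2   L3   L4
            [0, 1, 0, 2, 1],
            [1, 1, 0, 2, 1],
            [1, 1, 0, 0, 1],
            [2, 1, 0, 0, 1],
            [np.nan, 1, 0, 1, 1],
        ],
        dtype=float,
    )
    return w.GenotypeMatrix(
        [f"s{i}" for i in range(5)],
        [f"L{j}" for j in range(5)],
        calls,
        {f"L{j}": f"amp{j}" for j in range(5)},
    )
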