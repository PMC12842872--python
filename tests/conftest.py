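import numpy as np
import pytest

import endoscan as es


@pytest.fixture(scope="session")
def small_cohort():
    """Five groups of 60, 40 null variants plus one planted gradient."""
    cfg = es.SimConfig(
        group_sizes=(60, 60, 60, 60, 60),
        n_null_variants=40,
        planted=(es.PlantedVariant((0.20, 0.20, 0.25, 0.40, 0.40), "grad"),),
        seed=11,
    )
    return es.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def camp_cohort():
    """Discovery-sized cohort (groups 171/154/168/163/177) with a planted
    two-group shift and nulls."""
    cfg = es.SimConfig(
        n_null_variants=200,
        planted=(es.PlantedVariant((0.25, 0.25, 0.25, 0.37, 0.37), "shift"),),
        seed=23,
    )
    return es.simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_sample_table(rng, group_sizes, n_pcs=3):
    """Small random design for oracle comparisons."""
    groups = np.repeat(np.arange(1, len(group_sizes) + 1), group_sizes)
    n = len(groups)
    sex = rng.integers(0, 2, n).astype(float)
    if sex.min() == sex.max():  # avoid a rank-deficient design
        sex[0] = 1.0 - sex[0]
    return es.SampleTable(
        np.array([f"s{i}" for i in range(n)], dtype=object),
        groups,
        rng.normal(9.0, 2.0, n),
        sex,
        rng.standard_normal((n, n_pcs)),
        n_pcs_expected=n_pcs,
    )
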