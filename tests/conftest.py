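import numpy as np
import pytest

from sncfrag.cohort import CohortConfig, generate_cohort
from sncfrag.references import ReferenceConfig, generate_references


@pytest.fixture(scope="session")
def small_refs():
    return generate_references(ReferenceConfig(
        n_nuclear_trna_families=6, n_mito_trna_families=3, n_rrna=2,
        n_yrna=2, n_mirna=4, seed=11))


@pytest.fixture(scope="session")
def small_cohort(small_refs):
    cfg = CohortConfig(
        group_sizes={"HC": 6, "SC": 6, "UC": 6, "CD": 6},
        library_size_range=(60_000, 80_000), seed=7)
    return generate_cohort(small_refs, cfg)


@pytest.fixture(scope="session")
def study_refs():
    """Reference set with the full category structure (300 families)."""
    return generate_references(ReferenceConfig(n_mirna=218, seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
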