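"""Shared fixtures: small simulated twin cohorts with known structure."""

import numpy as np
import pytest

from twinace import biometric_model as bm
from twinace import preprocess as prep
from twinace import synthetic_twins as st


def univariate_paths(a2: float, c2: float, e2: float | None = None) -> bm.PathMatrices:
    e2 = 1.0 - a2 - c2 if e2 is None else e2
    return st.paths_from_structure({"A": [a2], "C": [c2], "E": [e2]}, {})


@pytest.fixture(scope="session")
def ace_univariate():
    """Complete univariate ACE cohort: a2=0.6, c2=0.2, e2=0.2, 5000 pairs/group."""
    cfg = st.SimulationConfig(
        n_pairs_per_group=5000,
        true_paths={"M": univariate_paths(0.6, 0.2), "F": univariate_paths(0.6, 0.2)},
        phenotype_names=("x",),
        seed=11,
    )
    return st.simulate_twin_dataset(cfg)


@pytest.fixture(scope="session")
def two_trait_records():
    """Two-trait cohort with skew and missingness (the small study preset)."""
    return st.simulate_twin_dataset(st.two_trait_config(seed=7, n_pairs_per_group=1500))


@pytest.fixture(scope="session")
def two_trait_prepared(two_trait_records):
    specs = [
        prep.PhenotypeSpec("traits", log_transform=True, extreme_tail="high"),
        prep.PhenotypeSpec("vocabulary", extreme_tail="low"),
    ]
    prepared, _ = prep.preprocess_dataset(two_trait_records, specs)
    return prepared
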