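import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from corticonet import CohortConfig, default_parcellation, generate_cohort


@pytest.fixture(scope="session")
def pmap():
    return default_parcellation()


@pytest.fixture(scope="session")
def null_cohort(pmap):
    """Two groups drawn from one population (no planted effect)."""
    return generate_cohort(pmap, CohortConfig(n_a=30, n_b=15), seed=42)


@pytest.fixture(scope="session")
def deficit_cohort(pmap):
    """Strong executive-language coupling in group A, halved in group B."""
    config = CohortConfig(
        within_r=0.6,
        pair_between_r={("strategic_executive", "language"): 0.30},
        group_b_coupling={("strategic_executive", "language"): 0.5},
    )
    return generate_cohort(pmap, config, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
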