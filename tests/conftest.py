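import numpy as np
import pandas as pd
import pytest

from tcdtyper import CohortConfig, build_tcd_profile, generate_cohort

RECOVERY_SEEDS = (1, 2, 3)


@pytest.fixture(scope="session")
def small_cohort():
    """Planted 4-subtype cohort at the reference study conditions
    (severity effects 0/0.5/1/2 log2, 50 samples per subtype)."""
    return generate_cohort(CohortConfig(samples_per_subtype=50, seed=RECOVERY_SEEDS[0]))


@pytest.fixture(scope="session")
def small_profile(small_cohort):
    return build_tcd_profile(small_cohort.expression, small_cohort.signatures)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_expression():
    """10 genes x (1 tumour + 2 normal) toy matrix with unit normals."""
    genes = [f"g{i}" for i in range(1, 11)]
    values = pd.DataFrame(
        {
            "tum": [3, 2, 1, 0.5, 0.4, 0.1, 1, 1, 1, 1],
            "nrm1": 1.0,
            "nrm2": 1.0,
        },
        index=genes,
    )
    return values
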