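import numpy as np
import pandas as pd
import pytest

from sf_endotyper import preprocess, synthdata


@pytest.fixture(scope="session")
def default_cohort() -> synthdata.SyntheticCohort:
    """Full-size default cohort (708 + 653 samples), generated once."""
    return synthdata.generate_cohort(synthdata.CohortConfig(seed=1))


@pytest.fixture(scope="session")
def small_cohort() -> synthdata.SyntheticCohort:
    """Desk-scale cohort for fast unit tests."""
    config = synthdata.CohortConfig(
        n_discovery=120,
        n_replication=100,
        n_aptamers=120,
        n_intracellular=66,
        seed=11,
    )
    return synthdata.generate_cohort(config)


@pytest.fixture(scope="session")
def small_log_matrix(small_cohort) -> preprocess.AbundanceMatrix:
    return preprocess.log_transform(preprocess.AbundanceMatrix(small_cohort.abundance))


@pytest.fixture()
def toy_matrix() -> preprocess.AbundanceMatrix:
    df = pd.DataFrame(
        np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]),
        index=["s1", "s2"],
        columns=["a1", "a2", "a3"],
    )
    return preprocess.AbundanceMatrix(df)
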