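import warnings

import pytest

from nutric import SyntheticConfig, cohort_to_frame, simulate_cohort

warnings.filterwarnings("ignore", message="Hosmer-Lemeshow group")


@pytest.fixture(scope="session")
def default_records():
    """Reference-sized synthetic cohort (n = 598, seed 0)."""
    return simulate_cohort(SyntheticConfig(n=598, seed=0))


@pytest.fixture(scope="session")
def default_frame(default_records):
    return cohort_to_frame(default_records)


@pytest.fixture(scope="session")
def big_frame():
    """Large cohort for derivation and Monte-Carlo checks."""
    return cohort_to_frame(simulate_cohort(SyntheticConfig(n=5000, seed=1)))
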