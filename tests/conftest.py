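import numpy as np
import pytest
from hypothesis import settings

from hrpfnorms import CohortConfig, LMSTriple, generate_cohort
from hrpfnorms.norms import printed_curves

# property tests explore the same example sequence on every run
settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def boys12_bmi() -> LMSTriple:
    """Published BMI triple for 12-year-old boys."""
    return LMSTriple(0.203, 16.59, 0.141)


@pytest.fixture(scope="session")
def boys12_grip() -> LMSTriple:
    """Published hand-grip triple for 12-year-old boys."""
    return LMSTriple(0.227, 22.53, 0.483)


@pytest.fixture(scope="session")
def curves():
    """Published LMS curves for BMI and hand grip, both sexes."""
    return printed_curves()


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort, shared across tests (2,970 records)."""
    return generate_cohort(CohortConfig(seed=20240601))


def random_triples(rng: np.random.Generator, n: int):
    """Valid LMS triples spanning the realistic parameter range."""
    return [
        LMSTriple(
            float(rng.uniform(-2.0, 2.0)),
            float(rng.uniform(5.0, 120.0)),
            float(rng.uniform(0.05, 0.5)),
        )
        for _ in range(n)
    ]
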