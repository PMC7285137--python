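import numpy as np
import pytest

from pedree import (
    CohortRecipe,
    StudyConfig,
    Subject,
    derive_anthropometry,
    generate_cohort,
    synthetic_growth_reference,
)


@pytest.fixture(scope="session")
def reference():
    return synthetic_growth_reference()


@pytest.fixture(scope="session")
def default_cohort(reference):
    """One default synthetic cohort (2426 subjects), anthropometry derived."""
    cohort = generate_cohort(CohortRecipe(rng_seed=11))
    derive_anthropometry(cohort, reference)
    return cohort


@pytest.fixture
def config():
    return StudyConfig()


@pytest.fixture
def tiny_subjects():
    return [
        Subject(id="a", sex="female", age_years=12.0, weight_kg=45.0, height_cm=150.0,
                mree_kcal_d=1300.0, rq=0.82),
        Subject(id="b", sex="male", age_years=15.5, weight_kg=95.0, height_cm=170.0,
                mree_kcal_d=2000.0, rq=0.85),
        Subject(id="c", sex="f", age_years=16.0, weight_kg=88.0, height_cm=162.0,
                mree_kcal_d=1800.0, rq=0.78),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
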