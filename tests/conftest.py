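import pytest

from dietkidney import CohortConfig, generate_cohort
from dietkidney.pipeline import attach_scores, derive_scores, prepare_sample


@pytest.fixture(scope="session")
def small_cohort():
    """One moderate cohort shared across read-only tests."""
    return generate_cohort(CohortConfig(n_subjects=1500, seed=1))


@pytest.fixture(scope="session")
def prepared(small_cohort):
    tables, report = prepare_sample(small_cohort)
    return tables, report


@pytest.fixture(scope="session")
def derived(prepared):
    tables, _ = prepared
    return derive_scores(tables)


@pytest.fixture(scope="session")
def analysis_frame(prepared, derived):
    tables, _ = prepared
    diet, dash, models, scores = derived
    return attach_scores(tables, diet, dash, scores)
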