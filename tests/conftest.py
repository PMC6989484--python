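import numpy as np
import pytest

import dsidx


def _labels_for(cohort):
    model = dsidx.fit_gfactor(cohort.baseline_tests())
    g0 = dsidx.score_gfactor(model, cohort.baseline_tests())
    g1 = dsidx.score_gfactor(model, cohort.followup_tests())
    return dsidx.label_decline(
        g0,
        g1,
        cohort.data["followup_years"].to_numpy(),
        subject_id=cohort.data["subject_id"].to_numpy(),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Default-config cohort at n=800 for fast unit tests."""
    return dsidx.generate_cohort(dsidx.default_config(n_subjects=800, seed=7))


@pytest.fixture(scope="session")
def small_labels(small_cohort):
    return _labels_for(small_cohort)


@pytest.fixture(scope="session")
def full_cohort():
    """Default-config cohort at the study's sample size (n=2542)."""
    return dsidx.generate_cohort(dsidx.default_config(seed=11))


@pytest.fixture(scope="session")
def full_labels(full_cohort):
    return _labels_for(full_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
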