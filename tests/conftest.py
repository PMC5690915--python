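import numpy as np
import pytest

from setupbudget import CohortTruth, generate_cohort, generate_couch_sag, generate_wl_log
from setupbudget.model import SetupUncertaintyModel


def signflip_pvalue(values, n_resamples=20_000, seed=0):
    """Independent sign-flip resampling oracle for the one-sample location
    test.  Because the sum of squares is flip-invariant, |mean| is a monotone
    function of |t|, so flipping signs of the observed values and comparing
    |mean| reproduces the exact symmetric-null p-value as B -> inf."""
    rng = np.random.default_rng(seed)
    v = np.asarray(values, dtype=float)
    obs = abs(v.mean())
    signs = rng.choice([-1.0, 1.0], size=(n_resamples, v.size))
    resampled = np.abs((signs * v).mean(axis=1))
    return float((resampled >= obs - 1e-12).mean())


@pytest.fixture(scope="session")
def study_truth():
    return CohortTruth(seed=20160508)


@pytest.fixture(scope="session")
def study_cohort(study_truth):
    return generate_cohort(study_truth)


@pytest.fixture(scope="session")
def study_fit(study_truth, study_cohort):
    records, _ = study_cohort
    model = SetupUncertaintyModel(
        records,
        wl_records=generate_wl_log(study_truth, 24),
        couch_records=generate_couch_sag(study_truth),
    )
    return model.fit()
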