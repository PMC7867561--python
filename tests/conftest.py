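import numpy as np
import pytest

import fsdcm


@pytest.fixture(scope="session")
def records():
    """The packaged 19-subject clinical table, validated."""
    return fsdcm.packaged_clinical_table()


@pytest.fixture(scope="session")
def table3(records):
    """Raw fixture frame including the printed composite columns."""
    return fsdcm.packaged_clinical_table(as_records=False)


@pytest.fixture(scope="session")
def ev_table():
    return fsdcm.packaged_explained_variance()


@pytest.fixture(scope="session")
def noisy_subject_posterior():
    """One inversion of a realistic (360-volume) simulated subject."""
    theta = fsdcm.ConnectionParams(0.2, -0.1, 0.1, -0.2)
    ts = fsdcm.generate_subject_series(theta, seed=11)
    return fsdcm.invert_subject(fsdcm.estimate_csd(ts), subject_id="noisy")


def make_posteriors(means, cov=None, prior_var=1.0 / 16.0):
    """Hand-built subject posteriors for group-level tests."""
    means = np.asarray(means, dtype=float)
    if cov is None:
        cov = np.eye(4) * 0.01
    return [
        fsdcm.SubjectPosterior(
            subject_id=str(i + 1), mean=m, covariance=np.array(cov),
            free_energy=0.0, explained_variance_pct=50.0)
        for i, m in enumerate(means)
    ]
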