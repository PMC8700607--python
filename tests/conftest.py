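import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import teafp
from teafp.classification import TEA_CLASSES, paired_plsda_study, preprocess_for_classification

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_dataset():
    """The default 107-sample two-channel study at seed 1."""
    return teafp.generate_dataset(seed=1)


@pytest.fixture(scope="session")
def studies_table(default_dataset):
    """All ten adulteration studies (five teas x two channels)."""
    return teafp.run_all_studies(default_dataset, seed=1)


@pytest.fixture(scope="session")
def preprocessed_samples(default_dataset):
    """Fully pretreated (QC-corrected) sample matrices per channel."""
    return {
        ch: preprocess_for_classification(default_dataset, ch) for ch in ("uv", "fld")
    }


@pytest.fixture(scope="session")
def paired_reports(default_dataset, preprocessed_samples):
    """Calibration/prediction reports of all ten paired PLS-DA models."""
    out = {}
    for ch in ("uv", "fld"):
        for tea in TEA_CLASSES:
            out[(tea, ch)] = paired_plsda_study(
                default_dataset, tea, seed=1, channel=ch,
                preprocessed=preprocessed_samples[ch],
            )
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
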