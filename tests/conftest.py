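import numpy as np
import pytest

from isrfit import (
    FitConfig,
    ModelParams,
    OGTTRecord,
    SecretionParams,
    generate_subject,
    validation_spec,
)
from isrfit.synthetic import VALIDATION_BOUNDS


@pytest.fixture
def secretion_params():
    return SecretionParams(km=0.6, c0=1000.0, alpha=0.01)


@pytest.fixture
def single_params(secretion_params):
    return ModelParams(kind="single", secretion=secretion_params, tau_p=15.0)


@pytest.fixture
def two_comp_params(secretion_params):
    return ModelParams(
        kind="two_compartment", secretion=secretion_params, tau_p=15.0, tau_i=30.0
    )


@pytest.fixture
def ogtt_record():
    """A small clinical-style record in mg/dl with one missing c-peptide entry."""
    times = np.array([-10.0, 0.0, 20.0, 30.0, 60.0, 90.0, 120.0, 150.0, 180.0])
    return OGTTRecord(
        times=times,
        glucose=np.array([90.0, 92.0, 130.0, 145.0, 140.0, 120.0, 108.0, 100.0, 95.0]),
        insulin=np.array([4.0, 5.0, 40.0, 60.0, 55.0, 35.0, 20.0, 10.0, 6.0]),
        cpeptide=np.array([1.2, 1.3, 3.5, 4.8, np.nan, 3.2, 2.4, 1.8, 1.4]),
        subject_id="fixture",
        glucose_unit="mg/dl",
    )


@pytest.fixture(scope="session")
def noiseless_subject():
    """Molar-coupled noiseless synthetic subject at tau_p = 15 min."""
    return generate_subject(validation_spec(15.0, noise_fraction=0.0, seed=11))


@pytest.fixture(scope="session")
def noiseless_ensemble(noiseless_subject):
    from isrfit import fit_ensemble

    config = FitConfig(n_starts=16, seed=5, bounds=VALIDATION_BOUNDS)
    return fit_ensemble(noiseless_subject.record, "insulin", config=config)
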