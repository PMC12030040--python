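import pytest

from pbpkddi import (DosingRegimen, cabotegravir, compute_pk_metrics,
                     reference_subject, simulate)


@pytest.fixture(scope="session")
def ref_subject():
    return reference_subject()


@pytest.fixture(scope="session")
def cab():
    return cabotegravir()


@pytest.fixture(scope="session")
def single_dose_regimen():
    return DosingRegimen(dose=30.0)


@pytest.fixture(scope="session")
def cab_single_dose_profile(cab, ref_subject, single_dose_regimen):
    """Single 30 mg oral dose on the reference subject, 240 h window."""
    return simulate(cab, ref_subject, single_dose_regimen)


@pytest.fixture(scope="session")
def cab_single_dose_metrics(cab_single_dose_profile):
    return compute_pk_metrics(cab_single_dose_profile)
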