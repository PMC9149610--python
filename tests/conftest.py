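import pytest

from nivflow import (
    BloodGasSample,
    PatientRecord,
    PatientStatus,
    VentilatorConfig,
    default_initial_config,
)


def bga(ph=7.40, paco2=50.0, spo2=95.0, taken_at=0.0, on_niv=True):
    return BloodGasSample(ph=ph, paco2=paco2, spo2=spo2,
                          taken_at=taken_at, on_niv=on_niv)


@pytest.fixture
def new_record():
    return PatientRecord(patient_id="P1", status=PatientStatus.NEW)


@pytest.fixture
def recurring_record():
    return PatientRecord(patient_id="P2", status=PatientStatus.RECURRING,
                         stored_night_config=default_initial_config())


@pytest.fixture
def config():
    return default_initial_config()
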