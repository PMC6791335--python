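import copy

import pytest
from hypothesis import HealthCheck, settings

from bioscoop import CohortConfig, generate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def cohort():
    """A mid-sized seeded cohort shared across tests (read-only)."""
    return generate_cohort(CohortConfig(n_records=40, seed=7))


@pytest.fixture(scope="session")
def cohort_docs(cohort):
    return [r.to_doc() for r in cohort]


@pytest.fixture
def valid_doc():
    """A hand-built canonical record with every block populated."""
    return copy.deepcopy({
        "collectionId": "COL-01",
        "dataSource": "donor_questionnaire",
        "donor": {
            "birthDate": "1975-04-12",
            "birthPlace": "Gdansk, Poland",
            "bloodGroup": "A+",
            "ethnicOrigin": "Polish",
            "eyeColour": "blue",
            "hairColour": "brown",
            "residencePlace": "Lodz, Poland",
            "sex": "male",
            "skinTone": "II",
        },
        "anthropometry": {
            "bmi": 22.857143,
            "ci": 13.061224,
            "extras": {"armSpanCm": 176.5},
            "heightCm": 175.0,
            "hipCm": 100.0,
            "waistCm": 80.0,
            "weightKg": 70.0,
            "whr": 0.8,
        },
        "donorId": "DON-0001",
        "medicalEvents": [
            {"eventDate": "2010-05-04", "eventType": "disease", "icd10Code": "J45.1"},
        ],
        "sample": {"materialForm": "serum"},
        "sampleId": "SAM-0001",
        "timestamp": "2019-03-02",
    })
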