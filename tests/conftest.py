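import pytest

from dqmm.synthetic import make_study_fixture, make_study_spec, generate_dataset


@pytest.fixture(scope="session")
def study():
    """Clean two-site transplant-study fixture: (dataset, schema)."""
    return make_study_fixture(seed=1)


@pytest.fixture(scope="session")
def dirty_study():
    """Study fixture with known missing/violation injection: (dataset, truth, spec)."""
    from dqmm.synthetic import (
        GENDER_PATH,
        RECIPIENT_AGE_PATH,
        SITE_PATH,
    )

    spec = make_study_spec(
        seed=7,
        n_rows=1000,
        missing_rate={GENDER_PATH: 0.1},
        violation_rate={RECIPIENT_AGE_PATH: 0.2},
    )
    dataset, truth = generate_dataset(spec)
    return dataset, truth, spec


NESTED_TWO_ROWS = (
    '{"children": [{"name": "composition", "children": ['
    '{"name": "context", "children": [{"name": "health_care_facility", '
    '"children": [{"name": "name", "value": "SiteA"}]}]}]}]}\n'
    '{"children": [{"name": "composition", "children": ['
    '{"name": "context", "children": [{"name": "health_care_facility", '
    '"children": [{"name": "name", "value": "SiteB"}]}]}]}]}\n'
)

FACILITY_PATH = "dataset-row/composition/context/health_care_facility/name"


@pytest.fixture
def two_row_dataset():
    from dqmm.data_model import load_dataset

    return load_dataset(NESTED_TWO_ROWS, format="nested-records")
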