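import pandas as pd
import pytest

from contactprofiler import DiaryDataset, GeneratorConfig, generate


@pytest.fixture
def tiny_dataset() -> DiaryDataset:
    """One subject, two visits (home, work) and two encounters on one day."""
    subjects = pd.DataFrame(
        [{"subject_id": "S01", "age": 30, "sex": "female",
          "household_size": 3, "n_children": 1}]
    )
    visits = pd.DataFrame(
        [
            {"subject_id": "S01", "day": "Wed", "tool": "paper", "visit_id": "v1",
             "setting": "home", "duration_h": 2.0, "n_reach": 2, "n_setting": 3},
            {"subject_id": "S01", "day": "Wed", "tool": "paper", "visit_id": "v2",
             "setting": "work", "duration_h": 8.0, "n_reach": 1, "n_setting": 10},
        ]
    )
    encounters = pd.DataFrame(
        [
            {"subject_id": "S01", "day": "Wed", "tool": "paper", "visit_id": "v1",
             "contact_id": "c1", "duration_h": 0.5, "touch": True},
            {"subject_id": "S01", "day": "Wed", "tool": "paper", "visit_id": "v1",
             "contact_id": "c1", "duration_h": 0.25, "touch": False},
        ]
    )
    return DiaryDataset(subjects=subjects, visits=visits, encounters=encounters)


@pytest.fixture(scope="session")
def default_study():
    """One full synthetic study at the default conditions, fixed seed."""
    dataset, truth = generate(GeneratorConfig(), seed=1)
    return dataset, truth
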