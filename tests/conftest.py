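import numpy as np
import pandas as pd
import pytest

from perigraph.cohort import CohortTable, FeatureSpec, RiskFactorSchema
from perigraph.simulate import SimulationConfig, generate_cohort


@pytest.fixture
def toy_schema():
    return RiskFactorSchema([FeatureSpec("smoker"), FeatureSpec("priorPTB")])


@pytest.fixture
def toy_table(toy_schema):
    """Three patients, two binary features, fully observed."""
    return CohortTable(
        patient_id=pd.Index(["P1", "P2", "P3"], name="patient_id"),
        features=pd.DataFrame({"smoker": [1.0, 0.0, 1.0], "priorPTB": [0.0, 0.0, 1.0]}),
        parity=pd.Series(["parous"] * 3, name="parity"),
        labels=pd.DataFrame({"PTB": [0, 0, 1]}),
        schema=toy_schema,
    )


@pytest.fixture
def toy_csv(tmp_path, toy_table):
    path = tmp_path / "cohort.csv"
    toy_table.write_csv(path)
    return path


@pytest.fixture(scope="session")
def small_cohort():
    """120 patients, 10% planted outliers with a strong feature shift."""
    return generate_cohort(SimulationConfig(
        n_patients=120, prevalence=0.1, n_features=8, n_informative=3,
        effect_delta=0.5, seed=11))


@pytest.fixture(scope="session")
def planted_cohort():
    """The planted-outlier benchmark stratum used for recovery checks."""
    return generate_cohort(SimulationConfig(
        n_patients=500, prevalence=0.1, effect_delta=0.6, seed=0))
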