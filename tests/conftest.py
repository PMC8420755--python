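import numpy as np
import pytest

from cachexpk import (
    CovariateEffect,
    FoceSettings,
    PKParams,
    PopulationModelSpec,
    StudyDesign,
    generate_cohort,
    structural_model_spec,
)
from cachexpk.foce import PKDataset


@pytest.fixture(scope="session")
def table4_structural() -> PopulationModelSpec:
    """Generative population model at the published structural estimates."""
    return structural_model_spec()


@pytest.fixture(scope="session")
def small_arms():
    """Balanced 16-mouse design (2 strains x TF/TB x 2 and 10 mg/kg)."""
    return (
        (1, 0, "2", 2), (1, 1, "2", 2), (1, 0, "10", 2), (1, 1, "10", 2),
        (0, 0, "2", 2), (0, 1, "2", 2), (0, 0, "10", 2), (0, 1, "10", 2),
    )


@pytest.fixture(scope="session")
def structural_cohort_79(table4_structural):
    """One replicate of the structural-model recovery design: 79 mice,
    4 samples each at 1/48/96/168 h, 2 and 10 mg/kg arms."""
    arms = (
        (1, 0, "2", 10), (1, 1, "2", 10), (1, 0, "10", 10), (1, 1, "10", 9),
        (0, 0, "2", 10), (0, 1, "2", 10), (0, 0, "10", 10), (0, 1, "10", 10),
    )
    design = StudyDesign(arms=arms, terminal_h=168.0, artifact_rate=0.0,
                         model=table4_structural)
    return generate_cohort(design, seed=20210)


@pytest.fixture(scope="session")
def structural_dataset_79(structural_cohort_79):
    return PKDataset.from_profiles(structural_cohort_79)


@pytest.fixture
def neutral_init():
    """Generic starting values a modeller would pick without seeing truth."""
    return PopulationModelSpec(
        theta=PKParams(CL=10.0, V1=50.0, Q=30.0, V2=50.0),
        omega2={"CL": 0.1, "V1": 0.1, "V2": 0.1},
        sigma_log=0.2,
    )


@pytest.fixture
def fast_settings():
    return FoceSettings(n_starts=1)
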