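import numpy as np
import pytest

from gmdrpower.analytic import calibrate_covariate_sd
from gmdrpower.data_io import GenotypeDataset, ScenarioSpec
from gmdrpower.simulator import simulate_case_control

#: printed group penetrances of the reference checkerboard configuration
PEN_LOW, PEN_HIGH = 0.073, 0.221


@pytest.fixture(scope="session")
def calibrated_sd() -> float:
    """Covariate SD pinned to the reference group penetrances (0.073, 0.221)."""
    return calibrate_covariate_sd(-5.30, 2.5, 1.0, PEN_LOW, PEN_HIGH)


@pytest.fixture
def toy_dataset() -> GenotypeDataset:
    """4 subjects x 2 markers, balanced, no covariates."""
    return GenotypeDataset(
        subject_ids=["a", "b", "c", "d"],
        phenotype=np.array([1, 1, 0, 0]),
        covariates=np.empty((4, 0)),
        genotypes=np.array([[0, 1], [2, 1], [0, 0], [2, 2]]),
        marker_names=["M1", "M2"],
    )


@pytest.fixture(scope="session")
def fig1_dataset(calibrated_sd):
    """One simulated dataset under the reference checkerboard scenario."""
    spec = ScenarioSpec(
        "checkerboard", maf=0.5, beta_g=2.5, covariate_sd=calibrated_sd,
        n_total=2000, seed=20240001,
    )
    return simulate_case_control(spec)
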