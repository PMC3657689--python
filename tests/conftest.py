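import numpy as np
import pytest

from rehabpower.datagen import GeneratingModel, StudyDesign, simulate_dataset


@pytest.fixture
def mild_model():
    """Well-identified variance components (interior optimum), used where a
    reference implementation must also converge cleanly."""
    return GeneratingModel(
        fixed_intercept=10.0,
        slope_treatment=-1.0,
        sd_intercept=2.0,
        sd_slope=1.0,
        corr_int_slope=-0.4,
        sd_residual=1.0,
    )


@pytest.fixture
def default_model():
    return GeneratingModel()


@pytest.fixture
def small_panel(mild_model):
    """16 subjects x 4 waves, balanced and complete."""
    return simulate_dataset(StudyDesign(8, 4), mild_model, seed=2024)


@pytest.fixture
def rng():
    return np.random.default_rng(11)
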