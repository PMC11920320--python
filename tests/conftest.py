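import numpy as np
import pytest

from osteokinetics import GroundTruth, NoiseSpec, reference_truth_panel
from osteokinetics import reference


@pytest.fixture(scope="session")
def growth_table():
    return reference.growth_parameters()


@pytest.fixture(scope="session")
def proliferation_table():
    return reference.proliferation_rates()


@pytest.fixture(scope="session")
def diffusion_table():
    return reference.diffusion_estimates()


@pytest.fixture(scope="session")
def phenotype_table():
    return reference.phenotype_scores()


@pytest.fixture(scope="session")
def truth_panel():
    return reference_truth_panel()


@pytest.fixture
def hos_truth():
    """Fast-growing line with published-scale parameters."""
    return GroundTruth(
        cell_line_id="HOS",
        alpha=2.1797,
        beta=0.53,
        rho5=1.48,
        rho10=1.58,
        n5=8,
        n10=2,
        D=1.19e-2,
        t_appearance=11.0,
    )


@pytest.fixture
def quiet_noise():
    return NoiseSpec(volume_sigma=0.0, confluence_sigma=0.0, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
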