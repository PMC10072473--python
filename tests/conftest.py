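import numpy as np
import pytest

from synscreen.synthetic import SyntheticScreenSpec, generate_screen


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Small noiseless screen: scores are an exact function of the truth."""
    spec = SyntheticScreenSpec(
        n_cell_lines=6, n_drugs=5, n_genes=60, n_modules=3, noise_sd=0.0, seed=11
    )
    return generate_screen(spec)


@pytest.fixture(scope="session")
def noisy_bundle():
    spec = SyntheticScreenSpec(
        n_cell_lines=10, n_drugs=8, n_genes=80, n_modules=4, noise_sd=2.0, seed=7
    )
    return generate_screen(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
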