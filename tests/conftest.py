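import numpy as np
import pytest

from shiftbench import (
    Spectrum,
    SynthConfig,
    TreeParams,
    generate_truth,
    make_experimental,
    simulate_all,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tree_params():
    return TreeParams()


def make_spectrum(intensities, ppm_max=10.0, ppm_min=0.0, molecule_id="s"):
    return Spectrum(molecule_id, ppm_max, ppm_min, np.asarray(intensities, dtype=float))


@pytest.fixture
def random_spectra(rng):
    """Dense random positive spectra on a shared small grid."""
    return [
        make_spectrum(rng.random(256) + 1e-3, molecule_id=f"r{i}") for i in range(20)
    ]


@pytest.fixture(scope="session")
def small_benchmark():
    """A 20-molecule synthetic benchmark: truths, experimental spectra, clean sims."""
    cfg = SynthConfig(n_molecules=20, seed=7)
    truth = generate_truth(cfg)
    experimental = make_experimental(truth, noise=0.01, seed=7)
    simulated = simulate_all(truth)
    return truth, experimental, simulated
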