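import numpy as np
import pytest

from magbin import GenomeSpec, simulate_community


@pytest.fixture(scope="session")
def small_community():
    """4 genomes x 12 samples, noiseless enough for exact recovery checks."""
    specs = [
        GenomeSpec(id=f"g{i + 1}", length=20_000, gc_target=0.35 + 0.1 * i)
        for i in range(4)
    ]
    truth, depths, coverage = simulate_community(
        specs, n_samples=12, seed=42, scaftig_min=800, scaftig_max=1200, noise_cv=0.0
    )
    return truth, depths, coverage


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
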