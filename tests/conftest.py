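import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fcarchetypes import SynthConfig, simulate_dataset

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_dataset():
    """30 subjects x 4 runs of 24-node connectomes, 2x2 grid, clear signal."""
    cfg = SynthConfig(
        n_subjects=30,
        n_runs=4,
        n_nodes=24,
        block_effect=1.0,
        noise_sd=0.4,
        run_consistency=0.8,
        seed=42,
    )
    cs, truth = simulate_dataset(cfg)
    return cfg, cs, truth


@pytest.fixture(scope="session")
def blob_data():
    """Four well-separated Gaussian blobs (separation >= 6 sd), 5 features."""
    rng = np.random.default_rng(7)
    centers = np.zeros((4, 5))
    centers[1, 0] = centers[3, 0] = 12.0
    centers[2, 1] = centers[3, 1] = 12.0
    X = np.vstack([c + rng.standard_normal((50, 5)) for c in centers])
    labels = np.repeat(np.arange(4), 50)
    perm = rng.permutation(len(labels))
    return X[perm], labels[perm]
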