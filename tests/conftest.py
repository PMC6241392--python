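import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def two_blobs(rng):
    """Two well-separated 2-D Gaussian blobs (~20 sigma apart) with labels."""
    a = rng.normal([0.0, 0.0], 1.0, size=(300, 2))
    b = rng.normal([20.0, 20.0], 1.0, size=(300, 2))
    x = np.vstack([a, b])
    y = np.repeat([0, 1], 300)
    perm = rng.permutation(len(x))
    return x[perm], y[perm]


@pytest.fixture(scope="session")
def default_truth_small():
    """A small default synthetic experiment shared across tests."""
    from plexquant import default_truth, generate_experiment

    truth = default_truth(seed=7, n_events=800)
    samples, _ = generate_experiment(truth)
    return truth, samples


def ingest(samples):
    """Apply the standard ingestion steps to raw in-memory event tables
    (boundary removal with detector bounds, arcsinh on bead channels)."""
    from plexquant import remove_boundary_events, transform_arcsinh
    from plexquant.synthetic import DETECTOR_RANGES

    out = {}
    for name, ev in samples.items():
        ev = remove_boundary_events(
            ev,
            ["FSC-A", "SSC-A"],
            bounds={ch: (None, DETECTOR_RANGES[ch]) for ch in ("FSC-A", "SSC-A")},
        ).copy()
        for ch in ("FL6-H", "FL2-H"):
            ev[ch] = transform_arcsinh(ev[ch].to_numpy())
        out[name] = ev.reset_index(drop=True)
    return out
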