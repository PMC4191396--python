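import numpy as np
import pandas as pd
import pytest

from cgtwist.helimap import HelicalAxisFrames
from cgtwist.presets import get_preset
from cgtwist.synthgen import simulate_coupled_dynamics


@pytest.fixture(scope="session")
def straight_axis():
    return HelicalAxisFrames.straight(12)


@pytest.fixture(scope="session")
def curved_axis():
    """A gently bent axis with consistent tangents, for transform tests."""
    t = np.linspace(0.0, 1.0, 12)
    origins = np.column_stack([3 * np.sin(2 * t), 3 * (1 - np.cos(2 * t)), 37 * t])
    tangents = np.gradient(origins, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    refs = np.cross(tangents, [0.0, 1.0, 0.2])
    refs /= np.linalg.norm(refs, axis=1, keepdims=True)
    return HelicalAxisFrames(np.arange(12), origins, tangents, refs)


@pytest.fixture(scope="session")
def tcga_run():
    """One medium-length coupled trajectory at the TCGA-K study conditions,
    shared across tests that only read it."""
    params = get_preset("TCGA-K")
    snapshots, ions, truth = simulate_coupled_dynamics(params, 100_000, seed=1234)
    return params, snapshots, ions, truth


def random_records(rng, n, d_range=(0.5, 10.5), r_range=(0.0, 14.0)):
    return pd.DataFrame(
        {
            "snapshot": np.zeros(n, dtype=int),
            "ion_id": np.arange(n),
            "species": "K+",
            "D": rng.uniform(*d_range, n),
            "R_A": rng.uniform(*r_range, n),
            "A_deg": rng.uniform(0.0, 360.0, n),
        }
    )
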