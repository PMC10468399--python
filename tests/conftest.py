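import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True)
settings.load_profile("reproducible")

from rhpkit.alphabet import PSEUDO_CLASS_HLB, sequence_hlb
from rhpkit.latent_model import ModelConfig, train
from rhpkit.sequence_io import extract_windows_many
from rhpkit.synthetic_data import make_benchmark_pair


@pytest.fixture(scope="session")
def benchmark_pair():
    """Small membrane-like / globular-like family pair (seeded)."""
    return make_benchmark_pair(seed=11, n_sequences=100)


@pytest.fixture(scope="session")
def benchmark_windows(benchmark_pair):
    membrane, globular = benchmark_pair
    ws = extract_windows_many(membrane + globular)
    labels = np.array([sequence_hlb(w.letters, PSEUDO_CLASS_HLB)[1] for w in ws])
    groups = np.array(
        ["membrane" if w.parent_id.startswith("membrane") else "globular" for w in ws]
    )
    return ws, labels, groups


@pytest.fixture(scope="session")
def small_trained_model(benchmark_windows):
    """A briefly trained latent model shared across tests."""
    ws, labels, groups = benchmark_windows
    cfg = ModelConfig(max_epochs=25, seed=7)
    model, hist = train(ws, labels, cfg, groups=groups)
    return model, hist, ws, labels, groups
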