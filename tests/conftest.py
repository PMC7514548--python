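import numpy as np
import pytest

from capscore.capsim import SimParams, make_dataset, to_subject_data


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_corpus():
    """Two short, strongly separable synthetic subjects."""
    return [to_subject_data(s)
            for s in make_dataset(2, 600, SimParams(snr=4.0), seed=42)]


@pytest.fixture(scope="session")
def separable_epochs(small_corpus):
    """Flat epoch matrix + labels pooled over the small corpus."""
    x = np.concatenate([d.epochs for d in small_corpus])
    y = np.concatenate([d.phase_labels for d in small_corpus])
    rid = np.concatenate([np.full(d.phase_labels.size, i)
                          for i, d in enumerate(small_corpus)])
    return x, y, rid
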