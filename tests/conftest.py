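import numpy as np
import pytest
from hypothesis import settings

import succpred as sp

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def motif_fixture():
    """Synthetic succinylome with the default planted motif (100/300 sites)."""
    proteins, annotations = sp.generate_succinylome(
        n_proteins=60, mean_length=400, n_pos_sites=100, n_neg_sites=300,
        seed=11)
    windows = sp.extract_windows(proteins, annotations,
                                 negatives_from_unannotated=False)
    y = np.array([1 if w.label == "positive" else 0 for w in windows])
    return proteins, annotations, windows, y


@pytest.fixture(scope="session")
def pos_neg_windows(motif_fixture):
    _, _, windows, y = motif_fixture
    pos = [w for w, t in zip(windows, y) if t == 1]
    neg = [w for w, t in zip(windows, y) if t == 0]
    return pos, neg


@pytest.fixture(scope="session")
def make_random_windows():
    """Factory for random 31-mer windows (K center, optional pad prefix)."""
    letters = np.array(list(sp.seqio.STANDARD_AA))

    def _make(n, seed=0, n_flank=15, pad_some=False):
        rng = np.random.default_rng(seed)
        out = []
        for i in range(n):
            chars = rng.choice(letters, size=2 * n_flank + 1)
            chars[n_flank] = "K"
            s = "".join(chars)
            if pad_some and i % 3 == 0:
                cut = int(rng.integers(1, n_flank))
                s = "-" * cut + s[cut:]
            out.append(s)
        return out

    return _make


@pytest.fixture(scope="session")
def fitted_aac_model(motif_fixture):
    """A small fitted AAC-only classifier shared by prediction tests."""
    _, _, windows, y = motif_fixture
    clf = sp.SuccinylationSiteClassifier(feature_set="AAC", random_state=7)
    return clf.fit(windows, y)
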