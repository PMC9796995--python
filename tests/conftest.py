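import numpy as np
import pytest

from fluencylab.phonological import bundled_lexicon
from fluencylab.semantic import EmbeddingLexicon, bundled_embeddings


@pytest.fixture(scope="session")
def pron_lex():
    return bundled_lexicon()


@pytest.fixture(scope="session")
def emb_lex():
    return bundled_embeddings()


@pytest.fixture()
def toy_emb():
    """Tiny 2-d embedding with known geometry."""
    return EmbeddingLexicon(
        {
            "east": np.array([1.0, 0.0]),
            "north": np.array([0.0, 1.0]),
            "west": np.array([-1.0, 0.0]),
            "northeast": np.array([1.0, 1.0]),
        }
    )


def constant_angle_embedding(theta_deg: float, n_words: int = 5):
    """Words whose consecutive vectors turn by exactly theta_deg."""
    words = [f"w{i}" for i in range(n_words)]
    vecs = {}
    for i, w in enumerate(words):
        a = np.radians(theta_deg * i)
        vecs[w] = np.array([np.cos(a), np.sin(a)])
    return words, EmbeddingLexicon(vecs)
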