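import numpy as np
import pytest

from mtlscreen.preprocess import UserDocument

# Crowdsource-vs-expert 4x4 risk confusion counts (rows expert, columns
# crowdsource; order none/low/moderate/severe) used by the agreement tests.
TABLE2 = np.array(
    [
        [29, 1, 1, 5],
        [11, 13, 20, 6],
        [6, 11, 47, 51],
        [1, 1, 8, 34],
    ],
    dtype=np.int64,
)

# Per-risk-level train/test counts of the assembled suicide-risk corpus.
TRAIN_LEVEL_COUNTS = {"none": 127, "low": 50, "moderate": 113, "severe": 206}
TEST_LEVEL_COUNTS = {"none": 32, "low": 13, "moderate": 28, "severe": 52}


def make_doc(user_id: str, tokens, label=None) -> UserDocument:
    return UserDocument(user_id=user_id, tokens=list(tokens), label=label)


def make_docs(n: int, label, prefix: str, n_tokens: int = 5):
    return [
        make_doc(f"{prefix}{i:04d}", [f"tok{i}_{j}" for j in range(n_tokens)], label)
        for i in range(n)
    ]


@pytest.fixture
def table2():
    return TABLE2.copy()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
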