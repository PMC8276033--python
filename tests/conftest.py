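import numpy as np
import pytest

from ersnet.model import ModelConfig, SecretionRecord
from ersnet.tails import ALPHABET, TailSequence


def random_tail(rng: np.random.Generator) -> TailSequence:
    return TailSequence("".join(ALPHABET[i] for i in rng.integers(0, 20, size=7)))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_tails(rng):
    def _make(n: int) -> list[TailSequence]:
        return [random_tail(rng) for _ in range(n)]

    return _make


@pytest.fixture
def tiny_config():
    """Small, fast config for tests that exercise mechanics, not accuracy."""
    return ModelConfig(hidden_size=8, fc_width=4, dropout_rate=0.2,
                       iterations=30, seed=7)


@pytest.fixture
def small_records(rng, random_tails):
    tails = random_tails(24)
    responses = rng.uniform(0.2, 5.0, size=24)
    return [SecretionRecord(t, float(r)) for t, r in zip(tails, responses)]


# Five-protein FASTA fixture: 4 long proteins (one tail with 'X', two sharing
# TAEKDEL, one with a trailing stop) and 1 short protein -> expected counters
# 3 retained / 2 unique / 1 length-rejected / 1 alphabet-rejected.
FIVE_PROTEIN_FASTA = """\
>p1 endoplasmin-like
MSKEEAQRLAKEFGITAEKDEL
>p2 tail with ambiguity code
MAAAAAAAAAAAAGGXSLEL
>p3 short peptide
MKTAY
>p4 BiP-like, stop codon retained
MDEKKRLAYAAGITAEKDEL*
>p5 divergent tail
MLLQERTWGVAPLLIGSLEL
"""


@pytest.fixture
def five_protein_fasta(tmp_path):
    path = tmp_path / "five.faa"
    path.write_text(FIVE_PROTEIN_FASTA)
    return path
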