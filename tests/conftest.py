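import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from mirms import Oligo


@pytest.fixture
def let7a():
    return Oligo("UGAGGUAGUAGGUUGUAUAGUU")


@pytest.fixture
def mir17():
    return Oligo("CAAAGUGCUUACAGUGCAGGUAG")


@pytest.fixture
def mir200c():
    return Oligo("UAAUACUGCCGGGUAAUGAUGGA")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_sequence(rng, length, alphabet="ACGU"):
    return "".join(rng.choice(list(alphabet), size=length))
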