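import numpy as np
import pytest

from lineakit.haplogroups import HaplogroupTree
from lineakit.reference import synthetic_reference


@pytest.fixture(scope="session")
def reference() -> str:
    return synthetic_reference()


@pytest.fixture(scope="session")
def hg_tree() -> HaplogroupTree:
    return HaplogroupTree.default()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_sequence(rng: np.random.Generator, n: int, missing: float = 0.0) -> str:
    chars = np.array(list("ACGT"))
    seq = chars[rng.integers(0, 4, n)]
    if missing:
        mask = rng.random(n) < missing
        seq[mask] = np.where(rng.random(mask.sum()) < 0.5, "N", "-")
    return "".join(seq)
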