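import numpy as np
import pytest

from errantiscan import longread, synthetic_data
from errantiscan.formats import SequenceRecord

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


@pytest.fixture(scope="session")
def te():
    """A small-seeded TE consensus shared across tests."""
    return synthetic_data.gen_te_consensus(seed=7)


@pytest.fixture(scope="session")
def catalog():
    return longread.default_catalog()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def embed(te, catalog, variant, rng, flank=1000, deletion=None, subst_rate=0.0):
    """One read = flank + LTR + variant-internal + LTR + flank."""
    element = (
        te.ltr.sequence
        + catalog.apply(variant, te.internal.sequence, deletion)
        + te.ltr.sequence
    )
    seq = random_seq(rng, flank) + element + random_seq(rng, flank)
    if subst_rate > 0:
        arr = list(seq)
        for i in np.flatnonzero(rng.random(len(arr)) < subst_rate):
            choices = [b for b in "ACGT" if b != arr[i]]
            arr[i] = choices[int(rng.integers(0, 3))]
        seq = "".join(arr)
    return SequenceRecord(f"read_{variant}", seq)
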