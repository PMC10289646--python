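import numpy as np
import pytest

from amphiprof.physchem import profile_record
from amphiprof.sequence_io import AHRecord

# In-text fixture peptides: the wild-type N-terminal 24-mer, its first 18
# residues, and the 5W mutant (V4, V8, A12, V15, A16 -> W).
WT_24 = "MQNVINTVKGKALEVAEYLTPVLK"
WT_18 = WT_24[:18]
FIVE_W_POSITIONS = (4, 8, 12, 15, 16)
FIVE_W_24 = "".join(
    "W" if i + 1 in FIVE_W_POSITIONS else aa for i, aa in enumerate(WT_24)
)


@pytest.fixture
def wt_record():
    return AHRecord(id="hATG3_1-24", sequence=WT_24, family="ATG3", phylum="Chordata")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_sequence(rng, length):
    from amphiprof.physchem import AMINO_ACIDS

    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


@pytest.fixture
def small_profiles(rng):
    seqs = [random_sequence(rng, int(n)) for n in rng.integers(8, 30, size=6)]
    return [profile_record(AHRecord(id=f"s{i}", sequence=s)) for i, s in enumerate(seqs)]
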