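from __future__ import annotations

import numpy as np
import pytest

from crmsearch.core import FeatureInstance, InstanceIndex, Sequence, SequenceSet

BASES = "ACGT"


def make_set(label, items):
    """items: list of (id, residues)."""
    return SequenceSet(label, [Sequence(id=i, residues=r) for i, r in items])


def random_dna(rng, n, gc=0.5, alphabet="ACGT"):
    if alphabet == "ACGT":
        p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        return "".join(BASES[i] for i in rng.choice(4, size=n, p=p))
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=n))


def index_of(instances, sset=None):
    idx = InstanceIndex(sequence_set=sset)
    for inst in instances:
        idx.add(inst)
    return idx


def inst(seq, start, end, feature, strand="+", score=None):
    return FeatureInstance(seq=seq, start=start, end=end, feature=feature,
                           strand=strand, score=score)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
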