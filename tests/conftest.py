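import numpy as np
import pandas as pd
import pytest

from phylogeo.seqdata import Alignment, HaplotypeTable, encode_sequence


def make_alignment(seqs: dict[str, tuple[str, str]]) -> Alignment:
    """Alignment from {individual: (population, sequence)}."""
    ids = list(seqs)
    pops = [seqs[i][0] for i in ids]
    matrix = np.vstack([encode_sequence(seqs[i][1], i) for i in ids])
    meta = pd.DataFrame({"population_id": pops},
                        index=pd.Index(ids, name="individual_id"))
    return Alignment(ids=ids, populations=pops, matrix=matrix, meta=meta)


@pytest.fixture
def small_alignment() -> Alignment:
    return make_alignment({
        "a1": ("P1", "AAAAACGTCG"),
        "a2": ("P1", "AAAAACGTCG"),
        "a3": ("P1", "AATAACGTCG"),
        "b1": ("P2", "AATAACGTTG"),
        "b2": ("P2", "CATAACGTTG"),
    })


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
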