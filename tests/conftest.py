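import numpy as np
import pytest
from hypothesis import settings

from mitopop.alignment import AlignedSequenceSet

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_aln(seqs: dict[str, str], ages: dict[str, float] | None = None,
             partitions=None) -> AlignedSequenceSet:
    """Build an alignment from {id: sequence} for toy tests."""
    ids = list(seqs)
    matrix = np.array([list(s) for s in seqs.values()], dtype="U1")
    age_arr = np.array([(ages or {}).get(i, 0.0) for i in ids])
    return AlignedSequenceSet(ids=ids, matrix=matrix, ages=age_arr,
                              partitions=partitions or {})


@pytest.fixture
def toy_aln():
    """Six sequences, three distinct haplotypes with multiplicities 3, 2, 1."""
    return make_aln({
        "a1": "ACGTACGTAC",
        "a2": "ACGTACGTAC",
        "a3": "ACGTACGTAC",
        "b1": "ACGTACGTAT",
        "b2": "ACGTACGTAT",
        "c1": "ACGAACGTAT",
    })


@pytest.fixture(scope="session")
def small_fixture():
    """A scaled-down study-design bundle, shared across tests."""
    from mitopop.simulate import make_study_fixture

    return make_study_fixture(seed=2024, scale=0.25)
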