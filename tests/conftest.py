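import numpy as np
import pytest

from smallrna import syndata
from smallrna.annotate import ReferenceIndex


@pytest.fixture(scope="session")
def table4():
    return syndata.load_table4_fixture()


@pytest.fixture(scope="session")
def reference(table4):
    """Small synthetic reference shared across tests (pure function of seed)."""
    return syndata.build_reference(table4, n_decoys=24, seed=0)


@pytest.fixture(scope="session")
def ref_index(reference):
    return ReferenceIndex(reference)


@pytest.fixture()
def rng():
    return np.random.default_rng(1)


def naive_scan(query, records):
    """Brute-force O(n*m) substring oracle used against align_exact."""
    hits = []
    for rec in records:
        start = 0
        while (idx := rec.sequence.find(query, start)) != -1:
            hits.append((rec.id, idx))
            start = idx + 1
    return sorted(hits)


def random_dna(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
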