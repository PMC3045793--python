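import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nullbench as nb

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def seq():
    def make(residues: str, id: str = "x") -> nb.NucleotideSequence:
        return nb.NucleotideSequence(id=id, residues=residues)

    return make


@pytest.fixture
def point_mass_wam():
    """WAM assigning probability 1 to ACGAG."""
    return nb.fit_wam([nb.NucleotideSequence("t", "ACGAG")], order=1, pseudocount=0.0)


@pytest.fixture
def random_wam():
    """A moderate random order-1 WAM of length 12 (all probabilities positive)."""
    rng = np.random.default_rng(7)
    dists = []
    for p in range(12):
        n_ctx = 4 ** min(p, 1)
        dists.append(rng.dirichlet([4.0] * 4, size=n_ctx))
    return nb.WAMModel(dists=dists, order=1, pseudocount=0.0)


@pytest.fixture(scope="session")
def stratified_100():
    """The length-100 stratified random set at the default 50 per mark."""
    return nb.generate_gc_stratified(50, 100, seed=42)


def all_kmers(k: int):
    """Every ACGT k-mer as a NucleotideSequence (exhaustive oracle input)."""
    from itertools import product

    return [
        nb.NucleotideSequence(id="".join(p), residues="".join(p))
        for p in product("ACGT", repeat=k)
    ]
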