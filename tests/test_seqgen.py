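"""Stratified generator: composition exactness, count law, pruning, sampling."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import nullbench as nb
from nullbench.sequence import gc_mark


def expected_marks(length: int, cons_len: int = 0, cons_gc: int = 0) -> set[int]:
    """Brute-force oracle: marks reached by batches j=0..100."""
    l_free = length - cons_len
    return {
        gc_mark((l_free * j) // 100 + cons_gc, length) for j in range(101)
    }


class TestCountLaw:
    @pytest.mark.parametrize(
        "length,consensus,expected_total",
        [
            (62, None, 3150),
            (100, None, 5050),
            (70, nb.ConsensusSpec(49, "AG"), 3450),
        ],
    )
    def test_printed_set_sizes(self, length, consensus, expected_total):
        data = nb.generate_gc_stratified(50, length, seed=3, consensus=consensus)
        assert len(data) == expected_total
        assert data.occupied_marks.size * 50 == expected_total

    def test_minimal_example_enumerates_exactly(self):
        # N=1, L=4: K1 = floor(4*j/100) takes values 0..4, marks 0,25,50,75,100
        data = nb.generate_gc_stratified(1, 4, seed=0)
        assert len(data) == 5
        assert set(data.marks.tolist()) == {0, 25, 50, 75, 100}
        gc = [s.gc_count for s in data.sequences()]
        assert sorted(gc) == [0, 1, 2, 3, 4]

    @given(
        length=st.integers(min_value=1, max_value=500),
        n=st.integers(min_value=1, max_value=3),
    )
    def test_total_matches_bruteforce_enumeration(self, length, n):
        data = nb.generate_gc_stratified(n, length, seed=1)
        marks = expected_marks(length)
        assert len(data) == n * len(marks)
        assert set(data.occupied_marks.tolist()) == marks
        counts = np.bincount(data.marks, minlength=101)
        assert set(counts[counts > 0].tolist()) == {n}


class TestComposition:
    def test_exact_gc_count_per_batch(self):
        data = nb.generate_gc_stratified(4, 53, seed=9)
        counts = data.counts()
        gc = counts[:, 1] + counts[:, 2]
        for i, sid in enumerate(data.ids):
            j = int(sid.split("_")[1])
            assert gc[i] == (53 * j) // 100

    def test_consensus_inserted_and_counted(self):
        cons = nb.ConsensusSpec(3, "AG")
        data = nb.generate_gc_stratified(2, 10, seed=5, consensus=cons)
        for s in data.sequences():
            assert s.residues[2:4] == "AG"
        counts = data.counts()
        gc = counts[:, 1] + counts[:, 2]
        for i, sid in enumerate(data.ids):
            j = int(sid.split("_")[1])
            assert gc[i] == (8 * j) // 100 + 1  # free GC + the consensus G

    def test_marks_recoverable_from_sequences(self):
        data = nb.generate_gc_stratified(3, 70, seed=2, consensus=nb.ConsensusSpec(49, "AG"))
        recomputed = [s.mark for s in data.sequences()]
        assert recomputed == data.marks.tolist()

    def test_alphabet_is_strict(self):
        data = nb.generate_gc_stratified(2, 25, seed=8)
        for s in data.sequences():
            assert set(s.residues) <= set("ACGT")
            assert len(s) == 25


class TestDeterminismAndErrors:
    def test_same_seed_identical_bytes(self):
        a = nb.generate_gc_stratified(3, 40, seed=11, consensus=nb.ConsensusSpec(5, "AG"))
        b = nb.generate_gc_stratified(3, 40, seed=11, consensus=nb.ConsensusSpec(5, "AG"))
        assert np.array_equal(a.codes, b.codes)
        assert a.ids == b.ids

    def test_different_seed_differs(self):
        a = nb.generate_gc_stratified(3, 40, seed=1)
        b = nb.generate_gc_stratified(3, 40, seed=2)
        assert not np.array_equal(a.codes, b.codes)

    @pytest.mark.parametrize("n,length", [(0, 10), (-1, 10), (5, 0)])
    def test_nonpositive_parameters_rejected(self, n, length):
        with pytest.raises(ValueError):
            nb.generate_gc_stratified(n, length, seed=0)

    def test_consensus_exceeding_length_rejected(self):
        with pytest.raises(ValueError):
            nb.generate_gc_stratified(2, 5, seed=0, consensus=nb.ConsensusSpec(5, "AG"))


class TestSampleFamily:
    def test_point_mass_model_yields_copies(self, point_mass_wam):
        seqs = nb.sample_family(point_mass_wam, 3, seed=0)
        assert [s.residues for s in seqs] == ["ACGAG"] * 3

    def test_gc_half_model_empirical_gc(self):
        # i.i.d.-equivalent WAM with P(G)=P(C)=0.5: GC fraction ~ Binomial mean 1.0...
        # here all bases are G or C, so every sequence is 100% GC
        dists = [np.tile([0.0, 0.5, 0.5, 0.0], (4 ** min(p, 1), 1)) for p in range(30)]
        model = nb.WAMModel(dists=dists, order=1, pseudocount=0.0)
        seqs = nb.sample_family(model, 1000, seed=4)
        gc = np.mean([s.gc_fraction for s in seqs])
        assert gc == 1.0

    def test_iid_equivalent_wam_gc_within_three_se(self):
        g = 0.3
        row = [(1 - g) / 2, g / 2, g / 2, (1 - g) / 2]
        dists = [np.tile(row, (4 ** min(p, 1), 1)) for p in range(30)]
        model = nb.WAMModel(dists=dists, order=1, pseudocount=0.0)
        seqs = nb.sample_family(model, 1000, seed=4)
        gc = np.mean([s.gc_fraction for s in seqs])
        se = np.sqrt(g * (1 - g) / (30 * 1000))
        assert abs(gc - g) < 3 * se

    def test_zero_samples_rejected(self, point_mass_wam):
        with pytest.raises(ValueError):
            nb.sample_family(point_mass_wam, 0, seed=0)


class TestSyntheticAcceptorWam:
    def test_average_gc_tracks_request(self):
        for g in (0.38, 0.5, 0.65):
            model = nb.make_synthetic_acceptor_wam(
                g, length=70, consensus=nb.ConsensusSpec(49, "AG"), seed=1
            )
            # consensus AG contributes 1 G over 70 positions; Dirichlet noise is mild
            assert abs(model.average_gc() - g) < 0.06

    def test_consensus_positions_are_point_mass(self):
        model = nb.make_synthetic_acceptor_wam(
            0.5, length=10, consensus=nb.ConsensusSpec(3, "AG"), seed=0
        )
        assert np.allclose(model.dists[2][:, 0], 1.0)  # A
        assert np.allclose(model.dists[3][:, 2], 1.0)  # G
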