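"""Log-odds scoring and the null-swap identity."""

import numpy as np
import pytest

import nullbench as nb
from nullbench.scoring import UndefinedScoreError, score_dataset
from tests.conftest import all_kmers

SIX_NULLS = [
    nb.make_fixed_gc(0.05),
    nb.make_fixed_gc(0.25),
    nb.make_uniform(),
    nb.make_fixed_gc(0.75),
    nb.make_fixed_gc(0.95),
    nb.TARGET,
]


class TestLogOdds:
    def test_identical_family_and_null_scores_zero(self, seq):
        u = nb.make_uniform()
        for s in ("ACGT", "GGGG", "ATATAT"):
            assert nb.log_odds(seq(s), u, u).log_odds == 0.0

    def test_direct_arithmetic(self, seq):
        rec = nb.log_odds(seq("GGCC"), nb.make_fixed_gc(0.75), nb.make_uniform())
        assert rec.log_odds == pytest.approx(4 * np.log2(1.5))
        assert rec.positive

    def test_zero_score_classified_negative(self, seq):
        rec = nb.log_odds(seq("ACGT"), nb.make_uniform(), nb.make_uniform())
        assert rec.log_odds == 0.0 and not rec.positive

    def test_record_consistency(self, seq, random_wam):
        x = seq("ACGTACGTACGT")
        rec = nb.log_odds(x, random_wam, nb.make_fixed_gc(0.3))
        assert rec.log_odds == pytest.approx(rec.family_bits - rec.null_bits)
        assert rec.mark == x.mark

    def test_target_null_dominates_fixed_nulls_exhaustively(self, seq):
        """S_target <= S_fixed for every 4-mer and every family model."""
        fams = [nb.make_fixed_gc(0.3), nb.make_fixed_gc(0.8)]
        for x in all_kmers(4):
            for fam in fams:
                s_target = nb.log_odds(x, fam, nb.TARGET).log_odds
                for gc in (0.05, 0.25, 0.5, 0.75, 0.95):
                    s_fixed = nb.log_odds(x, fam, nb.make_fixed_gc(gc)).log_odds
                    assert s_target <= s_fixed + 1e-12

    def test_double_minus_inf_raises(self, seq):
        with pytest.raises(UndefinedScoreError):
            nb.log_odds(seq("GA"), nb.make_fixed_gc(0.0), nb.make_fixed_gc(1.0))


class TestSwapNull:
    def test_uniform_is_identity(self, seq):
        x = seq("ACGTTGCA")
        assert nb.swap_null(3.25, x, nb.make_uniform()) == pytest.approx(3.25)

    def test_direct_arithmetic(self, seq):
        s = nb.swap_null(0.0, seq("GGGG"), nb.make_fixed_gc(0.95))
        assert s == pytest.approx(4 * np.log2(0.25 / 0.475))

    def test_round_trip_against_direct_scoring(self, seq, random_wam):
        """swap_null(uniform log-odds) reproduces direct scoring for every null."""
        rng = np.random.default_rng(2)
        xs = [
            nb.NucleotideSequence.from_codes(
                f"x{i}", rng.integers(0, 4, size=12, dtype=np.uint8)
            )
            for i in range(25)
        ]
        families = [random_wam, nb.make_fixed_gc(0.4)]
        for x in xs:
            for fam in families:
                s_u = nb.log_odds(x, fam, nb.make_uniform()).log_odds
                for null in SIX_NULLS:
                    direct = nb.log_odds(x, fam, null).log_odds
                    assert nb.swap_null(s_u, x, null) == pytest.approx(
                        direct, abs=1e-9
                    )

    def test_zero_probability_null_flagged_degenerate(self, seq):
        with pytest.warns(RuntimeWarning, match="degenerate"):
            s = nb.swap_null(0.0, seq("GA"), nb.make_fixed_gc(1.0))
        assert s == np.inf


class TestScoreDataset:
    def test_cardinality_and_ordering(self):
        data = nb.generate_gc_stratified(1, 4, seed=0)  # 5 sequences
        df = score_dataset(data, nb.make_uniform(), [nb.make_uniform(), nb.TARGET])
        assert len(df) == 10
        key = list(zip(df["mark"], df["id"], df["null_label"]))
        assert key == sorted(key)

    def test_target_null_with_uniform_family_never_positive(self, stratified_100):
        df = score_dataset(stratified_100, nb.make_uniform(), [nb.TARGET])
        assert (df["log_odds"] <= 0).all()
        assert not df["positive"].any()

    def test_per_mark_mean_monotone_under_fixed_null(self, stratified_100):
        """i.i.d. family + fixed-GC null: per-mark mean S is exactly monotone."""
        df = score_dataset(
            stratified_100, nb.make_fixed_gc(0.65), [nb.make_fixed_gc(0.25)]
        )
        means = nb.per_mark_mean(df).to_numpy()
        assert (np.diff(means) > 0).all()

    def test_empty_null_list_rejected(self, stratified_100):
        with pytest.raises(ValueError):
            score_dataset(stratified_100, nb.make_uniform(), [])

    def test_wam_family_fixed_null_quasi_linear_in_gc(self):
        """With a WAM family under a fixed-GC null, per-mark mean log-odds
        is quasi-linear in the mark (Spearman |rho| >= 0.99) whenever the
        family's composition and the null differ; a family with no net GC
        bias scored against the uniform null has no compositional mismatch
        and hence no trend, so that pairing is excluded."""
        from scipy.stats import spearmanr

        negatives = nb.generate_gc_stratified(
            50, 70, seed=31, consensus=nb.ConsensusSpec(49, "AG")
        )
        fixed = {g: nb.make_fixed_gc(g) for g in (0.05, 0.25, 0.5, 0.75, 0.95)}
        for fam_gc in (0.38, 0.5, 0.65):
            truth = nb.make_synthetic_acceptor_wam(
                fam_gc, length=70, consensus=nb.ConsensusSpec(49, "AG"), seed=32
            )
            training = nb.sample_family(truth, 1000, seed=33)
            model = nb.fit_wam(training, order=1, pseudocount=1.0)
            for null_gc, null in fixed.items():
                if fam_gc == 0.5 and null_gc == 0.5:
                    continue
                means = nb.per_mark_mean(score_dataset(negatives, model, [null]))
                rho = spearmanr(means.index, means.to_numpy()).statistic
                assert abs(rho) >= 0.99, (fam_gc, null_gc, rho)
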