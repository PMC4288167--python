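import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tfocc.pwm import (
    PWM,
    ScoredSites,
    build_pwm,
    filter_by_relative_score,
    information_content,
    relative_score_threshold,
    score_sequence,
)

UNIFORM = np.full((4, 3), 10.0)


def make_sites(scores, **kw):
    scores = np.asarray(scores, dtype=float)
    return ScoredSites(
        chrom="chr",
        positions=np.arange(len(scores)) * 10,
        strands=np.full(len(scores), "+"),
        scores=scores,
        width=5,
        **kw,
    )


class TestBuildPWM:
    def test_uniform_counts_score_zero(self):
        pwm = build_pwm(UNIFORM, pseudo_count=1.0)
        assert np.allclose(pwm.matrix, 0.0)

    def test_pseudo_count_split_hand_value(self):
        # column (4,0,0,0), total pseudo-count 1 split 0.25 per base:
        # f_A = 4.25/5 = 0.85, score_A = log2(0.85/0.25)
        pwm = build_pwm(np.array([[4], [0], [0], [0]]), pseudo_count=1.0)
        assert pwm.matrix[0, 0] == pytest.approx(np.log2(0.85 / 0.25), abs=1e-12)
        assert pwm.matrix[0, 0] == pytest.approx(1.766, abs=1e-3)
        assert pwm.matrix[1, 0] == pytest.approx(np.log2(0.05 / 0.25), abs=1e-12)

    def test_zero_column_without_pseudocount_rejected(self):
        counts = np.array([[4, 0], [0, 0], [0, 0], [0, 0]])
        with pytest.raises(ValueError, match="all-zero"):
            build_pwm(counts, pseudo_count=0.0)

    def test_malformed_dimensions_rejected(self):
        with pytest.raises(ValueError):
            build_pwm(np.ones((3, 5)))
        with pytest.raises(ValueError):
            build_pwm(np.ones((4, 0)))

    def test_negative_counts_rejected(self):
        counts = UNIFORM.copy()
        counts[0, 0] = -1
        with pytest.raises(ValueError):
            build_pwm(counts)

    def test_background_must_be_valid(self):
        with pytest.raises(ValueError):
            build_pwm(UNIFORM, background=[0.5, 0.5, 0.0, 0.0])


class TestInformationContent:
    def test_uniform_is_zero(self):
        assert information_content(build_pwm(UNIFORM)) == pytest.approx(0.0, abs=1e-12)

    def test_certain_base_is_two_bits_per_column(self):
        # frequencies (1,0,0,0) against uniform background: 2 bits
        pwm = build_pwm(np.array([[1], [0], [0], [0]]), pseudo_count=0.0)
        assert information_content(pwm) == pytest.approx(2.0, abs=1e-12)

    def test_matches_independent_column_entropy_sum(self, default_pwm):
        # oracle: per-column relative entropy summed with plain Python
        import math

        expected = 0.0
        for i in range(default_pwm.length):
            for b in range(4):
                f = default_pwm.frequencies[b, i]
                expected += f * math.log2(f / 0.25)
        assert information_content(default_pwm) == pytest.approx(expected, rel=1e-12)

    def test_nonnegative_for_uniform_background(self, default_pwm):
        assert information_content(default_pwm) >= 0


class TestScoreSequence:
    def test_single_column_lookup(self):
        pwm = build_pwm(np.array([[4], [0], [0], [0]]), pseudo_count=1.0)
        sites = score_sequence(pwm, "AC")
        plus = sites.scores[sites.strands == "+"]
        assert plus[0] == pytest.approx(pwm.matrix[0, 0])
        assert plus[1] == pytest.approx(pwm.matrix[1, 0])

    def test_window_count_both_strands(self, default_pwm):
        seq = "ACGTACGTACGTACGT"
        sites = score_sequence(default_pwm, seq)
        n_win = len(seq) - default_pwm.length + 1
        assert (sites.strands == "+").sum() == n_win
        assert (sites.strands == "-").sum() == n_win

    def test_palindromic_pwm_strand_symmetry(self):
        # a motif equal to its own reverse complement scores both strands
        # identically at every position
        counts = np.array(
            [[8, 1, 1, 1], [1, 8, 1, 1], [1, 1, 8, 1], [1, 1, 1, 8]], dtype=float
        )  # consensus ACGT, a palindrome
        pwm = build_pwm(counts)
        sites = score_sequence(pwm, "ACGTTTGCACGT")
        plus = sites.scores[sites.strands == "+"]
        minus = sites.scores[sites.strands == "-"]
        assert np.allclose(plus, minus)

    def test_all_n_sequence_yields_no_windows(self, default_pwm):
        sites = score_sequence(default_pwm, "N" * (default_pwm.length + 3))
        assert len(sites) == 0

    def test_internal_n_masks_overlapping_windows(self, default_pwm):
        m = default_pwm.length
        seq = "A" * m + "N" + "A" * m
        sites = score_sequence(default_pwm, seq)
        # only the two windows not touching the N survive, per strand
        assert (sites.strands == "+").sum() == 2
        assert set(sites.positions[sites.strands == "+"]) == {0, m + 1}

    def test_sequence_shorter_than_motif_rejected(self, default_pwm):
        with pytest.raises(ValueError, match="shorter"):
            score_sequence(default_pwm, "ACG"[: default_pwm.length - 5])

    def test_uniform_pwm_scores_everything_zero(self):
        pwm = build_pwm(UNIFORM)
        sites = score_sequence(pwm, "ACGTGTCA")
        assert np.allclose(sites.scores, 0.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_strand_symmetry_random(self, seed):
        """Score of a window on + equals the score of its reverse complement
        scanned on the - strand at the mirrored coordinate."""
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 20, size=(4, 5)).astype(float)
        counts[rng.integers(4), :] += 1  # avoid all-zero columns
        pwm = build_pwm(counts)
        seq = "".join(rng.choice(list("ACGT"), size=30))
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        fwd = score_sequence(pwm, seq)
        rev = score_sequence(pwm, rc)
        plus = fwd.scores[fwd.strands == "+"]
        minus_rc = rev.scores[rev.strands == "-"][::-1]
        assert np.allclose(plus, minus_rc, atol=1e-10)


class TestRelativeScoreFilter:
    def test_literal_rule_can_empty_the_set(self):
        # threshold = 0.7 * (9 - (-10)) = 13.3 exceeds every score
        sites = make_sites([-10, 0, 8, 9])
        kept = filter_by_relative_score(sites, 0.7, mode="absolute_range")
        assert len(kept) == 0

    def test_literal_rule_fraction_zero_keeps_nonnegative(self):
        sites = make_sites([-10, 0, 8, 9])
        kept = filter_by_relative_score(sites, 0.0, mode="absolute_range")
        assert set(kept.scores) == {0, 8, 9}

    def test_offset_rule(self):
        # threshold = -10 + 0.7 * 19 = 3.3
        sites = make_sites([-10, 0, 8, 9])
        kept = filter_by_relative_score(sites, 0.7, mode="offset_from_min")
        assert set(kept.scores) == {8, 9}

    @pytest.mark.parametrize("mode", ["absolute_range", "offset_from_min"])
    def test_idempotent(self, mode):
        sites = make_sites([-2, 0, 4.0, 9, 9.4, 10])
        once = filter_by_relative_score(sites, 0.7, mode=mode)
        twice = filter_by_relative_score(once, 0.7, mode=mode)
        assert np.array_equal(once.scores, twice.scores)
        assert np.array_equal(once.positions, twice.positions)

    def test_monotone_in_fraction(self):
        rng = np.random.default_rng(0)
        sites = make_sites(rng.normal(0, 5, size=40))
        strict = filter_by_relative_score(sites, 0.8, mode="offset_from_min")
        loose = filter_by_relative_score(sites, 0.5, mode="offset_from_min")
        assert set(strict.positions).issubset(set(loose.positions))

    def test_empty_input_warns(self):
        sites = make_sites([])
        with pytest.warns(UserWarning):
            out = filter_by_relative_score(sites, 0.7)
        assert len(out) == 0

    def test_invalid_mode_and_fraction(self):
        sites = make_sites([1.0, 2.0])
        with pytest.raises(ValueError):
            filter_by_relative_score(sites, 1.5)
        with pytest.raises(ValueError):
            relative_score_threshold(np.array([1.0, 2.0]), 0.7, mode="nope")


class TestScoredSitesInvariants:
    def test_positions_must_increase_per_strand(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            ScoredSites(
                chrom="chr",
                positions=np.array([5, 5]),
                strands=np.array(["+", "+"]),
                scores=np.array([1.0, 2.0]),
                width=3,
            )

    def test_same_position_on_both_strands_allowed(self):
        s = ScoredSites(
            chrom="chr",
            positions=np.array([5, 5]),
            strands=np.array(["+", "-"]),
            scores=np.array([1.0, 2.0]),
            width=3,
        )
        assert len(s) == 2
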