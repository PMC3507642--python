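"""PWM scanning, palindromes, specificity Z-scores and pair spacing."""

import numpy as np
import pytest
from scipy import stats

from cistromedose.motifs import (
    PWM,
    MotifHit,
    is_palindromic,
    motif_mode_association,
    motif_zscore,
    pair_spacing,
    read_meme_pwm,
    scan_pwm,
    scan_sequences,
    score_strength_association,
    write_meme_pwm,
)
from cistromedose.simulate import default_are_pwm, default_partner_pwm


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestScan:
    def test_consensus_planted_at_known_position_scores_maximal(self):
        pwm = default_partner_pwm()
        rng = np.random.default_rng(0)
        seq = random_seq(rng, 10) + pwm.consensus() + random_seq(rng, 10)
        hits = scan_pwm(seq, pwm)
        best = max(hits, key=lambda h: h.score)
        assert best.position == 10
        assert best.score == pytest.approx(pwm.max_score())

    def test_consensus_attains_global_maximum(self):
        pwm = default_partner_pwm()
        rng = np.random.default_rng(1)
        for _ in range(20):
            hits = scan_pwm(random_seq(rng, 200), pwm, threshold=-1e9)
            assert all(h.score <= pwm.max_score() + 1e-9 for h in hits)

    def test_uniform_pwm_scores_all_zero(self):
        pwm = PWM(np.full((4, 6), 0.25), pseudocount=0.0)
        hits = scan_pwm("ACGTACGTACGT", pwm, threshold=-1.0)
        assert all(h.score == pytest.approx(0.0) for h in hits)

    def test_short_sequence_yields_no_hits(self):
        assert scan_pwm("ACG", default_are_pwm()) == []

    def test_n_windows_skipped(self):
        pwm = default_partner_pwm()
        seq = "AAA" + pwm.consensus()[:3] + "N" + pwm.consensus()[4:] + "AAA"
        hits = [h for h in scan_pwm(seq, pwm, threshold=-1e9) if 3 <= h.position <= 3]
        assert hits == []

    def test_palindromic_pwm_hits_both_strands_equally(self):
        pwm = default_are_pwm()
        rng = np.random.default_rng(2)
        for _ in range(10):
            seq = random_seq(rng, 50) + pwm.consensus() + random_seq(rng, 50)
            hits = scan_pwm(seq, pwm)
            by_pos = {}
            for h in hits:
                by_pos.setdefault(h.position, {})[h.strand] = h.score
            for pos, strands in by_pos.items():
                assert set(strands) == {"+", "-"}
                assert strands["+"] == pytest.approx(strands["-"], abs=1e-9)

    def test_strand_mirror_consistency(self):
        pwm = default_partner_pwm()
        rng = np.random.default_rng(3)
        seq = random_seq(rng, 120)
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        fwd = scan_pwm(seq, pwm, threshold=2.0)
        rev = scan_pwm(rc, pwm, threshold=2.0)
        mapped = sorted(
            (len(seq) - h.width - h.position, "+-"[h.strand == "+"], round(h.score, 6))
            for h in rev
        )
        orig = sorted((h.position, h.strand, round(h.score, 6)) for h in fwd)
        assert mapped == orig


class TestPalindrome:
    def test_reverse_complement_symmetric_matrix(self):
        assert is_palindromic(default_are_pwm())

    def test_poly_a_is_not_palindromic(self):
        probs = np.zeros((4, 6))
        probs[0] = 1.0
        assert not is_palindromic(PWM(probs))

    def test_width_one_at_gc_balance(self):
        assert is_palindromic(PWM(np.array([[0.3], [0.2], [0.2], [0.3]]), pseudocount=0.0))


class TestZScore:
    def test_arithmetic_on_planted_motif(self):
        rng = np.random.default_rng(4)
        pwm = default_are_pwm()
        genome = {"chr1": random_seq(rng, 60_000)}
        bound = {}
        for i in range(60):
            s = random_seq(rng, 40) + pwm.consensus() + random_seq(rng, 40)
            bound[f"s{i}"] = ("chr1", s)
        res = motif_zscore(bound, pwm, genome, background_groups=50, seed=9)
        assert res.bound_count == 60
        assert res.z > 5

    def test_background_drawn_sequences_give_small_z(self):
        rng = np.random.default_rng(5)
        pwm = default_partner_pwm()
        genome = {"chr1": random_seq(rng, 100_000)}
        zs = []
        for rep in range(20):
            start = rng.integers(0, 90_000, 40)
            bound = {f"s{i}": ("chr1", genome["chr1"][s : s + 100])
                     for i, s in enumerate(start)}
            zs.append(motif_zscore(bound, pwm, genome, background_groups=30,
                                   seed=rep).z)
        assert abs(np.mean(zs)) < 1.0

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(6)
        pwm = default_partner_pwm()
        genome = {"chr1": random_seq(rng, 30_000)}
        bound = {f"s{i}": ("chr1", random_seq(rng, 80)) for i in range(20)}
        r1 = motif_zscore(bound, pwm, genome, background_groups=25, seed=123)
        r2 = motif_zscore(bound, pwm, genome, background_groups=25, seed=123)
        assert r1.z == r2.z and r1.random_mean == r2.random_mean


class TestPairSpacing:
    def make_hits(self, seq_id, pos_a, pos_b, wa=15, wb=7):
        return (
            [MotifHit(seq_id, pos_a, "+", 10.0, wa)],
            [MotifHit(seq_id, pos_b, "+", 8.0, wb)],
        )

    def test_planted_fifteen_bp_spacing_is_modal(self):
        hits_a, hits_b = [], []
        for i in range(200):
            # ARE middle at 57, partner middle at 72: 15 bp apart
            a, b = self.make_hits(f"s{i}", 50, 69)
            hits_a += a
            hits_b += b
        hist = pair_spacing(hits_a, hits_b)
        assert hist.mode == 15
        assert hist.counts.sum() == 200

    def test_out_of_range_pairs_excluded(self):
        a, b = self.make_hits("s", 0, 64)  # middles 60 bp apart
        hist = pair_spacing(a, b)
        assert hist.counts.sum() == 0 and hist.mode is None

    def test_uniform_random_placement_is_flat(self):
        rng = np.random.default_rng(7)
        hits_a, hits_b = [], []
        # width-1 hits make midpoint == position, so distances are explicit
        for i in range(4000):
            d = int(rng.integers(10, 51))
            hits_a.append(MotifHit(f"u{i}", 100, "+", 1.0, 1))
            hits_b.append(MotifHit(f"u{i}", 100 + d, "+", 1.0, 1))
        hist = pair_spacing(hits_a, hits_b)
        chi = stats.chisquare(hist.counts)
        assert chi.pvalue > 0.01


class TestModeAssociation:
    def test_perfect_association(self):
        presence = {f"a{i}": True for i in range(10)} | {f"r{i}": False for i in range(10)}
        modes = {f"a{i}": "activation" for i in range(10)} | {
            f"r{i}": "repression" for i in range(10)
        }
        res = motif_mode_association(presence, modes)
        assert res.p_value == pytest.approx(2 / 184756, rel=1e-6)

    def test_no_association_gives_p_one(self):
        presence = {"a0": True, "a1": False, "r0": True, "r1": False}
        modes = {"a0": "activation", "a1": "activation",
                 "r0": "repression", "r1": "repression"}
        assert motif_mode_association(presence, modes).p_value == 1.0

    def test_single_mode_is_error(self):
        with pytest.raises(ValueError):
            motif_mode_association({"a": True}, {"a": "activation"})


class TestStrengthAssociation:
    def test_delegates_to_rank_sum(self):
        from cistromedose.cistrome import compare_strength_groups

        a, b = [10.0, 12, 15, 11], [5.0, 6, 7]
        d1 = score_strength_association(a, b)
        d2 = compare_strength_groups(a, b)
        assert (d1.statistic, d1.p_value) == (d2.statistic, d2.p_value)

    def test_detects_planted_strength_difference(self):
        rng = np.random.default_rng(8)
        with_motif = rng.normal(1000, 200, 500)
        without = rng.normal(800, 200, 500)
        assert score_strength_association(with_motif, without).p_value < 0.05

    def test_equal_groups_not_significant(self):
        rng = np.random.default_rng(9)
        x = rng.normal(1000, 200, 300)
        assert score_strength_association(x, x).p_value > 0.9


def test_meme_round_trip(tmp_path):
    pwm = default_are_pwm()
    path = tmp_path / "are.meme"
    write_meme_pwm(pwm, path)
    back = read_meme_pwm(path)
    assert back.width == 15
    assert np.allclose(back.probs, pwm.probs, atol=1e-4)
    assert is_palindromic(back, tol=1e-3)
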