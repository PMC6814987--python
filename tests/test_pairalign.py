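import math

import numpy as np
import pytest
from scipy.optimize import brentq

from mitocomp.pairalign import (
    InvalidScoringScheme,
    ScoringScheme,
    find_hsps,
    global_align,
    solve_karlin_altschul,
)
from mitocomp.seqio import Genome, Interval, reverse_complement

from conftest import random_seq


def sw_oracle(a: str, b: str, scheme: ScoringScheme):
    """Independent local-alignment oracle (Biopython's exact DP engine)."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scheme.match
    aligner.mismatch_score = scheme.mismatch
    aligner.open_gap_score = -scheme.gap_open
    aligner.extend_gap_score = -scheme.gap_extend
    alns = aligner.align(a, b)
    best = alns[0]
    (a_blocks, b_blocks) = best.aligned
    a_iv = (int(a_blocks[0][0]), int(a_blocks[-1][1]))
    b_iv = (int(b_blocks[0][0]), int(b_blocks[-1][1]))
    return best.score, a_iv, b_iv


def overlap_frac(lo1, hi1, lo2, hi2):
    ov = max(0, min(hi1, hi2) - max(lo1, lo2))
    return ov / max(hi1 - lo1, hi2 - lo2)


class TestKarlinAltschul:
    def test_plus1_minus1_closed_form(self):
        # quadratic in e^lambda solves exactly: lambda = ln 3
        ka = solve_karlin_altschul(ScoringScheme(match=1, mismatch=-1))
        assert ka.lam == pytest.approx(math.log(3), abs=1e-9)

    def test_plus2_minus3_matches_scalar_root_oracle(self):
        scheme = ScoringScheme(match=2, mismatch=-3)

        def f(lam):
            return 0.25 * math.exp(2 * lam) + 0.75 * math.exp(-3 * lam) - 1.0

        oracle = brentq(f, 1e-9, 5.0)
        ka = solve_karlin_altschul(scheme)
        assert ka.lam == pytest.approx(oracle, abs=1e-6)

    def test_default_scheme_lambda_solves_equation(self):
        scheme = ScoringScheme()
        ka = solve_karlin_altschul(scheme)
        total = sum(
            0.0625 * math.exp(ka.lam * (scheme.match if i == j else scheme.mismatch))
            for i in range(4)
            for j in range(4)
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_inapplicable_scheme_rejected(self):
        with pytest.raises(InvalidScoringScheme):
            solve_karlin_altschul(ScoringScheme(match=1, mismatch=1))

    def test_nonnegative_expected_score_rejected(self):
        with pytest.raises(InvalidScoringScheme):
            # expected score = 0.25*5 - 0.75*1 = +0.5
            solve_karlin_altschul(ScoringScheme(match=5, mismatch=-1))


class TestFindHsps:
    def test_self_hit_full_length(self, make_genome):
        g = make_genome(10, 5000)
        hits = find_hsps(g, g)
        full = [h for h in hits if h.aligned_len == 5000]
        assert len(full) == 1
        h = full[0]
        assert h.identity == 1.0
        assert h.strand == "+"
        assert h.query == Interval(0, 5000)
        assert h.evalue < 1e-6

    def test_planted_copy_matches_sw_oracle(self):
        rng = np.random.default_rng(77)
        base = random_seq(rng, 1000)
        seq = base[:700] + base[100:300] + base[900:]
        g = Genome(id="p", sequence=seq)
        hits = find_hsps(g, g)
        off = [
            h
            for h in hits
            if not (h.strand == "+" and h.query.start == h.subject.start)
        ]
        # exactly one reciprocal pair covering the planted copies
        assert len(off) == 2
        spans = sorted((h.query.start, h.query.end) for h in off)
        assert overlap_frac(*spans[0], 100, 300) >= 0.9
        assert overlap_frac(*spans[1], 700, 900) >= 0.9
        # oracle: best local alignment of the two halves finds the same copy
        score, a_iv, b_iv = sw_oracle(seq[:500], seq[500:], ScoringScheme())
        assert overlap_frac(*a_iv, 100, 300) >= 0.9
        assert overlap_frac(b_iv[0] + 500, b_iv[1] + 500, 700, 900) >= 0.9

    def test_unrelated_sequences_no_hits(self):
        rng1, rng2 = np.random.default_rng(5), np.random.default_rng(6)
        a = Genome(id="a", sequence=random_seq(rng1, 1000))
        b = Genome(id="b", sequence=random_seq(rng2, 1000))
        scheme = ScoringScheme()
        hits = find_hsps(a, b, evalue_max=1e-6)
        assert hits == []
        # oracle: no ungapped local alignment reaches the score threshold
        ka = solve_karlin_altschul(scheme)
        s_star = ka.score_threshold(1e-6, 1000, 1000)
        score, _, _ = sw_oracle(a.sequence, b.sequence, scheme)
        assert score < s_star

    def test_word_size_too_small_rejected(self, make_genome):
        g = make_genome(1, 100)
        with pytest.raises(ValueError):
            find_hsps(g, g, word_size=3)

    def test_word_size_exceeding_length_warns_empty(self, make_genome):
        g = make_genome(1, 6)
        with pytest.warns(UserWarning):
            assert find_hsps(g, g, word_size=7) == []

    def test_strand_symmetry(self):
        rng = np.random.default_rng(8)
        q = Genome(id="q", sequence=random_seq(rng, 600))
        # subject contains a copy of part of q plus a reverse-complemented copy
        s_seq = (
            random_seq(rng, 100)
            + q.sequence[50:200]
            + random_seq(rng, 100)
            + reverse_complement(q.sequence[300:450])
            + random_seq(rng, 100)
        )
        s = Genome(id="s", sequence=s_seq)
        fwd = find_hsps(q, s)
        rev = find_hsps(q, Genome(id="s_rc", sequence=reverse_complement(s_seq)))
        assert len(fwd) == len(rev) >= 2
        n = s.length_bp
        flipped = sorted(
            (
                h.query.start,
                h.query.end,
                n - h.subject.end,
                n - h.subject.start,
                "-" if h.strand == "+" else "+",
                h.score,
            )
            for h in rev
        )
        original = sorted(
            (
                h.query.start,
                h.query.end,
                h.subject.start,
                h.subject.end,
                h.strand,
                h.score,
            )
            for h in fwd
        )
        assert flipped == original

    def test_evalue_consistency(self):
        rng = np.random.default_rng(9)
        base = random_seq(rng, 800)
        seq = base[:500] + base[100:250] + base[650:]
        g = Genome(id="e", sequence=seq)
        scheme = ScoringScheme()
        ka = solve_karlin_altschul(scheme)
        hits = find_hsps(g, g, scheme=scheme, ka=ka)
        m = n = g.length_bp
        assert hits
        for h in hits:
            expected = ka.K * m * n * math.exp(-ka.lam * h.score)
            assert h.evalue == pytest.approx(expected, rel=1e-9)
            # identity * aligned_len is an integer match count
            assert abs(h.identity * h.aligned_len - round(h.identity * h.aligned_len)) < 1e-9

    def test_determinism(self, make_genome):
        g = make_genome(30, 2000)
        assert find_hsps(g, g) == find_hsps(g, g)


class TestGlobalAlign:
    def test_identity(self):
        a = "ACGTACGTAC"
        aa, bb, score, ident = global_align(a, a, ScoringScheme(match=1, mismatch=-1))
        assert aa == bb == a
        assert score == len(a)
        assert ident == 1.0

    def test_hand_filled_dp(self):
        # ACGT vs ACT, match +1 mismatch -1 open 2 extend 1 (gap of length L
        # costs open + (L-1)*extend): best is ACGT / AC-T = 3 matches - 2
        aa, bb, score, ident = global_align(
            "ACGT", "ACT", ScoringScheme(match=1, mismatch=-1, gap_open=2, gap_extend=1)
        )
        assert score == 1
        assert (aa, bb) == ("ACGT", "AC-T")

    def test_empty_b_all_gap(self):
        scheme = ScoringScheme(match=1, mismatch=-1, gap_open=5, gap_extend=2)
        a = "ACGTACGT"
        aa, bb, score, ident = global_align(a, "", scheme)
        assert aa == a
        assert bb == "-" * len(a)
        assert score == -(scheme.gap_open + (len(a) - 1) * scheme.gap_extend)

    def test_matches_biopython_scores(self):
        from Bio import Align

        rng = np.random.default_rng(12)
        scheme = ScoringScheme(match=1, mismatch=-2, gap_open=5, gap_extend=2)
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = -2
        # both conventions price a length-L gap at open + (L-1)*extend
        aligner.open_gap_score = -scheme.gap_open
        aligner.extend_gap_score = -scheme.gap_extend
        for _ in range(10):
            a = random_seq(rng, int(rng.integers(5, 60)))
            b = random_seq(rng, int(rng.integers(5, 60)))
            _, _, score, _ = global_align(a, b, scheme)
            assert score == aligner.score(a, b)
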