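"""PWM scoring, exact p-values, scanning and inverted-dimer detection."""

import itertools

import numpy as np
import pytest

from soxgrn.genome_model import GenomeSequence, Peak
from soxgrn.motif_dimer import (
    PWM,
    MotifHit,
    ScoreDistribution,
    detect_dimers,
    dimer_fraction_and_spacers,
    rank_and_select_top,
    read_jaspar,
    reverse_complement,
    scan,
    score_pvalue_table,
    sox_core_pwm,
    write_jaspar,
)
from soxgrn.synthetic_data import generate_dimer_windows

CONSENSUS = "AACAATG"


@pytest.fixture(scope="module")
def pwm():
    return sox_core_pwm()


@pytest.fixture(scope="module")
def dist(pwm):
    return ScoreDistribution(pwm)


def enumerate_tails(pwm, precision=1e-3):
    """Oracle: integer-score tail probabilities from all 4^L background L-mers."""
    int_matrix = np.rint(pwm.log_odds / precision).astype(int)
    L = pwm.length
    scores = {}
    for word in itertools.product(range(4), repeat=L):
        s = sum(int_matrix[b, j] for j, b in enumerate(word))
        prob = np.prod([pwm.background[b] for b in word])
        scores[s] = scores.get(s, 0.0) + prob
    items = sorted(scores.items())
    tails = {}
    acc = 0.0
    for s, p in reversed(items):
        acc += p
        tails[s] = acc
    return tails, int_matrix


class TestScoreDistribution:
    def test_tails_match_exhaustive_enumeration(self, pwm, dist):
        tails, int_matrix = enumerate_tails(pwm)
        for s, tail in tails.items():
            assert dist.tail(s) == pytest.approx(tail, rel=1e-9)

    def test_max_score_tail_is_consensus_path_probability(self, pwm, dist):
        # the unique maximum is the consensus word; its tail is (1/4)^7
        assert dist.tail(dist.max_score) == pytest.approx(0.25 ** 7, rel=1e-12)

    def test_below_minimum_score_tail_is_one(self, dist):
        assert dist.tail(dist.min_score - 1000) == pytest.approx(1.0)

    def test_bad_precision_rejected(self, pwm):
        with pytest.raises(ValueError):
            score_pvalue_table(pwm, precision=0.0)


class TestScan:
    def test_consensus_yields_single_plus_hit(self, pwm):
        hits = scan(pwm, CONSENSUS)
        assert len(hits) == 1
        (h,) = hits
        assert h.strand == "+" and h.offset == 0
        assert h.p_value <= 1e-4

    def test_all_n_sequence_yields_nothing(self, pwm):
        assert scan(pwm, "N" * 60) == []

    def test_short_sequence_yields_nothing(self, pwm):
        assert scan(pwm, "ACG") == []

    def test_planted_consensus_and_revcomp_give_opposite_strands(self, pwm):
        seq = "GG" + CONSENSUS + "TTTT" + reverse_complement(CONSENSUS) + "CC"
        hits = scan(pwm, seq)
        assert {(h.offset, h.strand) for h in hits} == {(2, "+"), (13, "-")}

    def test_hits_match_word_enumeration_on_random_sequences(self, pwm, dist):
        """Every offset whose 7-mer is in the enumerated p<=1e-4 word set is a
        hit, and nothing else (forward and reverse strands)."""
        tails, int_matrix = enumerate_tails(pwm)
        passing = set()
        for word in itertools.product(range(4), repeat=pwm.length):
            s = sum(int_matrix[b, j] for j, b in enumerate(word))
            if tails[s] <= 1e-4:
                passing.add("".join("ACGT"[b] for b in word))
        rng = np.random.default_rng(5)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), 120))
            if rng.random() < 0.5:  # plant a consensus to keep hits non-trivial
                i = int(rng.integers(0, 100))
                seq = seq[:i] + CONSENSUS + seq[i + 7 :]
            expected = set()
            for off in range(len(seq) - 6):
                word = seq[off : off + 7]
                if word in passing:
                    expected.add((off, "+"))
                if reverse_complement(word) in passing:
                    expected.add((off, "-"))
            got = {(h.offset, h.strand) for h in scan(pwm, seq, dist=dist)}
            assert got == expected


def test_reverse_complement_invariance(pwm, seed=9, n=200):
    """Hits of the reverse complement are the mirrored hits of the original."""
    dist = ScoreDistribution(pwm)
    rng = np.random.default_rng(seed)
    for _ in range(n):
        length = int(rng.integers(20, 80))
        seq = "".join(rng.choice(list("ACGT"), length))
        if rng.random() < 0.5:
            i = int(rng.integers(0, length - 7))
            seq = seq[:i] + CONSENSUS + seq[i + 7 :]
        fwd = {(h.offset, h.strand) for h in scan(pwm, seq, dist=dist)}
        rev = {(h.offset, h.strand) for h in scan(pwm, reverse_complement(seq), dist=dist)}
        mirrored = {(len(seq) - off - 7, "-" if s == "+" else "+") for off, s in fwd}
        assert rev == mirrored


class TestRankAndSelect:
    def make_peaks(self, scores):
        return [
            Peak(f"p{i:03d}", "Sox9", "chr1", 0, 100, 50, s) for i, s in enumerate(scores)
        ]

    def test_top_n_by_score(self):
        peaks = self.make_peaks(range(500))
        top = rank_and_select_top(peaks, n=200)
        assert len(top) == 200
        assert min(p.score for p in top) == 300

    def test_fewer_than_n_returns_all(self):
        peaks = self.make_peaks(range(150))
        assert len(rank_and_select_top(peaks, n=200)) == 150

    def test_ties_broken_by_peak_id(self):
        peaks = self.make_peaks([5.0] * 10)
        top = rank_and_select_top(peaks, n=3)
        assert [p.peak_id for p in top] == ["p000", "p001", "p002"]

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError):
            rank_and_select_top([], n=0)


def hit(offset, strand, L=7):
    return MotifHit("s", offset, strand, 10.0, 1e-5, L)


class TestDetectDimers:
    def test_constructed_inverted_pair_spacer_four(self, pwm):
        seq = "T" * 10 + CONSENSUS + "ACGT" + reverse_complement(CONSENSUS) + "T" * 10
        hits = scan(pwm, seq)
        calls = detect_dimers(hits)
        assert len(calls) == 1
        (c,) = calls
        # plus hit at 10, minus hit at 10+7+4=21: gap between occupancies is 4
        assert c.spacer == 4 and c.orientation == "tail_to_tail"

    def test_head_to_head_when_minus_hit_is_five_prime(self):
        calls = detect_dimers([hit(0, "-"), hit(10, "+")])
        assert len(calls) == 1 and calls[0].orientation == "head_to_head"
        assert calls[0].spacer == 3

    def test_single_or_same_strand_hits_give_nothing(self):
        assert detect_dimers([hit(0, "+")]) == []
        assert detect_dimers([hit(0, "+"), hit(20, "+")]) == []

    def test_overlapping_or_distant_pairs_excluded(self):
        assert detect_dimers([hit(0, "+"), hit(5, "-")]) == []  # overlap
        assert detect_dimers([hit(0, "+"), hit(50, "-")], max_spacer=20) == []


class TestDimerFractionAndSpacers:
    def test_planted_windows_recovered(self):
        genome, peaks, planted, pwm = generate_dimer_windows(
            n_windows=200, planting_rate=0.5, spacer=6, seed=3
        )
        summary = dimer_fraction_and_spacers(peaks, genome, pwm)
        assert summary.n_scanned == 200
        assert abs(summary.fraction - 0.5) <= 0.03
        assert summary.spacers.mode == 6
        # every planted window is found
        assert set(planted) <= set(summary.best_calls)

    def test_background_false_positive_rate_bounded(self):
        genome, peaks, planted, pwm = generate_dimer_windows(
            n_windows=300, planting_rate=0.0, seed=4
        )
        summary = dimer_fraction_and_spacers(peaks, genome, pwm)
        assert summary.fraction <= 0.05

    def test_halfwidth_zero_gives_no_dimers(self):
        genome, peaks, _, pwm = generate_dimer_windows(n_windows=20, seed=5)
        summary = dimer_fraction_and_spacers(peaks, genome, pwm, halfwidth=0)
        assert summary.fraction == 0.0

    def test_missing_chromosome_skipped_and_reported(self):
        genome, peaks, _, pwm = generate_dimer_windows(n_windows=5, seed=6)
        stray = Peak("stray", "Sox9", "chrZ", 0, 101, 50, 1.0)
        summary = dimer_fraction_and_spacers(peaks + [stray], genome, pwm)
        assert summary.skipped_peaks == ["stray"]
        assert summary.n_scanned == 5


def test_jaspar_round_trip(tmp_path, pwm):
    path = tmp_path / "m.jaspar"
    write_jaspar(pwm, path)
    back = read_jaspar(path)
    assert back.length == pwm.length
    assert np.allclose(back.matrix, pwm.matrix, atol=0.02)
    assert scan(back, CONSENSUS)  # still recognizes its consensus


def test_pwm_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        PWM(np.full((4, 5), 0.3))
    with pytest.raises(ValueError, match="pseudocount"):
        mat = np.zeros((4, 5))
        mat[0] = 1.0
        PWM(mat)
    assert PWM.from_consensus("WWCAAWG").consensus == "WWCAAWG"
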