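"""PWM scanning with exact score p-values and inverted-homodimer detection.

A position weight matrix is scored as log2-odds against a background base
composition. The null distribution of the score of a random background L-mer
is computed exactly by position-wise convolution of the per-column score
distribution, after discretizing log-odds scores to a fixed precision
(default 1e-3). The tail probability P(score >= s) of a window's score is its
match p-value; a window is a hit when that p-value is at or below the cutoff
(default 1e-4, the MAST default). Windows containing N (repeat-masked bases)
are skipped individually.

SOX-family HMG-box factors such as Sox9 bind DNA as homodimers on inverted
(opposing-orientation) motif pairs. ``detect_dimers`` pairs opposite-strand
hits with a bounded spacer; the spacer counts the gap between the two motif
occupancies, so 0 means abutting. Orientation is labelled, not filtered:
``head_to_head`` when the '-'-strand hit lies 5' of the '+'-strand hit on the
reference, ``tail_to_tail`` otherwise.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import motifs as bio_motifs

from .genome_model import GenomeSequence, Peak

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}
_BASE_TO_CODE["N"] = 4
_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CG"): "S", frozenset("AT"): "W", frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V", frozenset("ACGT"): "N",
}

UNIFORM_BACKGROUND = np.full(4, 0.25)


def encode(sequence: str) -> np.ndarray:
    """Encode an ACGTN string as int8 codes (A=0, C=1, G=2, T=3, N=4)."""
    try:
        return np.array([_BASE_TO_CODE[b] for b in sequence.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid base {exc.args[0]!r}") from exc


def reverse_complement(sequence: str) -> str:
    return sequence.upper().translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


class PWM:
    """Probability PWM (rows A,C,G,T) with log2-odds scores over a background."""

    def __init__(self, probabilities, background=None, name: str = "pwm"):
        probs = np.asarray(probabilities, dtype=float)
        if probs.shape[0] != 4:
            raise ValueError("PWM needs 4 rows (A, C, G, T)")
        if probs.shape[1] < 4:
            raise ValueError("PWM needs length >= 4")
        if not np.allclose(probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")
        if (probs <= 0).any():
            raise ValueError("PWM probabilities must be positive; add pseudocounts")
        bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, dtype=float)
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must be 4 probabilities summing to 1")
        self.matrix = probs
        self.background = bg
        self.name = name
        self.log_odds = np.log2(probs / bg[:, None])

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def consensus(self) -> str:
        """IUPAC consensus: per column, the bases reaching >= 60% of the max prob."""
        letters = []
        for j in range(self.length):
            col = self.matrix[:, j]
            chosen = frozenset(BASES[i] for i in range(4) if col[i] >= 0.6 * col.max())
            letters.append(_IUPAC[chosen])
        return "".join(letters)

    @classmethod
    def from_counts(cls, counts, background=None, pseudocount: float = 0.25, name: str = "pwm") -> "PWM":
        c = np.asarray(counts, dtype=float) + pseudocount
        return cls(c / c.sum(axis=0, keepdims=True), background=background, name=name)

    @classmethod
    def from_consensus(
        cls, consensus: str, n_sites: int = 100, pseudocount: float = 0.25,
        background=None, name: str | None = None,
    ) -> "PWM":
        """Build a PWM from an IUPAC consensus with ``n_sites`` idealized sites."""
        rev = {v: set(k) for k, v in _IUPAC.items()}
        counts = np.zeros((4, len(consensus)))
        for j, letter in enumerate(consensus.upper()):
            if letter not in rev:
                raise ValueError(f"invalid IUPAC letter {letter!r}")
            allowed = rev[letter]
            for b in allowed:
                counts[_BASE_TO_CODE[b], j] = n_sites / len(allowed)
        return cls.from_counts(counts, background=background, pseudocount=pseudocount,
                               name=name or consensus)


def sox_consensus_pwm() -> PWM:
    """The degenerate SOX HMG-box consensus 5'-(A/T)(A/T)CAA(A/T)G-3' as a PWM.

    Note this motif carries at most 11 bits of information, so its best match
    p-value under a uniform background is ~4.9e-4; it cannot produce hits at
    the 1e-4 default cutoff and serves as a reference/consensus fixture.
    """
    return PWM.from_consensus("WWCAAWG", name="Sox_consensus")


def sox_core_pwm() -> PWM:
    """A non-degenerate SOX core word (AACAATG) PWM, sharp enough to reach p<=1e-4."""
    return PWM.from_consensus("AACAATG", name="Sox_core")


def read_jaspar(path: str | Path) -> PWM:
    """Read a JASPAR-style count matrix and convert to probabilities."""
    with open(path) as fh:
        motif = bio_motifs.read(fh, "jaspar")
    counts = np.array([list(motif.counts[b]) for b in BASES], dtype=float)
    return PWM.from_counts(counts, name=motif.name or motif.matrix_id or "jaspar")


def write_jaspar(pwm: PWM, path: str | Path, scale: int = 100) -> None:
    with open(path, "w") as fh:
        fh.write(f">{pwm.name} {pwm.name}\n")
        for i, b in enumerate(BASES):
            vals = " ".join(f"{pwm.matrix[i, j] * scale:7.2f}" for j in range(pwm.length))
            fh.write(f"{b} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# Exact score distribution
# ---------------------------------------------------------------------------

class ScoreDistribution:
    """Exact null distribution of the discretized log-odds score.

    Scores are discretized to integer multiples of ``precision`` log-odds
    units; the distribution of the total score of a random background L-mer
    is obtained by convolving the four-point per-column distributions.
    ``tail(s)`` is P(score >= s) for a discretized score.
    """

    def __init__(self, pwm: PWM, precision: float = 1e-3):
        if precision <= 0:
            raise ValueError("precision must be > 0")
        self.precision = precision
        self.int_matrix = np.rint(pwm.log_odds / precision).astype(np.int64)
        probs = np.array([1.0])
        offset = 0
        for j in range(pwm.length):
            col = self.int_matrix[:, j]
            lo = offset + int(col.min())
            hi = offset + probs.size - 1 + int(col.max())
            new = np.zeros(hi - lo + 1)
            for b in range(4):
                sh = offset + int(col[b]) - lo
                new[sh : sh + probs.size] += probs * pwm.background[b]
            probs, offset = new, lo
        self.offset = offset  # integer score of probs[0]
        self.probs = probs
        # tail[i] = P(score_int >= offset + i)
        self._tail = np.cumsum(probs[::-1])[::-1]
        self.min_score = offset
        self.max_score = offset + probs.size - 1

    def tail(self, score_int: int | np.ndarray) -> np.ndarray:
        """P(score >= s) for integer (discretized) scores; 1 below the minimum."""
        idx = np.asarray(score_int) - self.offset
        idx = np.clip(idx, 0, self._tail.size - 1)
        out = self._tail[idx]
        return np.where(np.asarray(score_int) > self.max_score, self._tail[-1], out)

    def hit_threshold(self, p_cutoff: float) -> int | None:
        """Smallest integer score whose tail probability is <= p_cutoff (None if none)."""
        idx = np.searchsorted(-self._tail, -p_cutoff, side="left")
        if idx >= self._tail.size:
            return None
        return int(self.offset + idx)

    def as_table(self) -> dict[float, float]:
        """score (log-odds units) -> tail probability, for attained scores only."""
        mask = self.probs > 0
        scores = (self.offset + np.nonzero(mask)[0]) * self.precision
        return dict(zip(scores.tolist(), self._tail[mask].tolist()))


def score_pvalue_table(pwm: PWM, precision: float = 1e-3) -> ScoreDistribution:
    """Exact score -> tail-probability map for ``pwm`` (see ScoreDistribution)."""
    return ScoreDistribution(pwm, precision=precision)


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    offset: int  # 0-based start of the match in the forward sequence
    strand: str  # '+' or '-'
    score: float  # log-odds, discretized
    p_value: float  # exact tail probability under the background
    length: int

    @property
    def end(self) -> int:
        return self.offset + self.length


def _window_int_scores(codes: np.ndarray, int_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integer scores of all windows plus validity mask (False where any N)."""
    L = int_matrix.shape[1]
    n = codes.size
    if n < L:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (win != 4).all(axis=1)
    safe = np.where(win == 4, 0, win).astype(np.int64)
    scores = int_matrix[safe, np.arange(L)].sum(axis=1)
    return scores, valid


def scan(
    pwm: PWM,
    sequence: str,
    p_cutoff: float = 1e-4,
    both_strands: bool = True,
    seq_id: str = "seq",
    dist: ScoreDistribution | None = None,
) -> list[MotifHit]:
    """Report every offset/strand whose match p-value is <= ``p_cutoff``.

    Reverse-strand scores are those of the reverse complement of each window.
    Windows containing N are skipped. Sequences shorter than the motif yield
    an empty result.
    """
    dist = dist or ScoreDistribution(pwm)
    codes = encode(sequence)
    L = pwm.length
    hits: list[MotifHit] = []
    fwd_scores, valid = _window_int_scores(codes, dist.int_matrix)
    if fwd_scores.size == 0:
        return hits
    strands = [("+", dist.int_matrix)]
    if both_strands:
        # reverse-complement the PWM instead of the sequence: rc[b, j] = m[3-b, L-1-j]
        rc_matrix = dist.int_matrix[::-1, ::-1]
        strands.append(("-", rc_matrix))
    for strand, matrix in strands:
        scores = fwd_scores if strand == "+" else _window_int_scores(codes, matrix)[0]
        pvals = dist.tail(scores)
        for off in np.nonzero(valid & (pvals <= p_cutoff))[0]:
            hits.append(
                MotifHit(seq_id, int(off), strand, float(scores[off] * dist.precision),
                         float(pvals[off]), L)
            )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def rank_and_select_top(peaks: Sequence[Peak], n: int = 200) -> list[Peak]:
    """The n highest-score peaks (ties broken by peak_id); all if fewer, with a warning."""
    if n <= 0:
        raise ValueError("n must be positive")
    ranked = sorted(peaks, key=lambda p: (-p.score, p.peak_id))
    if len(ranked) < n:
        logger.warning("only %d peaks available for top-%d selection", len(ranked), n)
        return ranked
    return ranked[:n]


# ---------------------------------------------------------------------------
# Dimer detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DimerCall:
    seq_id: str
    hit_plus: MotifHit
    hit_minus: MotifHit
    spacer: int  # gap in bp between the two motif occupancies (0 = abutting)
    orientation: str  # 'head_to_head' or 'tail_to_tail'

    @property
    def combined_p(self) -> float:
        return self.hit_plus.p_value * self.hit_minus.p_value


def detect_dimers(hits: Sequence[MotifHit], max_spacer: int = 20) -> list[DimerCall]:
    """All non-overlapping opposite-strand hit pairs with spacer <= max_spacer.

    A hit may participate in several pairs; all are reported. Orientation is
    head_to_head iff the '-'-strand hit lies 5' of the '+'-strand hit.
    """
    plus = [h for h in hits if h.strand == "+"]
    minus = [h for h in hits if h.strand == "-"]
    calls: list[DimerCall] = []
    for hp in plus:
        for hm in minus:
            first, second = (hp, hm) if hp.offset <= hm.offset else (hm, hp)
            spacer = second.offset - first.end
            if 0 <= spacer <= max_spacer:
                orientation = "head_to_head" if hm.offset < hp.offset else "tail_to_tail"
                calls.append(DimerCall(hp.seq_id, hp, hm, spacer, orientation))
    calls.sort(key=lambda c: (c.hit_plus.offset, c.hit_minus.offset))
    return calls


@dataclass
class SpacerDistribution:
    counts: Counter = field(default_factory=Counter)

    def add(self, spacer: int) -> None:
        self.counts[spacer] += 1

    @property
    def mode(self) -> int | None:
        """Spacer with the highest count; smallest spacer on ties."""
        if not self.counts:
            return None
        return min(self.counts, key=lambda s: (-self.counts[s], s))

    def as_dict(self) -> dict[int, int]:
        return dict(sorted(self.counts.items()))


@dataclass
class DimerScanSummary:
    n_scanned: int
    n_with_dimer: int
    fraction: float
    spacers: SpacerDistribution
    orientation_counts: Counter
    best_calls: dict[str, DimerCall]  # peak_id -> best (lowest combined p) dimer
    skipped_peaks: list[str]


def dimer_fraction_and_spacers(
    peaks: Sequence[Peak],
    genome: GenomeSequence,
    pwm: PWM,
    halfwidth: int = 50,
    p_cutoff: float = 1e-4,
    max_spacer: int = 20,
) -> DimerScanSummary:
    """Scan summit windows for inverted motif dimers.

    For each peak the +/- ``halfwidth`` summit window is scanned and dimers
    are detected; the summary reports the fraction of scanned peaks with at
    least one dimer and the spacer histogram over the best (lowest combined
    p-value; ties to the smallest spacer, then leftmost) dimer per peak.
    Peaks on chromosomes missing from the genome are skipped and reported.
    """
    dist = ScoreDistribution(pwm)
    spacers = SpacerDistribution()
    orientation_counts: Counter = Counter()
    best_calls: dict[str, DimerCall] = {}
    skipped: list[str] = []
    n_scanned = 0
    for p in peaks:
        if p.chrom not in genome:
            skipped.append(p.peak_id)
            continue
        n_scanned += 1
        window = genome.fetch_window(p.chrom, p.summit, halfwidth)
        hits = scan(pwm, window.sequence, p_cutoff=p_cutoff, seq_id=p.peak_id, dist=dist)
        calls = detect_dimers(hits, max_spacer=max_spacer)
        if not calls:
            continue
        best = min(calls, key=lambda c: (c.combined_p, c.spacer, c.hit_plus.offset))
        best_calls[p.peak_id] = best
        spacers.add(best.spacer)
        orientation_counts[best.orientation] += 1
    if skipped:
        logger.warning("%d peaks skipped (chromosome missing from genome)", len(skipped))
    fraction = len(best_calls) / n_scanned if n_scanned else 0.0
    return DimerScanSummary(
        n_scanned=n_scanned,
        n_with_dimer=len(best_calls),
        fraction=fraction,
        spacers=spacers,
        orientation_counts=orientation_counts,
        best_calls=best_calls,
        skipped_peaks=skipped,
    )
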