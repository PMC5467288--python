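"""Core coordinate types and readers/writers for gene models, peaks and sequences.

All coordinates inside the package are 0-based half-open on the forward
(reference) strand. Format converters (GTF is 1-based inclusive) live only in
this module, so every downstream module can assume a single convention.

The transcription start site (TSS) of a ``+``-strand gene is its ``start``;
for a ``-``-strand gene it is ``end - 1`` (the last base of the span).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')

VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class GeneModel:
    """Strand-aware gene span; the anchor for all distance/annotation logic."""

    gene_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: need 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class Peak:
    """Factor-labelled ChIP-seq interval with a summit and a tag-count score."""

    peak_id: str
    factor: str
    chrom: str
    start: int
    end: int
    summit: int  # absolute bp within [start, end)
    score: float  # total tags count (or signal value); >= 0

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"peak {self.peak_id}: negative start {self.start}")
        if not (self.start <= self.summit < self.end):
            raise ValueError(
                f"peak {self.peak_id}: summit {self.summit} outside [{self.start}, {self.end})"
            )
        if self.score < 0:
            raise ValueError(f"peak {self.peak_id}: negative score {self.score}")


@dataclass(frozen=True)
class Window:
    """A sub-sequence centred on a position, with clipping reported."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    sequence: str
    clipped: bool


class GenomeSequence:
    """chrom -> sequence over {A,C,G,T,N}; repeat-masked bases are N."""

    def __init__(self, sequences: dict[str, str]):
        self._seqs = {}
        for chrom, seq in sequences.items():
            seq = seq.upper()
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(f"chrom {chrom}: invalid bases {sorted(bad)}")
            self._seqs[chrom] = seq

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    @property
    def chroms(self) -> list[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def fetch_window(self, chrom: str, center: int, halfwidth: int) -> Window:
        """Return the inclusive window [center-halfwidth, center+halfwidth].

        The result has length ``2*halfwidth + 1`` unless clipped at a
        chromosome end, in which case ``clipped`` is set.
        """
        if halfwidth < 0:
            raise ValueError(f"halfwidth must be >= 0, got {halfwidth}")
        if chrom not in self._seqs:
            raise KeyError(f"unknown chromosome {chrom!r}")
        n = len(self._seqs[chrom])
        if not (0 <= center < n):
            raise ValueError(f"center {center} outside chromosome {chrom} of length {n}")
        lo = center - halfwidth
        hi = center + halfwidth + 1
        clipped = lo < 0 or hi > n
        lo_c, hi_c = max(lo, 0), min(hi, n)
        return Window(chrom, lo_c, hi_c, self._seqs[chrom][lo_c:hi_c], clipped)


def fetch_window(genome: GenomeSequence, chrom: str, center: int, halfwidth: int) -> Window:
    """Module-level convenience wrapper around :meth:`GenomeSequence.fetch_window`."""
    return genome.fetch_window(chrom, center, halfwidth)


# ---------------------------------------------------------------------------
# Gene model I/O
# ---------------------------------------------------------------------------

def read_gene_models(
    path: str | Path,
    format: str = "gtf",
    feature: str = "gene",
    id_attribute: str = "gene_id",
) -> list[GeneModel]:
    """Read gene models from GTF (Ensembl dialect) or BED12/BED6.

    GTF coordinates (1-based inclusive) are converted to the internal 0-based
    half-open convention. Only GTF records whose feature column equals
    ``feature`` are used. Duplicate gene ids raise; malformed lines raise with
    the offending line number.
    """
    fmt = format.lower()
    if fmt not in ("gtf", "bed12", "bed6", "bed"):
        raise ValueError(f"unsupported gene-model format {format!r}")
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            try:
                if fmt == "gtf":
                    if len(fields) < 9:
                        raise ValueError(f"expected 9 columns, got {len(fields)}")
                    if fields[2] != feature:
                        continue
                    attrs = dict(_GTF_ATTR_RE.findall(fields[8]))
                    if id_attribute not in attrs:
                        raise ValueError(f"missing attribute {id_attribute!r}")
                    gene = GeneModel(
                        gene_id=attrs[id_attribute],
                        chrom=fields[0],
                        start=int(fields[3]) - 1,  # 1-based inclusive -> 0-based
                        end=int(fields[4]),
                        strand=fields[6],
                    )
                else:
                    if len(fields) < 6:
                        raise ValueError(f"expected >= 6 BED columns, got {len(fields)}")
                    gene = GeneModel(
                        gene_id=fields[3],
                        chrom=fields[0],
                        start=int(fields[1]),
                        end=int(fields[2]),
                        strand=fields[5],
                    )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: parse error at line {lineno}: {exc}") from exc
            if gene.gene_id in seen:
                raise ValueError(f"{path}: duplicate gene_id {gene.gene_id!r} at line {lineno}")
            seen.add(gene.gene_id)
            genes.append(gene)
    if not genes:
        logger.warning("%s: no gene models read", path)
    return genes


def write_gene_models(
    genes: Iterable[GeneModel],
    path: str | Path,
    format: str = "gtf",
    feature: str = "gene",
    source: str = "soxgrn",
) -> None:
    fmt = format.lower()
    with open(path, "w") as fh:
        for g in genes:
            if fmt == "gtf":
                fh.write(
                    f"{g.chrom}\t{source}\t{feature}\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                    f'gene_id "{g.gene_id}";\n'
                )
            elif fmt in ("bed6", "bed12", "bed"):
                fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")
            else:
                raise ValueError(f"unsupported gene-model format {format!r}")


# ---------------------------------------------------------------------------
# Peak I/O
# ---------------------------------------------------------------------------

def _midpoint(start: int, end: int) -> int:
    return (start + end) // 2


def read_peaks(
    path: str | Path,
    format: str = "narrowpeak",
    factor: str = "",
    score_column: str = "signal",
) -> list[Peak]:
    """Read peaks from BED3/BED6 or ENCODE narrowPeak.

    narrowPeak column 10 is the summit offset from ``start`` (-1 allowed);
    when absent or -1 the floor midpoint is used. The peak score comes from
    column 5 (BED) or, for narrowPeak, from the signalValue column 7
    (``score_column='signal'``, the default) or column 5 (``'score'``).
    """
    fmt = format.lower()
    if fmt not in ("narrowpeak", "bed", "bed3", "bed6"):
        raise ValueError(f"unsupported peak format {format!r}")
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            f = line.split("\t")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                name = f[3] if len(f) > 3 and f[3] not in (".", "") else f"{factor or 'peak'}_{lineno}"
                if fmt == "narrowpeak":
                    if len(f) < 10:
                        raise ValueError(f"narrowPeak needs 10 columns, got {len(f)}")
                    score = float(f[6]) if score_column == "signal" else float(f[4])
                    offset = int(f[9])
                    summit = start + offset if offset >= 0 else _midpoint(start, end)
                else:
                    score = float(f[4]) if len(f) > 4 else 0.0
                    summit = _midpoint(start, end)
                peak = Peak(name, factor, chrom, start, end, summit, score)
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: parse error at line {lineno}: {exc}") from exc
            peaks.append(peak)
    if not peaks:
        logger.warning("%s: no peaks read", path)
    return peaks


def write_peaks(peaks: Iterable[Peak], path: str | Path, format: str = "narrowpeak") -> None:
    fmt = format.lower()
    with open(path, "w") as fh:
        for p in peaks:
            if fmt == "narrowpeak":
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t0\t.\t{p.score:g}\t-1\t-1\t"
                    f"{p.summit - p.start}\n"
                )
            elif fmt in ("bed", "bed6"):
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t{p.score:g}\t.\n")
            else:
                raise ValueError(f"unsupported peak format {format!r}")


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> GenomeSequence:
    return GenomeSequence({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})


def write_fasta(genome: GenomeSequence, path: str | Path) -> None:
    records = [SeqRecord(Seq(genome[c]), id=c, description="") for c in genome.chroms]
    SeqIO.write(records, str(path), "fasta")
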