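"""Positional annotation of ChIP-seq peaks relative to gene TSSs.

Each peak summit is assigned to its nearest gene (by TSS distance, same
chromosome) and the pair is classified into one of six positional classes.
Distances are strand-oriented: upstream means 5' of the TSS in the gene's
reading direction.

Classes are evaluated in strict precedence, with bounds closed at the near
edge and open at the far edge:

==========  ==========================================================
TSS         |d| <= 1 kb
PROMOTER    1 kb < upstream distance <= 5 kb (upstream only)
INTRAGENIC  summit inside the gene span, not TSS/PROMOTER
PROXIMAL    outside the gene and (5-10 kb upstream or 1-10 kb downstream)
DISTAL      outside the gene and 10 kb < |d| <= 100 kb
OTHER       outside the gene and |d| > 100 kb
==========  ==========================================================

The asymmetry of PROMOTER (upstream only) is deliberate: a summit 1-5 kb
downstream of the TSS but outside the gene falls through to PROXIMAL.
"""

from __future__ import annotations

import bisect
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .genome_model import GeneModel, Peak


class PositionClass(Enum):
    TSS = "TSS"
    PROMOTER = "PROMOTER"
    INTRAGENIC = "INTRAGENIC"
    PROXIMAL = "PROXIMAL"
    DISTAL = "DISTAL"
    OTHER = "OTHER"


@dataclass(frozen=True)
class PeakAnnotation:
    peak_id: str
    factor: str
    chrom: str
    summit: int
    gene_id: str
    position_class: PositionClass
    signed_distance: int  # summit - TSS, negated for '-' strand (upstream < 0)
    inside_gene: bool


def strand_oriented_distance(summit: int, gene: GeneModel) -> int:
    """Signed summit-TSS distance; negative = upstream (5' of the TSS)."""
    d = summit - gene.tss
    return d if gene.strand == "+" else -d


def classify(peak_summit: int, gene: GeneModel) -> PositionClass:
    """Classify a summit-gene pair on the same chromosome (see module docs)."""
    d = strand_oriented_distance(peak_summit, gene)
    up = -d if d < 0 else 0  # upstream distance
    down = d if d > 0 else 0
    inside = gene.contains(peak_summit)
    if abs(d) <= 1000:
        return PositionClass.TSS
    if 1000 < up <= 5000:
        return PositionClass.PROMOTER
    if inside:
        return PositionClass.INTRAGENIC
    if 5000 < up <= 10000 or 1000 < down <= 10000:
        return PositionClass.PROXIMAL
    if 10000 < abs(d) <= 100000:
        return PositionClass.DISTAL
    return PositionClass.OTHER


class _ChromIndex:
    """Genes of one chromosome sorted by (TSS, gene_id) for nearest queries."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.entries = sorted(genes, key=lambda g: (g.tss, g.gene_id))
        self.tss = [g.tss for g in self.entries]

    def nearest(self, summit: int) -> GeneModel:
        """Gene minimizing |summit - TSS|; ties by lexicographically smallest id."""
        i = bisect.bisect_left(self.tss, summit)
        best_d = None
        for j in (i - 1, i):
            if 0 <= j < len(self.tss):
                d = abs(self.tss[j] - summit)
                if best_d is None or d < best_d:
                    best_d = d
        assert best_d is not None
        # all genes at TSS == summit - best_d or summit + best_d are candidates
        candidates: list[GeneModel] = []
        for t in (summit - best_d, summit + best_d):
            lo = bisect.bisect_left(self.tss, t)
            hi = bisect.bisect_right(self.tss, t)
            candidates.extend(self.entries[lo:hi])
        return min(candidates, key=lambda g: g.gene_id)


def build_gene_index(genes: Iterable[GeneModel]) -> dict[str, _ChromIndex]:
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    return {c: _ChromIndex(gs) for c, gs in by_chrom.items()}


def annotate_nearest(
    peaks: Iterable[Peak], genes: Iterable[GeneModel]
) -> tuple[list[PeakAnnotation], list[str]]:
    """Annotate every peak against its nearest gene by TSS distance.

    Returns the annotations plus the ids of peaks on chromosomes that carry
    no genes (reported unannotated rather than dropped silently).
    """
    index = build_gene_index(genes)
    annotations: list[PeakAnnotation] = []
    unannotated: list[str] = []
    for p in peaks:
        if p.chrom not in index:
            unannotated.append(p.peak_id)
            continue
        g = index[p.chrom].nearest(p.summit)
        annotations.append(
            PeakAnnotation(
                peak_id=p.peak_id,
                factor=p.factor,
                chrom=p.chrom,
                summit=p.summit,
                gene_id=g.gene_id,
                position_class=classify(p.summit, g),
                signed_distance=strand_oriented_distance(p.summit, g),
                inside_gene=g.contains(p.summit),
            )
        )
    return annotations, unannotated


def class_distribution(
    annotations: Sequence[PeakAnnotation],
) -> tuple[dict[PositionClass, float], dict[PositionClass, int]]:
    """Fraction and count of annotations per positional class (fractions sum to 1)."""
    if not annotations:
        raise ValueError("class_distribution requires at least one annotation")
    counts = Counter(a.position_class for a in annotations)
    total = len(annotations)
    fractions = {c: counts.get(c, 0) / total for c in PositionClass}
    return fractions, {c: counts.get(c, 0) for c in PositionClass}


def annotations_to_frame(annotations: Sequence[PeakAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "peak_id": [a.peak_id for a in annotations],
            "factor": [a.factor for a in annotations],
            "chrom": [a.chrom for a in annotations],
            "summit": [a.summit for a in annotations],
            "gene_id": [a.gene_id for a in annotations],
            "signed_distance": [a.signed_distance for a in annotations],
            "position_class": [a.position_class.value for a in annotations],
            "inside_gene": [a.inside_gene for a in annotations],
        }
    )


def write_annotations(annotations: Sequence[PeakAnnotation], path: str | Path) -> None:
    annotations_to_frame(annotations).to_csv(path, sep="\t", index=False)
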