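"""DE x binding integration: direct-target calling.

Three modes of evidence integration are provided, mirroring how
loss-of-function expression data are combined with ChIP-seq binding:

* ``direct_targets_nearest`` -- a gene is a direct target of a factor iff it
  is differentially expressed in that factor's knockout design AND is the
  nearest gene (by TSS) of at least one of the factor's peaks.
* ``assign_flanking`` -- each peak summit is assigned the nearest gene on
  each reference side (within a distance cap), so genes need not be the
  single nearest to count as bound.
* ``trio_targets`` -- genes differentially expressed in BOTH knockout
  designs and flank-attached to at least one peak of EVERY factor.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .diffexpr import DEGeneSet
from .genome_model import GeneModel, Peak
from .peak_annotation import PeakAnnotation


@dataclass(frozen=True)
class TargetCall:
    gene_id: str
    factors: tuple[str, ...]
    directions: tuple[tuple[str, str], ...]  # (label, 'up'/'down') pairs
    evidence: tuple[tuple[str, str, str, int], ...]  # (factor, peak_id, label, distance)
    mode: str  # 'nearest' or 'flank'

    def evidence_for(self, factor: str) -> list[tuple[str, str, int]]:
        return [(pid, lab, d) for fac, pid, lab, d in self.evidence if fac == factor]


@dataclass(frozen=True)
class FlankAssignment:
    peak_id: str
    factor: str
    chrom: str
    summit: int
    upstream_gene: str | None  # nearest TSS <= summit on the reference
    downstream_gene: str | None  # nearest TSS > summit
    upstream_distance: int | None
    downstream_distance: int | None
    upstream_intragenic: bool = False
    downstream_intragenic: bool = False

    def attached_genes(self) -> list[tuple[str, str, int]]:
        out = []
        if self.upstream_gene is not None:
            out.append((self.upstream_gene, "upstream", self.upstream_distance))
        if self.downstream_gene is not None:
            out.append((self.downstream_gene, "downstream", self.downstream_distance))
        return out


def direct_targets_nearest(
    de_set: DEGeneSet, annotations: Sequence[PeakAnnotation], factor: str
) -> list[TargetCall]:
    """Per-factor direct targets: DE genes that are nearest gene of >=1 peak."""
    for a in annotations:
        if a.factor and a.factor != factor:
            raise ValueError(
                f"annotation {a.peak_id} carries factor {a.factor!r}, expected {factor!r}"
            )
    by_gene: dict[str, list[PeakAnnotation]] = {}
    for a in annotations:
        by_gene.setdefault(a.gene_id, []).append(a)
    calls = []
    for gene_id in sorted(set(by_gene) & de_set.genes):
        evidence = tuple(
            (factor, a.peak_id, a.position_class.value, a.signed_distance)
            for a in by_gene[gene_id]
        )
        calls.append(
            TargetCall(
                gene_id=gene_id,
                factors=(factor,),
                directions=((factor, de_set.direction_of(gene_id)),),
                evidence=evidence,
                mode="nearest",
            )
        )
    return calls


class _TssIndex:
    def __init__(self, genes: Sequence[GeneModel]):
        self.entries = sorted(genes, key=lambda g: (g.tss, g.gene_id))
        self.tss = [g.tss for g in self.entries]

    def flanks(self, summit: int, cap: int) -> tuple[GeneModel | None, GeneModel | None]:
        """Nearest gene with TSS <= summit and nearest with TSS > summit, within cap."""
        i = bisect.bisect_right(self.tss, summit)
        up = self.entries[i - 1] if i > 0 else None
        down = self.entries[i] if i < len(self.entries) else None
        if up is not None and summit - up.tss > cap:
            up = None
        if down is not None and down.tss - summit > cap:
            down = None
        return up, down


def assign_flanking(
    peaks: Iterable[Peak], genes: Iterable[GeneModel], distance_cap: int = 1_000_000
) -> list[FlankAssignment]:
    """Assign each peak the nearest gene (by TSS) on each reference side.

    A gene with TSS exactly at the summit counts as the upstream-side gene.
    A gene whose span contains the summit is attached to its own side and
    flagged intragenic. Sides without a gene within ``distance_cap`` are None.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    index = {c: _TssIndex(gs) for c, gs in by_chrom.items()}
    out: list[FlankAssignment] = []
    for p in peaks:
        up = down = None
        if p.chrom in index:
            up, down = index[p.chrom].flanks(p.summit, distance_cap)
        out.append(
            FlankAssignment(
                peak_id=p.peak_id,
                factor=p.factor,
                chrom=p.chrom,
                summit=p.summit,
                upstream_gene=up.gene_id if up else None,
                downstream_gene=down.gene_id if down else None,
                upstream_distance=p.summit - up.tss if up else None,
                downstream_distance=down.tss - p.summit if down else None,
                upstream_intragenic=bool(up and up.contains(p.summit)),
                downstream_intragenic=bool(down and down.contains(p.summit)),
            )
        )
    return out


def trio_targets(
    de_first: DEGeneSet,
    de_second: DEGeneSet,
    flanks_by_factor: Mapping[str, Sequence[FlankAssignment]],
    factors: Sequence[str] = ("Sox9", "Sox5", "Sox6"),
) -> list[TargetCall]:
    """Genes DE in both designs and flank-attached to peaks of every factor.

    ``de_first``/``de_second`` are the two knockout designs (e.g. the single
    Sox9-null and the Sox5/Sox6 double-null arrays). Directions from both DE
    sets are reported; no direction agreement is required.
    """
    missing = [f for f in factors if f not in flanks_by_factor]
    if missing:
        raise ValueError(f"missing flank assignments for factors {missing}")
    attached: dict[str, dict[str, list[tuple[str, str, int]]]] = {f: {} for f in factors}
    for f in factors:
        for fl in flanks_by_factor[f]:
            for gene_id, side, dist in fl.attached_genes():
                attached[f].setdefault(gene_id, []).append((fl.peak_id, side, dist))
    qualifying = de_first.genes & de_second.genes
    for f in factors:
        qualifying &= set(attached[f])
    calls = []
    label_first = de_first.label or "first"
    label_second = de_second.label or "second"
    for gene_id in sorted(qualifying):
        evidence = tuple(
            (f, pid, side, dist)
            for f in factors
            for pid, side, dist in sorted(attached[f][gene_id])
        )
        calls.append(
            TargetCall(
                gene_id=gene_id,
                factors=tuple(factors),
                directions=(
                    (label_first, de_first.direction_of(gene_id)),
                    (label_second, de_second.direction_of(gene_id)),
                ),
                evidence=evidence,
                mode="flank",
            )
        )
    return calls
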