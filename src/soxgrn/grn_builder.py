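"""Signed gene-regulatory-network assembly and export.

The sign convention follows loss-of-function logic: a gene DOWN-regulated in
a factor's knockout is inferred to be ACTIVATED by that factor; a gene
UP-regulated is inferred to be REPRESSED. Direct edges carry binding
evidence (peak ids); optional indirect edges are DE genes without binding
evidence, under the same sign rule. Factor self-loops (autoregulation) are
permitted.

Graphs export to SIF (interaction labels ``activates``/``represses``),
GraphML and node-link JSON; the JSON round-trips losslessly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .diffexpr import DEGeneSet
from .target_integration import TargetCall

ACTIVATED = "activated"
REPRESSED = "repressed"

_SIGN_FROM_DIRECTION = {"down": ACTIVATED, "up": REPRESSED}
_SIF_LABEL = {ACTIVATED: "activates", REPRESSED: "represses"}


@dataclass(frozen=True)
class GRNEdge:
    factor: str
    gene_id: str
    sign: str  # 'activated' or 'repressed'
    mode: str  # 'direct' or 'indirect'
    evidence: tuple[str, ...]  # peak ids; empty iff indirect
    fold_change: float
    conflict: bool = False

    def __post_init__(self) -> None:
        if self.sign not in (ACTIVATED, REPRESSED):
            raise ValueError(f"invalid sign {self.sign!r}")
        if self.mode == "direct" and not self.evidence:
            raise ValueError(f"direct edge {self.factor}->{self.gene_id} without evidence")
        if self.mode == "indirect" and self.evidence:
            raise ValueError(f"indirect edge {self.factor}->{self.gene_id} with evidence")


@dataclass
class GRN:
    factors: tuple[str, ...]
    edges: list[GRNEdge] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for e in self.edges:
            key = (e.factor, e.gene_id, e.mode)
            if key in seen:
                raise ValueError(f"duplicate edge {key}")
            seen.add(key)

    @property
    def nodes(self) -> set[str]:
        return set(self.factors) | {e.gene_id for e in self.edges}

    def edge_set(self, modes: Sequence[str] = ("direct", "indirect")) -> set[tuple[str, str, str]]:
        return {(e.factor, e.gene_id, e.sign) for e in self.edges if e.mode in modes}


def build_grn(
    de_sets: Mapping[str, DEGeneSet],
    target_calls: Mapping[str, Sequence[TargetCall]],
    include_indirect: bool = False,
) -> GRN:
    """Assemble factor->gene edges from DE sets and direct-target calls.

    ``de_sets`` maps each factor to the DE gene set of its loss-of-function
    design (Sox5 and Sox6 may share one double-null set). A target gene
    absent from the relevant DE set is an integration bug and raises.
    """
    factors = tuple(sorted(target_calls))
    edges: list[GRNEdge] = []
    for factor in factors:
        de = de_sets[factor]
        targeted: set[str] = set()
        for call in target_calls[factor]:
            gene = call.gene_id
            if gene in targeted:
                continue
            if gene not in de.genes:
                raise ValueError(
                    f"target {gene} of {factor} absent from its DE set (integration bug)"
                )
            row = de.table.loc[gene]
            peak_ids = tuple(pid for fac, pid, _lab, _d in call.evidence if fac == factor)
            edges.append(
                GRNEdge(
                    factor=factor,
                    gene_id=gene,
                    sign=_SIGN_FROM_DIRECTION[str(row["direction"])],
                    mode="direct",
                    evidence=peak_ids,
                    fold_change=float(row["fold_change"]),
                    conflict=bool(row.get("conflict", False)),
                )
            )
            targeted.add(gene)
        if include_indirect:
            for gene in sorted(de.genes - targeted):
                row = de.table.loc[gene]
                edges.append(
                    GRNEdge(
                        factor=factor,
                        gene_id=gene,
                        sign=_SIGN_FROM_DIRECTION[str(row["direction"])],
                        mode="indirect",
                        evidence=(),
                        fold_change=float(row["fold_change"]),
                        conflict=bool(row.get("conflict", False)),
                    )
                )
    return GRN(factors=factors, edges=edges)


def to_networkx(grn: GRN) -> nx.DiGraph:
    g = nx.DiGraph()
    for node in sorted(grn.nodes):
        g.add_node(node, kind="factor" if node in grn.factors else "gene")
    for e in grn.edges:
        g.add_edge(
            e.factor,
            e.gene_id,
            sign=e.sign,
            mode=e.mode,
            evidence=",".join(e.evidence),
            fold_change=e.fold_change,
            conflict=e.conflict,
        )
    return g


def export_graph(grn: GRN, path: str | Path, format: str = "sif") -> None:
    """Write the network as SIF, GraphML or node-link JSON."""
    fmt = format.lower()
    g = to_networkx(grn)
    if fmt == "sif":
        with open(path, "w") as fh:
            for e in grn.edges:
                fh.write(f"{e.factor}\t{_SIF_LABEL[e.sign]}\t{e.gene_id}\n")
    elif fmt == "graphml":
        nx.write_graphml(g, str(path))
    elif fmt == "json":
        data = nx.node_link_data(g, edges="edges")
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)
    else:
        raise ValueError(f"unknown graph format {format!r}")


def import_graph_json(path: str | Path) -> GRN:
    """Re-load a node-link JSON export into a GRN (round-trip safe)."""
    with open(path) as fh:
        data = json.load(fh)
    g = nx.node_link_graph(data, directed=True, edges="edges")
    factors = tuple(sorted(n for n, d in g.nodes(data=True) if d.get("kind") == "factor"))
    edges = [
        GRNEdge(
            factor=u,
            gene_id=v,
            sign=d["sign"],
            mode=d["mode"],
            evidence=tuple(x for x in d.get("evidence", "").split(",") if x),
            fold_change=float(d["fold_change"]),
            conflict=bool(d.get("conflict", False)),
        )
        for u, v, d in g.edges(data=True)
    ]
    return GRN(factors=factors, edges=edges)


def edge_table(grn: GRN) -> pd.DataFrame:
    """Attribute table for Cytoscape-style import."""
    return pd.DataFrame(
        [
            {
                "factor": e.factor,
                "gene_id": e.gene_id,
                "sign": e.sign,
                "mode": e.mode,
                "evidence": ",".join(e.evidence),
                "fold_change": e.fold_change,
                "conflict": e.conflict,
            }
            for e in grn.edges
        ]
    )
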