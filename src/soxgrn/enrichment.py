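"""Hypergeometric term enrichment with fold-enrichment ranking.

For a query gene list of size n drawn from a background universe of size N,
a term annotating K background genes and k query genes is scored with the
upper-tail hypergeometric probability P(X >= k) and the fold enrichment
(k/n)/(K/N). P-values are BH-adjusted across all tested terms; results are
ranked by fold enrichment. The DAVID-style EASE variant (substitute k-1 for
k, floored at 0) is available behind a flag.

When a differential gene list exceeds ``max_n`` (default 3000), the genes
with the highest fold change are kept before testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import DEGeneSet, bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class AnnotationMap:
    """term_id -> gene set over a background universe.

    Every annotated gene must be in the background; terms annotating no
    background gene are skipped with a warning.
    """

    terms: dict[str, frozenset[str]]
    background: frozenset[str]
    term_names: dict[str, str] | None = None

    def __post_init__(self) -> None:
        cleaned = {}
        for term_id, genes in self.terms.items():
            genes = frozenset(genes) & self.background
            stray = len(self.terms[term_id]) - len(genes)
            if stray:
                raise ValueError(
                    f"term {term_id}: {stray} annotated genes missing from background"
                )
            if not genes:
                logger.warning("term %s annotates no background gene; skipped", term_id)
                continue
            cleaned[term_id] = genes
        self.terms = cleaned

    def name_of(self, term_id: str) -> str:
        return (self.term_names or {}).get(term_id, term_id)

    @classmethod
    def read(
        cls,
        annotation_path: str | Path,
        background: Iterable[str],
        names_path: str | Path | None = None,
    ) -> "AnnotationMap":
        """Read a 2-column (gene_id, term_id) TSV plus an optional term-name table."""
        df = pd.read_csv(annotation_path, sep="\t", header=None, names=["gene_id", "term_id"],
                         comment="#")
        terms: dict[str, set[str]] = {}
        for gene, term in zip(df["gene_id"].astype(str), df["term_id"].astype(str)):
            terms.setdefault(term, set()).add(gene)
        names = None
        if names_path is not None:
            ndf = pd.read_csv(names_path, sep="\t", header=None, names=["term_id", "name"])
            names = dict(zip(ndf["term_id"].astype(str), ndf["name"].astype(str)))
        return cls({t: frozenset(g) for t, g in terms.items()}, frozenset(map(str, background)),
                   names)


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # query genes with term
    n: int  # query size
    K: int  # background genes with term
    N: int  # background size
    p_raw: float
    p_adj: float
    fold_enrichment: float  # (k/n)/(K/N)


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n)."""
    return float(hypergeom.sf(k - 1, N, K, n))


def select_gene_list(de_set: DEGeneSet | pd.DataFrame, max_n: int = 3000) -> list[str]:
    """All genes if the set is small; else the max_n with the highest fold change.

    Ties at the boundary are broken deterministically by gene_id.
    """
    table = de_set.table if isinstance(de_set, DEGeneSet) else de_set
    if table.empty:
        raise ValueError("empty gene set")
    if len(table) <= max_n:
        return sorted(table.index)
    fold = table["fold_change"]
    order = sorted(table.index, key=lambda g: (-fold[g], g))
    return order[:max_n]


def term_enrichment(
    query: Iterable[str], annotation: AnnotationMap, ease: bool = False
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of every term, ranked by fold enrichment.

    Query genes outside the background are reported and pruned. All tested
    terms are returned (use :func:`significant_terms` / :func:`top_terms`
    for the BH p_adj < 0.05 filter); ranking is by descending fold
    enrichment, ties by ascending p_raw then term_id.
    """
    query_set = set(map(str, query))
    stray = query_set - annotation.background
    if stray:
        logger.warning("%d query genes outside the background pruned", len(stray))
        query_set &= annotation.background
    n = len(query_set)
    N = len(annotation.background)
    if n == 0:
        raise ValueError("query is empty after pruning to the background")
    rows = []
    for term_id, genes in sorted(annotation.terms.items()):
        K = len(genes)
        k = len(genes & query_set)
        k_test = max(k - 1, 0) if ease else k
        p_raw = hypergeom_upper_tail(k_test, N, K, n)
        fold = (k / n) / (K / N)
        rows.append((term_id, k, K, p_raw, fold))
    p_adj = bh_adjust([r[3] for r in rows])
    results = [
        EnrichmentResult(
            term_id=term_id,
            term_name=annotation.name_of(term_id),
            k=k, n=n, K=K, N=N,
            p_raw=p_raw, p_adj=float(pa), fold_enrichment=fold,
        )
        for (term_id, k, K, p_raw, fold), pa in zip(rows, p_adj)
    ]
    results.sort(key=lambda r: (-r.fold_enrichment, r.p_raw, r.term_id))
    return results


def significant_terms(
    results: Sequence[EnrichmentResult], alpha: float = 0.05
) -> list[EnrichmentResult]:
    return [r for r in results if r.p_adj < alpha]


def top_terms(
    results: Sequence[EnrichmentResult], n: int = 10, alpha: float = 0.05
) -> list[EnrichmentResult]:
    """First n surviving (p_adj < alpha) terms of the ranked results."""
    return significant_terms(results, alpha)[:n]


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id, "term_name": r.term_name,
                "k": r.k, "n": r.n, "K": r.K, "N": r.N,
                "p_raw": r.p_raw, "p_adj": r.p_adj,
                "fold_enrichment": r.fold_enrichment,
            }
            for r in results
        ]
    )
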