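"""Process-gene projection network and GO term enrichment.

Genes annotated to biological-process terms form a bipartite graph; the
one-mode projection connects two genes with an edge weighted by the
number of shared terms.  Enrichment uses the one-sided hypergeometric
upper tail with Bonferroni adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom


@dataclass
class AnnotationTable:
    """gene -> set of BP term ids, plus the background universe."""

    terms: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.universe = set(self.universe) | set(self.terms)

    def genes_with(self, term: str) -> set[str]:
        return {g for g, ts in self.terms.items() if term in ts}

    def all_terms(self) -> set[str]:
        out: set[str] = set()
        for ts in self.terms.values():
            out |= ts
        return out


def project(
    annotations: AnnotationTable, genes: Iterable[str] | None = None
) -> nx.Graph:
    """One-mode projection over ``genes`` (default: whole universe).

    Edge {i, j} exists iff the two genes share >=1 term; weight is the
    intersection size.  Genes with no shared terms stay isolated nodes.
    """
    if genes is None:
        gene_list = sorted(annotations.universe)
    else:
        gene_list = sorted(set(genes))
        outside = set(gene_list) - annotations.universe
        if outside:
            raise KeyError(f"genes outside the universe: {sorted(outside)[:5]}")
    g = nx.Graph()
    g.add_nodes_from(gene_list)
    # accumulate shared-term counts term-by-term: cheaper than all pairs
    per_term: dict[str, list[str]] = {}
    gene_set = set(gene_list)
    for gene in gene_list:
        for term in annotations.terms.get(gene, ()):  # sorted not needed
            per_term.setdefault(term, []).append(gene)
    weights: dict[tuple[str, str], int] = {}
    for term, members in per_term.items():
        members = [m for m in members if m in gene_set]
        members.sort()
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                key = (members[i], members[j])
                weights[key] = weights.get(key, 0) + 1
    for (u, v), w in weights.items():
        g.add_edge(u, v, weight=w)
    return g


def family_link_density(
    graph: nx.Graph, families: Mapping[str, str], family: str
) -> float:
    """Edge density within one family's node set: E_f / C(n_f, 2)."""
    members = [v for v in graph.nodes if families.get(v) == family]
    n = len(members)
    if n < 2:
        raise ValueError(f"family {family!r} has {n} nodes; density undefined")
    mset = set(members)
    edges = sum(1 for u, v in graph.edges if u in mset and v in mset)
    return edges / (n * (n - 1) / 2)


def enrich(
    foreground: Iterable[str],
    annotations: AnnotationTable,
    alpha: float = 0.05,
    test_all_terms: bool = False,
) -> pd.DataFrame:
    """Hypergeometric enrichment of terms in ``foreground`` vs universe.

    For each term with k foreground genes out of n foreground, K universe
    genes carrying the term out of N, p = P(X >= k).  Adjusted p is
    Bonferroni, ``min(1, p * #tested)``; enriched iff adjusted <= alpha
    (boundary inclusive).  By default only terms present in the
    foreground are tested; ``test_all_terms`` widens the correction to
    every annotated term.
    """
    fg = set(foreground)
    if not fg:
        raise ValueError("empty foreground")
    outside = fg - annotations.universe
    if outside:
        raise KeyError(f"foreground outside universe: {sorted(outside)[:5]}")
    big_n = len(annotations.universe)
    n = len(fg)
    fg_terms: set[str] = set()
    for g in fg:
        fg_terms |= annotations.terms.get(g, set())
    tested = sorted(annotations.all_terms() if test_all_terms else fg_terms)
    n_tested = len(tested)
    rows = []
    for term in tested:
        carriers = annotations.genes_with(term)
        big_k = len(carriers)
        k = len(carriers & fg)
        p = float(hypergeom.sf(k - 1, big_n, big_k, n))
        adj = min(1.0, p * n_tested)
        rows.append(
            {
                "term": term,
                "foreground_count": k,
                "universe_count": big_k,
                "p_value": p,
                "p_adjusted": adj,
                "enriched": bool(adj <= alpha),
            }
        )
    return pd.DataFrame(
        rows, columns=["term", "foreground_count", "universe_count",
                       "p_value", "p_adjusted", "enriched"]
    )
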