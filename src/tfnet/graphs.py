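"""Shared graph metrics used by the co-expression, process-gene and
regulatory network stages.

Graphs are plain :class:`networkx.Graph` / :class:`networkx.DiGraph`
instances; the helpers here add the small set of degree/component/hub
summaries the pipeline reports, with deterministic tie-breaking.
"""

from __future__ import annotations

from typing import Hashable

import networkx as nx

__all__ = [
    "average_degree",
    "connected_components",
    "largest_component",
    "hub_report",
    "degree_sum_check",
]


def average_degree(graph: nx.Graph) -> float:
    """Mean degree of ``graph``.

    Undirected: ``2E/N``.  Directed: ``E/N`` (mean in-degree equals mean
    out-degree, so one number suffices).

    Raises
    ------
    ValueError
        If the graph has no nodes.
    """
    n = graph.number_of_nodes()
    if n == 0:
        raise ValueError("average degree undefined for an empty node set")
    e = graph.number_of_edges()
    if graph.is_directed():
        return e / n
    return 2.0 * e / n


def connected_components(graph: nx.Graph) -> list[set[Hashable]]:
    """Partition of nodes into connected components, largest first.

    Directed graphs use weak connectivity.  Components of equal size are
    ordered by their smallest node label (as string) for determinism.
    """
    if graph.is_directed():
        comps = nx.weakly_connected_components(graph)
    else:
        comps = nx.connected_components(graph)
    return sorted(
        (set(c) for c in comps),
        key=lambda c: (-len(c), min(str(v) for v in c)),
    )


def largest_component(graph: nx.Graph) -> set[Hashable]:
    """Node set of the largest (weakly) connected component."""
    comps = connected_components(graph)
    if not comps:
        return set()
    return comps[0]


def hub_report(graph: nx.Graph, k: int) -> list[tuple[Hashable, int]]:
    """Top-``k`` nodes by degree as ``(node, degree)`` pairs.

    For directed graphs total degree (in + out) is used; see
    :func:`hub_report_directed` for the split ranking.  Ordering is
    degree-descending with ties broken by ascending label.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(graph.degree(), key=lambda nd: (-nd[1], str(nd[0])))
    return ranked[:k]


def hub_report_directed(
    graph: nx.DiGraph, k: int
) -> dict[str, list[tuple[Hashable, int]]]:
    """Top-``k`` nodes by in-degree and by out-degree separately."""
    if k < 1:
        raise ValueError("k must be >= 1")
    by_in = sorted(graph.in_degree(), key=lambda nd: (-nd[1], str(nd[0])))
    by_out = sorted(graph.out_degree(), key=lambda nd: (-nd[1], str(nd[0])))
    return {"in": by_in[:k], "out": by_out[:k]}


def degree_sum_check(graph: nx.Graph) -> bool:
    """Handshake-lemma conservation check.

    Undirected: degree sum equals ``2E``.  Directed: in-degree sum and
    out-degree sum both equal ``E``.
    """
    e = graph.number_of_edges()
    if graph.is_directed():
        return (
            sum(d for _, d in graph.in_degree()) == e
            and sum(d for _, d in graph.out_degree()) == e
        )
    return sum(d for _, d in graph.degree()) == 2 * e
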