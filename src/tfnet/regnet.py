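"""Directed regulatory-graph analysis: homolog label transfer,
subnetwork extraction, triangle motifs and cross-network intersection.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import networkx as nx

logger = logging.getLogger(__name__)


def transfer_deg_labels(
    graph: nx.DiGraph,
    homology: Iterable[tuple[str, str]],
    deg_treatments: Mapping[str, set[str]],
) -> dict[str, set[str]]:
    """Label graph nodes with the treatments of their DEG homologs.

    ``homology`` yields (graph_gene, partner_gene) pairs, possibly
    many-to-many; ``deg_treatments`` maps partner gene -> treatments
    under which it is a DEG.  A node gets a treatment label iff at least
    one partner is a DEG for it (OR over partners).  Labels are also
    stored on the nodes as the ``deg_treatments`` attribute.
    """
    labels: dict[str, set[str]] = {}
    for node, partner in homology:
        if node not in graph:
            continue
        got = deg_treatments.get(partner, set())
        if got:
            labels.setdefault(node, set()).update(got)
    for node, ts in labels.items():
        graph.nodes[node]["deg_treatments"] = set(ts)
    return labels


def focal_subnetwork(
    graph: nx.DiGraph, focal: Iterable[str]
) -> tuple[nx.DiGraph, nx.DiGraph, dict[str, tuple[int, int]]]:
    """Induced subgraph on ``focal`` plus its one-step neighborhood.

    Returns ``(induced, shell, degrees)`` where ``shell`` is induced on
    focal nodes and their direct regulators/targets, and ``degrees``
    maps each focal node to its (in, out) degree in the full graph.
    Focal members missing from the graph are logged and skipped.
    """
    focal = set(focal)
    if not focal:
        raise ValueError("empty focal set")
    present = focal & set(graph.nodes)
    missing = focal - present
    if missing:
        logger.info("%d focal genes absent from the graph", len(missing))
    induced = graph.subgraph(present).copy()
    shell_nodes = set(present)
    for v in present:
        shell_nodes.update(graph.predecessors(v))
        shell_nodes.update(graph.successors(v))
    shell = graph.subgraph(shell_nodes).copy()
    degrees = {
        v: (graph.in_degree(v), graph.out_degree(v)) for v in sorted(present)
    }
    return induced, shell, degrees


def count_triangles(graph: nx.Graph) -> dict:
    """Triangles of the underlying undirected skeleton, with the directed
    orientation class of each triple.

    Orientation classes (directed input only): ``cyclic`` (a 3-cycle
    using single directions), ``feed_forward`` (acyclic orientation),
    ``with_mutual`` (at least one edge is reciprocated).  Undirected
    input reports the plain count.
    """
    directed = graph.is_directed()
    skeleton = nx.Graph()
    skeleton.add_nodes_from(graph.nodes)
    skeleton.add_edges_from((u, v) for u, v in graph.edges if u != v)
    triangles: list[tuple] = []
    classes = {"cyclic": 0, "feed_forward": 0, "with_mutual": 0}
    adj = {v: set(skeleton.neighbors(v)) for v in skeleton.nodes}
    # deterministic enumeration: each triangle found once via its lowest edge
    nodes_sorted = sorted(skeleton.nodes, key=str)
    index = {v: i for i, v in enumerate(nodes_sorted)}
    for u, v in skeleton.edges:
        a, b = (u, v) if index[u] < index[v] else (v, u)
        for w in adj[a] & adj[b]:
            if index[w] > index[b]:
                triangles.append((a, b, w))
    if directed:
        for a, b, w in triangles:
            mutual = sum(
                1
                for x, y in ((a, b), (b, w), (a, w))
                if graph.has_edge(x, y) and graph.has_edge(y, x)
            )
            if mutual > 0:
                classes["with_mutual"] += 1
            else:
                # orient each undirected edge by its single direction
                dg = nx.DiGraph()
                for x, y in ((a, b), (b, w), (a, w)):
                    if graph.has_edge(x, y):
                        dg.add_edge(x, y)
                    else:
                        dg.add_edge(y, x)
                if nx.is_directed_acyclic_graph(dg):
                    classes["feed_forward"] += 1
                else:
                    classes["cyclic"] += 1
    out = {"count": len(triangles), "triangles": sorted(triangles)}
    if directed:
        out["orientation_classes"] = classes
    return out


def intersect_networks(g1: nx.Graph, g2: nx.Graph) -> nx.Graph:
    """Graph on the common undirected edges of two networks.

    Directed inputs are symmetrized first (logged).  The result contains
    only the endpoints of shared edges; the summary counts are stored as
    graph attributes ``shared_edges`` / ``node_count``.
    """
    def undirect(g: nx.Graph) -> set[frozenset]:
        if g.is_directed():
            logger.info("symmetrizing a directed graph for intersection")
        return {frozenset((u, v)) for u, v in g.edges if u != v}

    shared = undirect(g1) & undirect(g2)
    out = nx.Graph()
    for e in shared:
        u, v = sorted(e, key=str)
        out.add_edge(u, v)
    out.graph["shared_edges"] = out.number_of_edges()
    out.graph["node_count"] = out.number_of_nodes()
    return out


def downstream_response_summary(
    graph: nx.DiGraph,
    labels: Mapping[str, set[str]],
    regulators_by_family: Mapping[str, Iterable[str]],
) -> dict:
    """Distinct DEG-labeled targets regulated by each family.

    For each family: the number of distinct out-neighbors of its member
    regulators that carry at least one DEG label, overall and per
    treatment (with per-treatment fractions of the overall set).
    A target regulated by several same-family members counts once.
    """
    out: dict[str, dict] = {}
    for family, members in sorted(regulators_by_family.items()):
        targets: set[str] = set()
        for m in members:
            if m in graph:
                targets.update(graph.successors(m))
        deg_targets = {t for t in targets if labels.get(t)}
        per_treatment: dict[str, int] = {}
        for t in deg_targets:
            for treatment in labels[t]:
                per_treatment[treatment] = per_treatment.get(treatment, 0) + 1
        total = len(deg_targets)
        out[family] = {
            "regulated_deg_targets": total,
            "per_treatment": dict(sorted(per_treatment.items())),
            "per_treatment_fraction": {
                k: (v / total if total else 0.0)
                for k, v in sorted(per_treatment.items())
            },
        }
    return out
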