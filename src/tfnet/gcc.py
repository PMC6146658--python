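"""Grey relational (grey correlation) analysis and co-expression network
construction.

For a reference sequence ``x0`` and comparison sequences ``x_i`` over n
points, the pointwise coefficient is

    xi_i(k) = (gmin + rho * gmax) / (|x0(k) - x_i(k)| + rho * gmax)

where ``gmin``/``gmax`` are the global min/max of |x0(k) - x_i(k)| over
the whole comparison set for this reference, and ``rho`` is the
resolution ratio (default 0.5).  The overall coefficient ``r_0i`` is the
mean of xi_i(k) over k.  Taking each gene in turn as the reference gives
a generally asymmetric square matrix; thresholding it with an OR rule
and max-weight yields the undirected co-expression graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .graphs import average_degree, connected_components

logger = logging.getLogger(__name__)

DEFAULT_RHO = 0.5
DEFAULT_TAU = 0.94


@dataclass
class GreyMatrix:
    """Square matrix of overall grey correlation coefficients.

    ``r.loc[g, h]`` is the coefficient with ``g`` as the reference
    sequence; the matrix is generally asymmetric.  Diagonal is 1.
    """

    r: pd.DataFrame
    rho: float
    n: int  # sequence length (number of treatments)


def gcc_pointwise(
    x0: Sequence[float],
    xi: Sequence[float],
    global_min: float,
    global_max: float,
    rho: float = DEFAULT_RHO,
) -> np.ndarray:
    """Pointwise grey coefficients xi_i(k) for one comparison sequence."""
    a = np.asarray(x0, dtype=float)
    b = np.asarray(xi, dtype=float)
    if a.shape != b.shape:
        raise ValueError("x0 and xi must have equal length")
    if rho < 0:
        raise ValueError("rho must be non-negative")
    if global_max < global_min or global_min < 0:
        raise ValueError("need global_max >= global_min >= 0")
    if global_max == 0:
        return np.ones_like(a)
    delta = np.abs(a - b)
    return (global_min + rho * global_max) / (delta + rho * global_max)


def gcc_overall(xi_vector: Sequence[float]) -> float:
    """Overall coefficient: arithmetic mean of the pointwise values."""
    v = np.asarray(xi_vector, dtype=float)
    if v.size == 0:
        raise ValueError("empty pointwise coefficient vector")
    return float(v.mean())


def gcc_matrix_values(x: np.ndarray, rho: float = DEFAULT_RHO) -> np.ndarray:
    """Grey correlation matrix for rows of ``x`` (genes x points).

    Row ``g`` holds overall coefficients with gene ``g`` as reference;
    global extrema are recomputed per reference row over all *other*
    genes and all points.  Diagonal is 1.
    """
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in the input matrix")
    m = x.shape[0]
    if m < 2:
        raise ValueError("need >=2 sequences")
    r = np.ones((m, m))
    others = np.arange(m)
    for g in range(m):
        delta = np.abs(x[g][None, :] - x)  # (m, n)
        mask = others != g
        gmin = delta[mask].min()
        gmax = delta[mask].max()
        if gmax == 0:
            r[g, :] = 1.0
            continue
        xi = (gmin + rho * gmax) / (delta + rho * gmax)
        r[g, :] = xi.mean(axis=1)
        r[g, g] = 1.0
    return r


def gcc_matrix(rel: pd.DataFrame, rho: float = DEFAULT_RHO) -> GreyMatrix:
    """Grey correlation matrix from a relative-expression table
    (genes x treatments)."""
    vals = gcc_matrix_values(rel.to_numpy(dtype=float), rho)
    r = pd.DataFrame(vals, index=rel.index, columns=rel.index)
    return GreyMatrix(r, rho, rel.shape[1])


@dataclass
class CoexpressionGraph:
    graph: nx.Graph
    tau: float
    directed_qualifying: int  # ordered pairs with r >= tau
    reciprocal_edges: int


def build_coexpression(
    grey: GreyMatrix, tau: float = DEFAULT_TAU
) -> tuple[CoexpressionGraph, dict]:
    """Threshold the grey matrix into an undirected weighted graph.

    Edge {i, j} exists iff ``r_ij >= tau`` OR ``r_ji >= tau``; its
    weight is ``max(r_ij, r_ji)`` and it is flagged reciprocal when both
    directions qualify.  All genes appear as nodes (isolates included).
    """
    if not (0 < tau):
        raise ValueError("tau must be positive")
    genes = list(grey.r.index)
    r = grey.r.to_numpy()
    g = nx.Graph()
    g.add_nodes_from(genes)
    directed_qualifying = 0
    reciprocal = 0
    m = len(genes)
    for i in range(m):
        for j in range(m):
            if i != j and r[i, j] >= tau:
                directed_qualifying += 1
    for i in range(m):
        for j in range(i + 1, m):
            fwd, rev = r[i, j], r[j, i]
            if fwd >= tau or rev >= tau:
                both = bool(fwd >= tau and rev >= tau)
                if both:
                    reciprocal += 1
                g.add_edge(
                    genes[i], genes[j],
                    weight=float(max(fwd, rev)), reciprocal=both,
                )
    comps = connected_components(g) if m else []
    metrics = {
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "directed_qualifying": directed_qualifying,
        "reciprocal_edges": reciprocal,
        "average_degree": average_degree(g) if m else 0.0,
        "n_components": len(comps),
        "largest_component_size": len(comps[0]) if comps else 0,
        "degree_sequence": sorted((d for _, d in g.degree()), reverse=True),
    }
    return CoexpressionGraph(g, tau, directed_qualifying, reciprocal), metrics


def family_density_ratio(
    graph: nx.Graph, families: Mapping[str, str]
) -> dict:
    """Within-family edge density divided by between-family density.

    Returns a dict with the two densities and their ratio; the ratio is
    ``inf`` when the between-density is zero but the within-density is
    not, and ``None`` (with a reason) when undefined.
    """
    nodes = list(graph.nodes)
    missing = [v for v in nodes if v not in families]
    if missing:
        raise KeyError(f"unlabeled nodes: {missing[:5]}")
    fams = {families[v] for v in nodes}
    if len(fams) < 2:
        raise ValueError("between-family density undefined with one family")
    sizes: dict[str, int] = {}
    for v in nodes:
        sizes[families[v]] = sizes.get(families[v], 0) + 1
    n = len(nodes)
    within_pairs = sum(s * (s - 1) // 2 for s in sizes.values())
    between_pairs = n * (n - 1) // 2 - within_pairs
    within_edges = sum(
        1 for u, v in graph.edges if families[u] == families[v]
    )
    between_edges = graph.number_of_edges() - within_edges
    result = {
        "within_edges": within_edges,
        "between_edges": between_edges,
        "within_pairs": within_pairs,
        "between_pairs": between_pairs,
    }
    if within_pairs == 0 or between_pairs == 0:
        result.update(ratio=None, reason="no within/between pairs")
        return result
    wd = within_edges / within_pairs
    bd = between_edges / between_pairs
    result.update(within_density=wd, between_density=bd)
    if bd == 0:
        result.update(
            ratio=float("inf") if wd > 0 else None,
            reason=None if wd > 0 else "both densities zero",
        )
    else:
        result.update(ratio=wd / bd, reason=None)
    return result


def degree_expression_correlation(
    graph: nx.Graph, rel: pd.DataFrame
) -> dict[str, float | None]:
    """Spearman rank correlation of node degree vs |log2FC| per treatment.

    Nodes must be a subset of the expression index.  A constant degree
    sequence makes the correlation undefined; ``None`` is reported.
    """
    nodes = sorted(graph.nodes, key=str)
    missing = [v for v in nodes if v not in rel.index]
    if missing:
        raise KeyError(f"nodes without expression: {missing[:5]}")
    degrees = np.array([graph.degree(v) for v in nodes], dtype=float)
    out: dict[str, float | None] = {}
    for t in rel.columns:
        if np.ptp(degrees) == 0:
            logger.warning("constant degree sequence: Spearman undefined")
            out[t] = None
            continue
        expr = np.abs(rel.loc[nodes, t].to_numpy(dtype=float))
        if np.ptp(expr) == 0:
            out[t] = None
            continue
        out[t] = float(spearmanr(degrees, expr).statistic)
    return out
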