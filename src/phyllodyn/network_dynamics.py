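"""Consecutive-month network comparison: inheritance and rewiring.

A node/edge of month *m+1* is *inherited* if it also exists in month *m*.
Per-node rewiring is quantified by a degree-corrected Dn score comparing a
node's weighted neighbourhood between the two network states: the two
neighbour-weight vectors (over the union of neighbours) are normalised to
unit length, and the raw score is the mean Euclidean distance of the two
vectors to their centroid — 0 for an unchanged neighbourhood, sqrt(2)/2
for completely disjoint neighbourhoods; the degree correction divides by
the number of distinct neighbours across both states.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network_inference import MonthNetwork, NetworkSeries

logger = logging.getLogger("phyllodyn")


@dataclass
class InheritanceResult:
    """Shared nodes/edges between one consecutive month pair."""

    month_from: str
    month_to: str
    shared_nodes: frozenset
    shared_edges: frozenset  # of frozenset pairs
    pct_nodes_inherited: float  # % of month_to nodes present in month_from
    pct_edges_inherited: float
    #: per inherited node: % of its month_to edges also present in month_from
    pct_edges_per_inherited_node: pd.Series


@dataclass
class RewiringResult:
    """Per-node Dn rewiring scores for one consecutive month pair."""

    month_from: str
    month_to: str
    scores: pd.Series  # Dn per node (union of both networks)
    raw_scores: pd.Series  # before degree correction
    weighting: str


def _pct(numer: int, denom: int) -> float:
    return 100.0 * numer / denom if denom else 0.0


def inherited(
    series: NetworkSeries, denominator: str = "later", require_sign_match: bool = False
) -> list[InheritanceResult]:
    """Inheritance between every consecutive month pair.

    ``denominator="later"`` expresses percentages relative to the later
    month (the fraction of its nodes/edges already present the month
    before); ``"earlier"`` uses the earlier month's counts.
    """
    if len(series) < 2:
        raise ValueError("need at least two networks")
    if denominator not in ("later", "earlier"):
        raise ValueError("denominator must be 'later' or 'earlier'")
    out = []
    for a, b in series.consecutive_pairs():
        nodes_shared = a.nodes & b.nodes

        def edge_set(net: MonthNetwork) -> set:
            if require_sign_match:
                return {(frozenset((u, v)), d["sign"])
                        for u, v, d in net.graph.edges(data=True)}
            return net.edges

        ea, eb = edge_set(a), edge_set(b)
        edges_shared = ea & eb
        ref = b if denominator == "later" else a
        ref_edges = eb if denominator == "later" else ea
        per_node = {}
        for node in sorted(nodes_shared):
            node_edges = {e for e in ref_edges
                          if node in (e if isinstance(e, frozenset) else e[0])}
            if node_edges:
                per_node[node] = _pct(len(node_edges & edges_shared), len(node_edges))
        out.append(InheritanceResult(
            month_from=a.month,
            month_to=b.month,
            shared_nodes=frozenset(nodes_shared),
            shared_edges=frozenset(
                e if isinstance(e, frozenset) else e[0] for e in edges_shared
            ),
            pct_nodes_inherited=_pct(len(nodes_shared), len(ref.nodes)),
            pct_edges_inherited=_pct(len(edges_shared), len(ref_edges)),
            pct_edges_per_inherited_node=pd.Series(per_node, dtype=float),
        ))
    return out


def node_degrees(net: MonthNetwork) -> pd.Series:
    """Number of incident edges per node (undirected, no self-loops)."""
    return pd.Series(dict(net.graph.degree()), dtype=int).sort_index()


def _neighbor_vector(net: MonthNetwork, node, universe: list, weighting: str):
    w = np.zeros(len(universe))
    if node in net.graph:
        adj = net.graph[node]
        for k, nb in enumerate(universe):
            if nb in adj:
                w[k] = 1.0 if weighting == "binary" else abs(adj[nb]["weight"])
    return w


def dn_score(
    net_a: MonthNetwork, net_b: MonthNetwork, weighting: str = "binary"
) -> RewiringResult:
    """Degree-corrected Dn rewiring score per node between two states.

    ``weighting="binary"`` uses edge presence only (the default, since
    edges are already significance-thresholded); ``"abs-correlation"``
    weights neighbours by |rho|.
    """
    if weighting not in ("binary", "abs-correlation"):
        raise ValueError("weighting must be 'binary' or 'abs-correlation'")
    raw, corrected = {}, {}
    for node in sorted(net_a.nodes | net_b.nodes):
        neighbors = set()
        for net in (net_a, net_b):
            if node in net.graph:
                neighbors |= set(net.graph[node])
        if not neighbors:  # present but isolated in both - cannot happen by
            continue  # construction (isolated nodes are excluded)
        universe = sorted(neighbors)
        va = _neighbor_vector(net_a, node, universe, weighting)
        vb = _neighbor_vector(net_b, node, universe, weighting)
        for v in (va, vb):
            norm = np.linalg.norm(v)
            if norm > 0:
                v /= norm
        centroid = (va + vb) / 2.0
        score = 0.5 * (np.linalg.norm(va - centroid) + np.linalg.norm(vb - centroid))
        raw[node] = float(score)
        corrected[node] = float(score / len(universe))
    return RewiringResult(
        month_from=net_a.month,
        month_to=net_b.month,
        scores=pd.Series(corrected, dtype=float),
        raw_scores=pd.Series(raw, dtype=float),
        weighting=weighting,
    )


def dynamics_summary(
    series: NetworkSeries, weighting: str = "binary"
) -> pd.DataFrame:
    """Tidy per-month-pair summary: node/edge counts, inheritance
    percentages and mean/median Dn scores."""
    if len(series) < 2:
        raise ValueError("need at least two networks")
    inh = inherited(series)
    rows = []
    for res, (a, b) in zip(inh, series.consecutive_pairs()):
        if a.n_edges == 0 and b.n_edges == 0:
            logger.warning("dynamics_summary: both %s and %s networks are empty",
                           a.month, b.month)
        rw = dn_score(a, b, weighting=weighting)
        rows.append(dict(
            month_from=res.month_from,
            month_to=res.month_to,
            nodes_from=a.n_nodes, edges_from=a.n_edges,
            nodes_to=b.n_nodes, edges_to=b.n_edges,
            n_shared_nodes=len(res.shared_nodes),
            n_shared_edges=len(res.shared_edges),
            pct_nodes_inherited=res.pct_nodes_inherited,
            pct_edges_inherited=res.pct_edges_inherited,
            mean_dn=float(rw.scores.mean()) if len(rw.scores) else 0.0,
            median_dn=float(rw.scores.median()) if len(rw.scores) else 0.0,
        ))
    return pd.DataFrame(rows)
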