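"""Evaluation metrics: tie strength, densities, CS-score and baselines.

Weak ties — edges with few shared neighbors relative to the endpoints'
degrees — are the signature of structural-hole spanners, so spanner sets
are judged by how *low* their mean average-connection-strength is, and the
CS-score combines that with the modularity of the accompanying partition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from . import cgm
from .shs import two_step_score

log = logging.getLogger(__name__)

__all__ = [
    "MethodScore",
    "EvaluationReport",
    "tie_strength",
    "avg_connection_strength",
    "cs_score",
    "subgraph_densities",
    "baseline_topk",
    "evaluate",
]

BASELINES = ("pagerank", "betweenness", "two_step")


def tie_strength(net: nx.Graph, i, j) -> float:
    """Tie strength of an edge: w_ij = c_ij / (k_i + k_j - 2 - c_ij),
    with c_ij the number of common neighbors.  Bridging (weak) ties score
    near 0; an edge inside a clique scores high.  The degenerate isolated
    dyad (denominator 0) is defined as 0."""
    if not net.has_edge(i, j):
        raise ValueError(f"({i!r}, {j!r}) is not an edge")
    cij = len(list(nx.common_neighbors(net, i, j)))
    denom = net.degree(i) + net.degree(j) - 2 - cij
    if denom <= 0:
        if cij == 0:
            log.warning("isolated dyad (%r, %r): tie strength defined as 0", i, j)
            return 0.0
        raise ValueError(f"inconsistent counts on edge ({i!r}, {j!r})")
    return cij / denom


def avg_connection_strength(net: nx.Graph, labels: Mapping, i) -> float:
    """Average connection strength w_i: the sum of tie strengths over i's
    incident edges divided by the number of *distinct communities* among
    i's neighbors (not the degree) — a node whose neighbors concentrate in
    one community can thus score above its largest single tie."""
    nbrs = list(net.neighbors(i))
    if not nbrs:
        raise ValueError(f"average connection strength undefined for isolated {i!r}")
    total = sum(tie_strength(net, i, j) for j in nbrs)
    n_comm = len({labels[j] for j in nbrs})
    return total / n_comm


def cs_score(Q: float, strengths: Sequence[float]) -> float:
    """CS-score: modularity divided by the mean of the top-k strengths.
    Higher is better (good communities + weak-tie spanners).  A zero mean
    strength yields the sentinel +inf (flagged in the log)."""
    if len(strengths) < 1:
        raise ValueError("need at least one strength")
    mean = float(np.mean(strengths))
    if mean == 0.0:
        log.warning("mean strength 0: CS-score reported as inf sentinel")
        return math.inf
    return Q / mean


def subgraph_densities(net: nx.Graph, nodeset) -> tuple[float, float]:
    """Intra and inter edge densities of a node subset g:

        rho_intra = |internal edges| / (Vg (Vg - 1) / 2)
        rho_inter = |boundary edges| / (Vg (V - Vg))
    """
    g = set(nodeset)
    V = net.number_of_nodes()
    Vg = len(g)
    if Vg <= 1 or Vg >= V:
        raise ValueError("need 1 < |nodeset| < V")
    internal = sum(1 for u, v in net.edges() if u in g and v in g)
    boundary = sum(1 for u, v in net.edges() if (u in g) != (v in g))
    return internal / (Vg * (Vg - 1) / 2.0), boundary / (Vg * (V - Vg))


def baseline_topk(net: nx.Graph, method: str, k: int) -> list:
    """Top-k nodes under a standard centrality baseline.

    Methods: 'pagerank' (damping 0.85), 'betweenness' (exact shortest-path
    betweenness), 'two_step' (global 2-step connectivity).  Ties broken by
    ascending label.
    """
    if method == "pagerank":
        scores = nx.pagerank(net, alpha=0.85)
    elif method == "betweenness":
        scores = nx.betweenness_centrality(net)
    elif method == "two_step":
        scores = {v: two_step_score(net, v) for v in net.nodes()}
    else:
        raise ValueError(f"unknown baseline {method!r}")
    ranked = sorted(scores.items(), key=lambda t: (-t[1], t[0]))
    return [v for v, _ in ranked[:k]]


@dataclass
class MethodScore:
    topk: list
    mean_strength: float
    cs: float


@dataclass
class EvaluationReport:
    Q: float
    k: int
    rows: dict  # method -> MethodScore


def evaluate(
    net: nx.Graph,
    labels: Mapping,
    methods: Sequence[str] = BASELINES,
    k: int = 10,
    rankings: Mapping[str, Sequence] | None = None,
    Q: float | None = None,
) -> EvaluationReport:
    """Score spanner-selection methods on one network + partition.

    For each method the top-k node set is either taken from ``rankings``
    (e.g. an SDHE result) or computed as a baseline; the report carries the
    mean average-connection-strength of the set (lower = better spanners)
    and the CS-score Q / mean-strength (higher = better joint detection).
    """
    if k < 1:
        raise ValueError("require k >= 1")
    if Q is None:
        Q = cgm.modularity(net, labels)
    rankings = rankings or {}
    rows = {}
    for method in methods:
        if method in rankings:
            topk = list(rankings[method])[:k]
        else:
            topk = baseline_topk(net, method, k)
        strengths = [avg_connection_strength(net, labels, v) for v in topk]
        mean = float(np.mean(strengths)) if strengths else 0.0
        cs = cs_score(Q, strengths) if strengths else math.nan
        rows[method] = MethodScore(topk=topk, mean_strength=mean, cs=cs)
    return EvaluationReport(Q=Q, k=k, rows=rows)
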