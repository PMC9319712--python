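"""Critical gap method (CGM): community detection on the embedded disk.

Embedded communities occupy contiguous angular sectors, so partitioning
reduces to cutting the circular node ordering at every consecutive angular
gap larger than a critical gap.  The sweep scores each candidate critical
gap by Newman modularity and keeps the argmax.  Closed-form critical gaps
are provided for two generative regimes: uniform angles (growing
preferential attachment) and Gaussian-mixture angles (nPSO).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
from scipy.integrate import quad
from scipy.stats import norm

from .npso import DiskCoordinates, TWO_PI

__all__ = [
    "CommunityAssignment",
    "modularity",
    "modularity_as_printed",
    "critical_gap_sweep",
    "critical_gap_gpa",
    "critical_gap_npso",
]


@dataclass
class CommunityAssignment:
    """A partition of the nodes into angular-arc communities."""

    label: Mapping[str, int]
    Q: float
    gap: float

    @property
    def n_communities(self) -> int:
        return len(set(self.label.values()))


def _community_sums(net: nx.Graph, labels: Mapping) -> tuple[dict, dict, int]:
    intra: dict = {}
    dsum: dict = {}
    for v in net.nodes():
        if v not in labels:
            raise ValueError(f"node {v!r} has no community label")
        dsum[labels[v]] = dsum.get(labels[v], 0) + net.degree(v)
    for u, v in net.edges():
        if labels[u] == labels[v]:
            intra[labels[u]] = intra.get(labels[u], 0) + 1
    return intra, dsum, net.number_of_edges()


def modularity(net: nx.Graph, labels: Mapping) -> float:
    """Newman modularity Q = (1/2E) sum_ij (A_ij - k_i k_j / 2E) delta(c_i, c_j).

    The trivial one-community partition scores 0; Q is bounded in [-1/2, 1).
    """
    intra, dsum, E = _community_sums(net, labels)
    if E == 0:
        raise ValueError("modularity undefined for an edgeless network")
    return sum(intra.get(c, 0) / E - (d / (2.0 * E)) ** 2 for c, d in dsum.items())


def modularity_as_printed(net: nx.Graph, labels: Mapping) -> float:
    """Modularity variant normalized by the node count V,

        Q = (1/4V) sum_ij (A_ij - k_i k_j / 2V)(s_i s_j + 1),

    where s_i s_j = 1 within a community and -1 across.  Exposed for audit
    only; the sweep optimizes the standard E-normalized form.
    """
    intra, dsum, E = _community_sums(net, labels)
    V = net.number_of_nodes()
    if V == 0:
        raise ValueError("empty network")
    return sum(
        intra.get(c, 0) / V - (d * d) / (4.0 * V * V) for c, d in dsum.items()
    )


def critical_gap_sweep(
    net: nx.Graph,
    coords: DiskCoordinates,
    monotone_stop: bool = False,
) -> CommunityAssignment:
    """Sweep the critical gap over all observed consecutive angular gaps.

    Nodes are sorted by angle; the candidate critical gaps are the distinct
    consecutive circular gaps.  For each candidate, the circle is cut at
    every gap exceeding it, giving a partition into contiguous arcs; the
    partition maximizing modularity wins, ties broken toward fewer
    communities (the larger candidate gap).  With ``monotone_stop`` the
    sweep instead stops at the first modularity decrease, mirroring the
    classical formulation; the result coincides whenever the modularity
    profile is unimodal in the gap.
    """
    nodes = [v for v in net.nodes()]
    missing = [v for v in nodes if v not in coords.theta]
    if missing:
        raise ValueError(f"{len(missing)} nodes lack coordinates, e.g. {missing[0]!r}")
    n = len(nodes)
    if n < 2:
        lab = {v: 1 for v in nodes}
        return CommunityAssignment(label=lab, Q=modularity(net, lab), gap=TWO_PI)

    order = sorted(nodes, key=lambda v: (coords.theta[v], v))
    th = np.array([coords.theta[v] for v in order])
    gaps = np.empty(n)
    gaps[:-1] = np.diff(th)
    gaps[-1] = th[0] + TWO_PI - th[-1]

    pos = {v: i for i, v in enumerate(order)}
    uv = np.array([[pos[u], pos[v]] for u, v in net.edges()], dtype=np.int64)
    deg = np.array([net.degree(v) for v in order], dtype=float)
    E = net.number_of_edges()
    if E == 0:
        raise ValueError("modularity undefined for an edgeless network")

    best_Q = -np.inf
    best_labels = None
    best_gap = None
    prev_Q = -np.inf
    for g in np.unique(gaps):
        cut = gaps > g
        labels = np.zeros(n, dtype=np.int64)
        labels[1:] = np.cumsum(cut[:-1])
        if not cut[-1] and labels[-1] != 0:
            labels[labels == labels[-1]] = 0  # wrap: last arc joins the first
        intra = int(np.count_nonzero(labels[uv[:, 0]] == labels[uv[:, 1]])) if len(uv) else 0
        dsum = np.bincount(labels, weights=deg)
        Q = intra / E - float(np.sum((dsum / (2.0 * E)) ** 2))
        if Q >= best_Q:
            best_Q, best_labels, best_gap = Q, labels, float(g)
        if monotone_stop and Q < prev_Q:
            break
        prev_Q = Q

    # relabel to 1..C in order of first appearance around the circle
    remap: dict = {}
    final = {}
    for i, v in enumerate(order):
        c = int(best_labels[i])
        if c not in remap:
            remap[c] = len(remap) + 1
        final[v] = remap[c]
    return CommunityAssignment(label=final, Q=float(best_Q), gap=best_gap)


def critical_gap_gpa(n: int, exact: bool = False) -> float:
    """Critical gap for uniformly scattered angles (GPA / plain PSO regime).

    The largest of the n consecutive gaps of n uniform angles behaves like
    the maximum of n exponentials of rate lambda = n/(2*pi); the closed-form
    approximation of its expectation is 2*pi*ln(n)/n.  With ``exact`` the
    expectation is computed by numerical quadrature of the max-gap density
        f(x) = (n^2 / 2 pi) e^{-n x / 2 pi} (1 - e^{-n x / 2 pi})^{n-1}.
    """
    if n < 2:
        raise ValueError("require n >= 2")
    if not exact:
        return TWO_PI * math.log(n) / n
    lam = n / TWO_PI
    # substitute u = lam * x: E = (1/lam) * int n u e^-u (1 - e^-u)^(n-1) du
    val, _ = quad(
        lambda u: n * u * math.exp(-u) * (1.0 - math.exp(-u)) ** (n - 1),
        0.0,
        math.log(n) + 50.0,
        limit=200,
    )
    return val / lam


def critical_gap_npso(n: int, mu: float, sigma: float) -> float:
    """Critical gap for Gaussian-mixture angles (nPSO regime).

    Angular gaps follow a folded normal |N(mu, sigma^2)|, approximated as
    exponential with mean
        1/lambda = sigma sqrt(2/pi) exp(-mu^2/2 sigma^2)
                   - mu [1 - 2 Phi(mu/sigma)],
    giving the critical gap ln(n)/lambda.
    """
    if sigma <= 0:
        raise ValueError(f"require sigma > 0, got {sigma}")
    inv_lambda = sigma * math.sqrt(2.0 / math.pi) * math.exp(
        -(mu * mu) / (2.0 * sigma * sigma)
    ) - mu * (1.0 - 2.0 * norm.cdf(mu / sigma))
    return math.log(n) * inv_lambda
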