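"""Structural-hole-spanner (SHS) detection in the embedded disk.

A spanner bridges two communities, so on the disk it lives near a
community boundary: inside the angular strip around a consecutive gap that
exceeds the critical gap, and outside the hub core (radius >= R0).  Within
that region candidates are ranked by 2-step connectivity, the number of
unlinked pairs among a node's neighbors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .cgm import CommunityAssignment
from .npso import DiskCoordinates, TWO_PI, angular_difference

log = logging.getLogger(__name__)

__all__ = [
    "RegionUndefinedError",
    "ShsRegionParams",
    "ShsResult",
    "two_step_score",
    "cross_boundary_probability",
    "shs_gap_infimum",
    "shs_gap_supremum",
    "radial_floor",
    "sdhe_detect",
]


class RegionUndefinedError(ValueError):
    """The closed-form angular region is undefined for these parameters."""


@dataclass
class ShsRegionParams:
    """Free parameters and derived bounds of the SHS angular region.

    ``a`` is the maximum tolerated cross-boundary connection probability
    (sets the region infimum); ``p`` the radial tail probability
    P(r > R0) (sets the hub-exclusion floor R0 as an empirical quantile).
    Derived fields are filled in by :func:`sdhe_detect`.
    """

    a: float = 0.5
    p: float = 0.9
    R0: float | None = None
    C: int | None = None
    sigma: float | None = None
    inf_gap: float | None = None
    sup_gap: float | None = None

    def __post_init__(self):
        if not 0.0 < self.a < 1.0:
            raise ValueError(f"require a in (0,1), got {self.a}")
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"require p in (0,1), got {self.p}")


@dataclass
class ShsResult:
    """Ranked spanner candidates plus the region bounds that produced them.

    ``ranking`` holds (node, two_step_score) pairs in detection order:
    ascending average connection strength (the weak-tie signature of a
    spanner), ties by ascending angular distance to the nearest community
    boundary, then label.  All 2-step scores are strictly positive.
    ``strength`` and ``boundary_distance`` map each ranked node to the
    quantities that ordered it.
    """

    ranking: list
    region: ShsRegionParams
    k: int
    boundary_distance: dict
    strength: dict

    @property
    def nodes(self) -> list:
        return [v for v, _ in self.ranking]


def two_step_score(net: nx.Graph, v) -> int:
    """Number of unlinked pairs among v's neighbors: C(k_v, 2) minus the
    edge count of the neighborhood subgraph.  High values flag local
    bridges whose neighborhoods would fall apart without them."""
    nbrs = list(net.neighbors(v))
    k = len(nbrs)
    nbr_set = set(nbrs)
    linked = sum(1 for u in nbrs for w in net.neighbors(u) if w in nbr_set) // 2
    return k * (k - 1) // 2 - linked


def cross_boundary_probability(
    dtheta: float, beta: float, zeta: float, R: float, R0: float
):
    """Fermi probability of a link across a community boundary of angular
    width ``dtheta`` between two nodes at the candidate radius R0,

        pAB = 1 / (1 + exp((beta zeta / 2)(2 R0 + 2 ln(dtheta/2) - R))).
    """
    x = (beta * zeta / 2.0) * (2.0 * R0 + 2.0 * np.log(np.asarray(dtheta) / 2.0) - R)
    return 1.0 / (1.0 + np.exp(x))


def shs_gap_infimum(a: float, beta: float, zeta: float, R: float, R0: float) -> float:
    """Smallest boundary gap keeping the cross-boundary connection
    probability at or below ``a``:

        inf = 2 ((1-a)/a)^(1/(beta zeta)) e^(R/2 - R0).

    Inverts :func:`cross_boundary_probability` exactly: plugging the result
    back yields pAB = a.
    """
    if not 0.0 < a < 1.0:
        raise ValueError(f"require a in (0,1), got {a}")
    return 2.0 * ((1.0 - a) / a) ** (1.0 / (beta * zeta)) * math.exp(R / 2.0 - R0)


def shs_gap_supremum(
    C: int,
    sigma: float,
    p: float | None = None,
    h: float | None = None,
    gamma: float | None = None,
    R0: float | None = None,
) -> float:
    """Largest boundary gap compatible with the planted mixture geometry:

        sup = 2 pi / C - 2 sigma sqrt(-2 ln(sqrt(2 pi) sigma p)).

    ``p`` may be given directly (the radial tail probability) or derived
    from the degree-tail coefficients as p = 1 - h e^((gamma-1) R0 / 2).
    Requires sqrt(2 pi) sigma p <= 1 and a positive result; otherwise the
    region is undefined and the caller falls back to the critical gap.
    """
    if sigma <= 0:
        raise ValueError(f"require sigma > 0, got {sigma}")
    if p is None:
        if h is None or gamma is None or R0 is None:
            raise ValueError("supply p directly or (h, gamma, R0)")
        p = 1.0 - h * math.exp((gamma - 1.0) * R0 / 2.0)
        if not 0.0 < p < 1.0:
            raise RegionUndefinedError(
                f"degree-tail chain gives p={p:.4g} outside (0,1)"
            )
    arg = math.sqrt(TWO_PI) * sigma * p
    if arg > 1.0:
        raise RegionUndefinedError(
            f"sqrt(2 pi) sigma p = {arg:.4g} > 1; root argument negative"
        )
    sup = TWO_PI / C - 2.0 * sigma * math.sqrt(-2.0 * math.log(arg))
    if sup <= 0:
        raise RegionUndefinedError(f"supremum {sup:.4g} <= 0")
    return sup


def radial_floor(coords: DiskCoordinates, p: float) -> float:
    """Hub-exclusion radius R0: the empirical (1-p) quantile of the
    embedded radii, so a fraction p of nodes lies at r > R0 and remains
    candidate material while the innermost hubs are excluded."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"require p in (0,1), got {p}")
    radii = np.array(sorted(coords.r.values()))
    return float(np.quantile(radii, 1.0 - p, method="lower"))


def _circular_std(angles: np.ndarray) -> float:
    z = np.exp(1j * angles)
    Rbar = np.abs(z.mean())
    Rbar = min(max(Rbar, 1e-12), 1.0 - 1e-12)
    return math.sqrt(-2.0 * math.log(Rbar))


def sdhe_detect(
    net: nx.Graph,
    coords: DiskCoordinates,
    assignment: CommunityAssignment,
    k: int,
    region: ShsRegionParams | None = None,
    beta: float = 10.0,
    zeta: float = 1.0,
) -> ShsResult:
    """Top-k structural-hole spanners from the embedded partition.

    Every consecutive angular gap exceeding the selected critical gap is a
    community boundary.  Candidates are the nodes within ``sup_gap`` of
    either boundary node's angle whose radius is at least R0 (hubs sit
    below the floor and are excluded) and whose 2-step connectivity is
    strictly positive (a node whose neighborhood is fully wired cannot
    span a hole).  Within the region, candidates are ranked by ascending
    average connection strength — a spanner is held to its communities by
    weak ties, so the weakest-tied candidates are the spanners — with
    angular proximity to the boundary breaking ties.  Fewer than k
    candidates may exist; a single-community partition has no boundary
    and yields an empty result.
    """
    if k < 1:
        raise ValueError("require k >= 1")
    region = region or ShsRegionParams()
    nodes = [v for v in net.nodes() if v in coords.theta]
    if len(nodes) != net.number_of_nodes():
        raise ValueError("coordinates do not cover the network")

    order = sorted(nodes, key=lambda v: (coords.theta[v], v))
    th = np.array([coords.theta[v] for v in order])
    n = len(order)
    gaps = np.empty(n)
    gaps[:-1] = np.diff(th)
    gaps[-1] = th[0] + TWO_PI - th[-1]

    region.C = assignment.n_communities
    if region.sigma is None:
        by_comm: dict = {}
        for v in nodes:
            by_comm.setdefault(assignment.label[v], []).append(coords.theta[v])
        stds = [_circular_std(np.array(a)) for a in by_comm.values() if len(a) > 1]
        region.sigma = float(np.mean(stds)) if stds else 0.1

    if region.R0 is None:
        region.R0 = radial_floor(coords, region.p)
    region.inf_gap = shs_gap_infimum(region.a, beta, zeta, coords.R, region.R0)
    if region.sup_gap is None:
        try:
            region.sup_gap = shs_gap_supremum(region.C, region.sigma, p=region.p)
        except RegionUndefinedError as err:
            log.warning(
                "supremum undefined (%s); falling back to the critical gap", err
            )
            region.sup_gap = assignment.gap

    boundary_idx = np.nonzero(gaps > assignment.gap)[0]
    dist: dict = {}
    for i in boundary_idx:
        j = (i + 1) % n
        for b in (i, j):
            d_all = angular_difference(th, th[b])
            for q in np.nonzero(d_all < region.sup_gap)[0]:
                v = order[q]
                if coords.r[v] >= region.R0:
                    d = float(d_all[q])
                    if v not in dist or d < dist[v]:
                        dist[v] = d

    from .metrics import avg_connection_strength  # deferred: metrics imports shs

    scored = [(v, two_step_score(net, v)) for v in sorted(dist)]
    scored = [(v, s) for v, s in scored if s > 0]
    w = {v: avg_connection_strength(net, assignment.label, v) for v, _ in scored}
    scored.sort(key=lambda t: (w[t[0]], dist[t[0]], t[0]))
    top = scored[:k]
    return ShsResult(
        ranking=top,
        region=region,
        k=k,
        boundary_distance={v: dist[v] for v, _ in top},
        strength={v: w[v] for v, _ in top},
    )
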