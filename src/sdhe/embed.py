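"""Efficient embedding (EE) of an observed network onto the Poincare disk.

Radial coordinates come from degrees (popular nodes sit near the centre).
Angular coordinates are found by a sequential likelihood placement driven
by common neighbors: pairs sharing many neighbors receive small expected
angular gaps, and each node is placed at the candidate angle maximizing
the Bernoulli log-likelihood of its observed (non-)adjacencies under the
Fermi connection rule.

The likelihood is evaluated in the *growth-replay* geometry: degree rank
stands in for arrival time, so a pair's connection odds are judged with
the radii and connection radius the popularity-similarity growth process
would have had when the younger endpoint arrived.  A static snapshot
geometry misjudges peripheral-peripheral edges (which formed early in
relative terms, at small radii) and fragments communities; the replay
geometry keeps the likelihood consistent with how scale-free links
actually form.

Placement is polished by coordinate-descent sweeps plus an arc-reordering
step: the circle is cut at the current community boundaries and the arcs
are re-laid in order of mutual edge affinity.  Single-angle moves cannot
merge a community that was split into interleaved arcs; moving whole arcs
can, and one or two such rounds suffice in practice.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .netcore import estimate_gamma, GammaEstimationError
from .npso import DiskCoordinates, TWO_PI, _attachment_radius

log = logging.getLogger(__name__)

__all__ = [
    "EmbeddingParams",
    "disk_radius",
    "radial_coordinate",
    "angular_gap_estimate",
    "embed",
]

F32 = np.float32


@dataclass(frozen=True)
class EmbeddingParams:
    """Parameters of the EE embedding.

    gamma is the degree exponent (> 2: the radial formulas carry a
    (gamma - 2) factor), T the Fermi temperature (default 0.1, hence
    beta = 1/T = 10), zeta the curvature constant, and K the scale
    constant of the angular-gap estimate (calibrated per network when
    None: the pair with the globally largest common-neighbor count is
    assigned one resolvable angular slot, 2*pi/V).
    """

    gamma: float
    T: float = 0.1
    zeta: float = 1.0
    K: float | None = None

    def __post_init__(self):
        if not self.gamma > 2.0:
            raise ValueError(f"require gamma > 2, got {self.gamma}")
        if not 0.0 < self.T < 1.0:
            raise ValueError(f"require T in (0,1), got {self.T}")

    @property
    def beta(self) -> float:
        return 1.0 / self.T


def disk_radius(V: int, E: int, gamma: float, T: float = 0.1) -> float:
    """Radius of the embedding disk,

        R = 2 ln[ V^2 (gamma-1)^2 T / (E sin(pi T) (gamma-2)^2) ].
    """
    if V < 2 or E < 1:
        raise ValueError("require V >= 2 and E >= 1")
    if gamma <= 2.0:
        raise ValueError(f"disk radius undefined for gamma <= 2, got {gamma}")
    num = V * V * (gamma - 1.0) ** 2 * T
    den = E * math.sin(math.pi * T) * (gamma - 2.0) ** 2
    return 2.0 * math.log(num / den)


def radial_coordinate(ki: int, V: int, gamma: float, T: float, R: float) -> float:
    """Degree-determined radius, capped at the disk rim:

        r_i = min{ R, 2 ln[ 2 V (gamma-1) T / (k_i sin(pi T) (gamma-2)) ] }.

    Non-increasing in the degree k_i; the maximum-degree node sits closest
    to the centre.  Isolated nodes (k = 0) are rejected: they carry no
    degree information and are pruned before embedding.
    """
    if ki < 1:
        raise ValueError("radial coordinate undefined for isolated nodes (k=0)")
    term = 2.0 * math.log(
        2.0 * V * (gamma - 1.0) * T / (ki * math.sin(math.pi * T) * (gamma - 2.0))
    )
    return min(R, term)


def angular_gap_estimate(
    cij: float, ri: float, rj: float, gamma: float, R: float, K: float = 1.0
) -> float:
    """Expected |angular gap| of a node pair from its common-neighbor count:

        phi = K * cij**(1/(2-gamma)) * exp(-(1/2)(ri + rj - R)/(2 - 4 gamma)).

    Strictly decreasing in cij for gamma > 2 (more shared neighbors means
    a smaller gap); increasing in ri + rj (peripheral pairs need larger
    gaps to carry the same evidence).  K fixes the overall angular scale.
    """
    if cij < 1:
        raise ValueError("gap estimate requires at least one common neighbor")
    return K * cij ** (1.0 / (2.0 - gamma)) * math.exp(
        -0.5 * (ri + rj - R) / (2.0 - 4.0 * gamma)
    )


def _resolve_gamma(degrees, gamma):
    if gamma != "auto":
        return float(gamma)
    positive = [d for d in degrees if d > 0]
    # modal degree marks the onset of the power-law bulk (the attachment
    # parameter m in grown networks); the minimum is fragile to a handful
    # of pendant nodes
    counts: dict = {}
    for d in positive:
        counts[d] = counts.get(d, 0) + 1
    mode = min(sorted(counts, key=lambda d: (-counts[d], d))[:1] or [2])
    kmin = max(2, mode)
    try:
        fit = estimate_gamma(degrees, kmin=kmin)
        g = fit.gamma
    except GammaEstimationError:
        log.warning("gamma estimation failed; falling back to gamma=2.5")
        return 2.5
    if g <= 2.05:
        log.warning("estimated gamma %.3f <= 2.05; clamping to 2.1", g)
        return 2.1
    return g


class _Embedder:
    """Mutable state of one embedding run (indices, radii, angles)."""

    def __init__(self, net, gamma, T, zeta, seed, max_anchors, nonedge_cap,
                 n_coarse=128, n_fine=25, n_keep=3):
        nodes = sorted(net.nodes())
        V = len(nodes)
        E = net.number_of_edges()
        A = nx.to_numpy_array(net, nodelist=nodes, dtype=np.float32)
        Cmat = A @ A
        np.fill_diagonal(Cmat, 0.0)
        degs = A.sum(axis=1).astype(int)

        g = _resolve_gamma(degs.tolist(), gamma)
        self.nodes, self.V, self.E = nodes, V, E
        self.adj = A.astype(bool)
        self.Cmat = Cmat
        self.gamma, self.T, self.zeta = g, T, zeta
        self.beta = 1.0 / T
        self.beta_f = 1.0 / (g - 1.0)
        self.R = disk_radius(V, E, g, T)
        self.r_out = np.array(
            [radial_coordinate(int(k), V, g, T, self.R) for k in degs]
        )
        # growth replay: degree rank = arrival time
        self.order = sorted(range(V), key=lambda i: (-degs[i], nodes[i]))
        rank = np.empty(V, dtype=np.int64)
        for s, v in enumerate(self.order, start=1):
            rank[v] = s
        self.rank = rank
        self.r_birth = 2.0 * np.log(rank)
        m_eff = max(1, round(E / V))
        self.Rt = np.array(
            [
                _attachment_radius(2.0 * math.log(t), m_eff, T, self.beta_f)
                if t > 1
                else 0.0
                for t in range(1, V + 1)
            ]
        )
        # angular-gap scale: max-c pair gets one resolvable slot 2*pi/V
        flat = int(np.argmax(Cmat))
        i_star, j_star = divmod(flat, V)
        cmax = Cmat[i_star, j_star]
        if cmax >= 1:
            phi0 = angular_gap_estimate(
                cmax, self.r_out[i_star], self.r_out[j_star], g, self.R, K=1.0
            )
            self.K = (TWO_PI / V) / phi0
        else:
            self.K = 1.0
        self.exp_coef = -0.5 / (2.0 - 4.0 * g)
        self.c_exp = 1.0 / (2.0 - g)
        self.max_anchors = max_anchors
        self.cap = nonedge_cap
        self.rng = np.random.default_rng(seed)
        self.theta = np.full(V, np.nan, dtype=F32)
        self.coarse = np.linspace(0.0, TWO_PI, n_coarse, endpoint=False, dtype=F32)
        self.fine = np.linspace(-TWO_PI / n_coarse, TWO_PI / n_coarse, n_fine, dtype=F32)
        self.n_keep = n_keep
        self.placed: list[int] = []

    # ---------------------------------------------------------- likelihood

    def _loglik(self, cand, others, chd, shp, Rthr, adjrow, w, beta):
        dth = np.abs(cand[:, None] - self.theta[others][None, :])
        dth = np.where(dth > math.pi, TWO_PI - dth, dth)
        arg = chd + shp * (np.float32(1.0) - np.cos(dth))
        d = np.arccosh(np.maximum(arg, np.float32(1.0))) / np.float32(self.zeta)
        x = np.float32(beta * self.zeta / 2.0) * (d - Rthr)
        lse = np.logaddexp(np.float32(0.0), x)
        ll = np.where(adjrow[None, :], -lse, x - lse)
        return (ll * w[None, :]).sum(axis=1)

    def place(self, v: int, exclude_self: bool = False, beta=None) -> float:
        """Best angle for node v given the current placements."""
        beta = self.beta if beta is None else beta
        others = np.array([u for u in self.placed if not (exclude_self and u == v)])
        if others.size == 0:
            return 0.0
        adjrow = self.adj[v, others]
        # the repulsion term is a smooth field: a capped subsample of
        # non-neighbors, reweighted, approximates it at O(cap) cost
        non = np.nonzero(~adjrow)[0]
        if non.size > self.cap:
            keep = self.rng.choice(non, self.cap, replace=False)
            nbr = np.nonzero(adjrow)[0]
            sel = np.concatenate([nbr, keep])
            w = np.ones(sel.size, dtype=F32)
            w[nbr.size:] = non.size / self.cap
            others, adjrow = others[sel], adjrow[sel]
        else:
            w = np.ones(others.size, dtype=F32)
        # pairwise geometry at link-formation time t = max(rank)
        t = np.maximum(self.rank[others], self.rank[v]).astype(float)
        rt = 2.0 * np.log(t)
        r_elder = np.where(
            self.rank[others] < self.rank[v], self.r_birth[others], self.r_birth[v]
        )
        r1 = self.beta_f * r_elder + (1.0 - self.beta_f) * rt
        Rthr = self.Rt[t.astype(np.int64) - 1].astype(F32)
        chd = np.cosh(self.zeta * (r1 - rt)).astype(F32)
        shp = (np.sinh(self.zeta * r1) * np.sinh(self.zeta * rt)).astype(F32)

        cand = [self.coarse]
        cv = self.Cmat[v, others]
        anchors = np.nonzero(cv >= 1)[0]
        if anchors.size:
            top = anchors[np.argsort(-cv[anchors], kind="stable")[: self.max_anchors]]
            ref = others[top]
            gaps = (
                self.K
                * cv[top] ** self.c_exp
                * np.exp(self.exp_coef * (self.r_out[v] + self.r_out[ref] - self.R))
            )
            cand.append(((self.theta[ref] + gaps) % TWO_PI).astype(F32))
            cand.append(((self.theta[ref] - gaps) % TWO_PI).astype(F32))
        cand = np.concatenate(cand)
        ll = self._loglik(cand, others, chd, shp, Rthr, adjrow, w, beta)
        best = cand[np.argsort(-ll)[: self.n_keep]]
        cand2 = ((best[:, None] + self.fine[None, :]).ravel() % TWO_PI).astype(F32)
        ll2 = self._loglik(cand2, others, chd, shp, Rthr, adjrow, w, beta)
        return float(cand2[int(np.argmax(ll2))])

    # ---------------------------------------------------------- passes

    def sequential_pass(self) -> None:
        for step, v in enumerate(self.order):
            self.theta[v] = 0.0 if step == 0 else self.place(v)
            self.placed.append(v)

    def sweep(self, beta=None) -> None:
        for v in self.order:
            self.theta[v] = self.place(v, exclude_self=True, beta=beta)

    def reorder_arcs(self, net) -> None:
        """Cut the circle at the current community boundaries and re-lay
        the arcs in a chain ordered by mutual edge affinity, preserving
        each arc's internal layout.  Merges interleaved splinters that
        single-node moves cannot."""
        from .cgm import critical_gap_sweep  # deferred: cgm imports npso only

        assignment = critical_gap_sweep(net, self.coordinates())
        lab = np.array([assignment.label[self.nodes[i]] for i in range(self.V)])
        arcs = sorted(set(lab.tolist()))
        if len(arcs) < 3:
            return
        members = {c: np.nonzero(lab == c)[0] for c in arcs}
        aff: dict = {}
        for ci, c in enumerate(arcs):
            for d in arcs[ci + 1 :]:
                e = self.adj[np.ix_(members[c], members[d])].sum()
                aff[(c, d)] = aff[(d, c)] = e / math.sqrt(
                    len(members[c]) * len(members[d])
                )
        chain = [max(arcs, key=lambda c: len(members[c]))]
        rest = set(arcs) - set(chain)
        while rest:
            head = max(rest, key=lambda c: (aff[(chain[0], c)], -c))
            tail = max(rest, key=lambda c: (aff[(chain[-1], c)], -c))
            if aff[(chain[0], head)] >= aff[(chain[-1], tail)]:
                chain.insert(0, head)
                rest.discard(head)
            else:
                chain.append(tail)
                rest.discard(tail)
        spans, starts = {}, {}
        for c in arcs:
            th = np.sort(self.theta[members[c]])
            if len(th) == 1:
                spans[c], starts[c] = 0.0, float(th[0])
                continue
            gaps = np.diff(np.concatenate([th, [th[0] + TWO_PI]]))
            widest = int(np.argmax(gaps))
            starts[c] = float(th[(widest + 1) % len(th)])
            spans[c] = float(TWO_PI - gaps[widest])
        total = sum(spans.values())
        gap = (TWO_PI - total) / len(arcs) if total < TWO_PI else 0.0
        scale = 1.0 if total < TWO_PI else (0.9 * TWO_PI) / total
        cursor = 0.0
        for c in chain:
            mem = members[c]
            rel = (self.theta[mem] - starts[c]) % TWO_PI
            self.theta[mem] = ((cursor + rel * scale) % TWO_PI).astype(F32)
            cursor += spans[c] * scale + gap

    def coordinates(self) -> DiskCoordinates:
        return DiskCoordinates(
            r={self.nodes[i]: float(self.r_out[i]) for i in range(self.V)},
            theta={self.nodes[i]: float(self.theta[i]) for i in range(self.V)},
            R=float(self.R),
        )


def embed(
    net: nx.Graph,
    gamma="auto",
    T: float = 0.1,
    zeta: float = 1.0,
    seed: int = 0,
    max_anchors: int = 20,
    nonedge_cap: int = 600,
    anneal_beta: float = 2.0,
    n_reorders: int = 2,
) -> DiskCoordinates:
    """Embed a network onto the Poincare disk.

    Nodes are placed sequentially in descending degree order (ties by
    label): the first at theta = 0, each later node at the angle
    maximizing the Bernoulli log-likelihood of its adjacencies among a
    candidate set combining a coarse angular grid, the +-gap placements
    around the ``max_anchors`` strongest common-neighbor anchors, and a
    fine local grid around the leading candidates.  The placement is then
    polished: one softened sweep at ``anneal_beta`` (escapes the sharp
    likelihood's local optima), and ``n_reorders`` rounds of arc
    reordering each followed by a full-sharpness sweep.

    ``gamma="auto"`` estimates the exponent from the degree tail.
    Disconnected inputs are reduced to the largest connected component
    (with a warning); V < 3 is an error.  Output is deterministic for a
    fixed input, seed and parameter set.
    """
    if net.number_of_nodes() < 3:
        raise ValueError("embedding requires at least 3 nodes")
    if not nx.is_connected(net):
        comp = max(nx.connected_components(net), key=lambda c: (len(c), sorted(c)[0]))
        log.warning(
            "input disconnected: embedding largest component (%d of %d nodes)",
            len(comp),
            net.number_of_nodes(),
        )
        net = net.subgraph(comp)

    st = _Embedder(net, gamma, T, zeta, seed, max_anchors, nonedge_cap)
    st.sequential_pass()
    st.sweep(beta=anneal_beta)
    for _ in range(n_reorders):
        st.reorder_arcs(net)
        st.sweep()
    return st.coordinates()
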