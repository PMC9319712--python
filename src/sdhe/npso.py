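"""nPSO generator: scale-free networks with planted angular communities.

The nonuniform popularity-similarity-optimization (nPSO) model grows a
network on the hyperbolic disk.  Node t arrives at radius 2 ln t with an
angular coordinate drawn from a Gaussian mixture on the circle (the planted
communities); earlier nodes drift outward ("popularity fading"), and each
arrival connects to min(m, t-1) existing nodes sampled by the Fermi
connection probability.  The generator returns both the network and the
ground truth (coordinates + community labels) needed by benchmarks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
from scipy.special import expit

__all__ = [
    "NpsoParams",
    "DiskCoordinates",
    "GroundTruth",
    "sample_angles",
    "angular_difference",
    "hyperbolic_distance",
    "connection_probability",
    "generate",
    "plant_bridges",
]

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class NpsoParams:
    """Parameters of the nPSO growth process.

    Attributes
    ----------
    n : int
        Final node count.
    m : int
        Links added per arriving node (1 <= m < n).
    gamma : float
        Target degree exponent, > 2.  Controls popularity fading through
        beta_fading = 1 / (gamma - 1).
    T : float
        Temperature of the Fermi connection rule, in (0, 1).
    zeta : float
        Curvature constant of the hyperbolic plane (default 1).
    C : int
        Number of Gaussian mixture components (planted communities); the
        component means are the C equally spaced angles 2*pi*t/C.
    sigma : float
        Angular standard deviation of each component, radians.  Defaults to
        (2*pi/C)/6 so adjacent components sit ~6 sigma apart and communities
        stay isolated.
    seed : int
        Seed of the single generator driving component choice, angular
        noise and attachment sampling, in that order.
    """

    n: int
    m: int
    gamma: float = 2.5
    T: float = 0.1
    zeta: float = 1.0
    C: int = 1
    sigma: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n < 2 or self.m < 1:
            raise ValueError(f"require n >= 2 and m >= 1, got n={self.n}, m={self.m}")
        if not self.gamma > 2.0:
            raise ValueError(f"require gamma > 2, got {self.gamma}")
        if not 0.0 < self.T < 1.0:
            raise ValueError(f"require T in (0,1), got {self.T}")
        if self.zeta <= 0:
            raise ValueError(f"require zeta > 0, got {self.zeta}")
        if self.C < 1:
            raise ValueError(f"require C >= 1, got {self.C}")
        if self.sigma is None:
            object.__setattr__(self, "sigma", (TWO_PI / self.C) / 6.0)
        if self.sigma <= 0:
            raise ValueError(f"require sigma > 0, got {self.sigma}")

    @property
    def beta_fading(self) -> float:
        """Popularity-fading exponent 1/(gamma-1); distinct from beta = 1/T."""
        return 1.0 / (self.gamma - 1.0)

    @property
    def component_means(self) -> np.ndarray:
        """Angular means of the C components: 2*pi*t/C for t = 1..C (mod 2*pi)."""
        return (TWO_PI * np.arange(1, self.C + 1) / self.C) % TWO_PI


@dataclass
class DiskCoordinates:
    """Per-node polar coordinates on the extended Poincare disk."""

    r: Mapping[str, float]
    theta: Mapping[str, float]
    R: float

    def nodes(self):
        return self.r.keys()


@dataclass
class GroundTruth:
    """Planted structure returned by the generator."""

    community: Mapping[str, int]
    coordinates: DiskCoordinates


def _node_label(t: int) -> str:
    return str(t)


def sample_angles(params: NpsoParams, rng: np.random.Generator | None = None):
    """Draw the planted angular coordinates.

    Each node's component is uniform over the C components (equal mixture
    proportions); its angle is the component mean plus N(0, sigma^2) noise,
    wrapped mod 2*pi.  Returns (theta, component) as dense arrays indexed by
    arrival order 0..n-1; component ids are 1..C.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    comp = rng.integers(1, params.C + 1, size=params.n)
    means = params.component_means
    theta = (means[comp - 1] + rng.normal(0.0, params.sigma, size=params.n)) % TWO_PI
    return theta, comp


def angular_difference(theta_i, theta_j):
    """Circle distance min(|ti - tj|, 2*pi - |ti - tj|), vectorized."""
    d = np.abs(np.asarray(theta_i, dtype=float) - np.asarray(theta_j, dtype=float)) % TWO_PI
    return np.where(d > math.pi, TWO_PI - d, d)


def hyperbolic_distance(ri, theta_i, rj, theta_j, zeta: float = 1.0):
    """Hyperbolic distance on the disk via the hyperbolic law of cosines,

        cosh(zeta*d) = cosh(zeta*ri)cosh(zeta*rj)
                       - sinh(zeta*ri)sinh(zeta*rj)cos(dtheta).

    Evaluated in the numerically stable form
    cosh(zeta*(ri-rj)) + sinh(zeta*ri)sinh(zeta*rj)(1 - cos(dtheta)) with
    the acosh argument clamped to >= 1, so d(ri, ri) is exactly 0 and
    dtheta = 0 returns |ri - rj|.
    """
    ri = np.asarray(ri, dtype=float)
    rj = np.asarray(rj, dtype=float)
    if zeta <= 0:
        raise ValueError(f"require zeta > 0, got {zeta}")
    if np.any(ri < 0) or np.any(rj < 0):
        raise ValueError("radial coordinates must be nonnegative")
    dtheta = angular_difference(theta_i, theta_j)
    arg = np.cosh(zeta * (ri - rj)) + np.sinh(zeta * ri) * np.sinh(zeta * rj) * (
        1.0 - np.cos(dtheta)
    )
    return np.arccosh(np.maximum(arg, 1.0)) / zeta


def connection_probability(d, R: float, beta: float, zeta: float = 1.0):
    """Fermi connection probability p = 1 / (1 + exp((beta*zeta/2)(d - R))).

    Overflow-safe for any |d - R|; equals 1/2 at d = R and is strictly
    decreasing in d.
    """
    if beta <= 0 or zeta <= 0:
        raise ValueError("require beta > 0 and zeta > 0")
    return expit(-(beta * zeta / 2.0) * (np.asarray(d, dtype=float) - R))


def _attachment_radius(rt: float, m: int, T: float, beta_f: float) -> float:
    """Connection cutoff R_t keeping the expected number of links ~ m.

    Standard popularity-similarity-optimization closed form for fading
    exponent beta_f < 1 and temperature T in (0, 1).
    """
    num = 2.0 * T * (1.0 - math.exp(-(1.0 - beta_f) * rt / 2.0))
    den = math.sin(math.pi * T) * m * (1.0 - beta_f)
    if num <= 0:
        return rt
    return rt - 2.0 * math.log(num / den)


def generate(params: NpsoParams):
    """Grow an nPSO network; returns (Network, GroundTruth).

    Node t = 1..n receives radius 2 ln t (zeta = 1 scale) and its
    pre-sampled mixture angle; every earlier node s fades to
    r_s(t) = beta_f * r_s + (1 - beta_f) * r_t with beta_f = 1/(gamma-1).
    Node t connects to exactly min(m, t-1) distinct existing nodes, sampled
    without replacement with weights given by the Fermi probability at the
    current radii.  The edge count is therefore the deterministic identity
    E = m*n - m(m+1)/2 for every seed.
    """
    n, m = params.n, params.m
    rng = np.random.default_rng(params.seed)
    theta, comp = sample_angles(params, rng)

    beta_f = params.beta_fading
    beta_fermi = 1.0 / params.T
    r_init = 2.0 * np.log(np.arange(1, n + 1, dtype=float))  # radius at arrival
    r_cur = np.zeros(n)

    edges_u = []
    edges_v = []
    for t in range(2, n + 1):
        i = t - 1  # 0-based index of the arriving node
        rt = r_init[i]
        # popularity fading of all earlier nodes to the current time
        r_cur[:i] = beta_f * r_init[:i] + (1.0 - beta_f) * rt
        r_cur[i] = rt
        mm = min(m, i)
        if mm == i:
            targets = np.arange(i)
        else:
            d = hyperbolic_distance(
                rt, theta[i], r_cur[:i], theta[:i], zeta=params.zeta
            )
            Rt = _attachment_radius(rt, m, params.T, beta_f)
            w = connection_probability(d, Rt, beta_fermi, params.zeta)
            w = np.clip(w, 1e-300, None)
            # Efraimidis-Spirakis weighted sampling without replacement
            keys = np.log(rng.random(i)) / w
            targets = np.sort(np.argpartition(keys, -mm)[-mm:])
        edges_u.extend([i] * len(targets))
        edges_v.extend(targets.tolist())

    labels = [_node_label(t) for t in range(1, n + 1)]
    net = nx.Graph()
    net.add_nodes_from(labels)
    net.add_edges_from((labels[u], labels[v]) for u, v in zip(edges_u, edges_v))

    R_final = _attachment_radius(r_init[-1], m, params.T, beta_f)
    coords = DiskCoordinates(
        r={labels[i]: float(r_cur[i]) for i in range(n)},
        theta={labels[i]: float(theta[i]) for i in range(n)},
        R=float(R_final),
    )
    truth = GroundTruth(
        community={labels[i]: int(comp[i]) for i in range(n)},
        coordinates=coords,
    )
    return net, truth


def plant_bridges(
    net: nx.Graph,
    truth: GroundTruth,
    n_bridges: int = 4,
    seed: int = 0,
    degree_cap: int | None = None,
):
    """Augment a generated network with known structural-hole spanners.

    Adds ``n_bridges`` new nodes; bridge i is wired to one node in each of
    two angularly adjacent planted communities (components i and i+1 mod C),
    so each bridge spans exactly one community boundary.  Anchor nodes are
    drawn uniformly from the community members (optionally capped in degree
    so anchors are not hubs).  Returns the list of bridge labels; ``net``
    and ``truth.community`` are modified in place (bridges get label 0).
    """
    comm = dict(truth.community)
    C = max(comm.values())
    if C < 2:
        raise ValueError("need at least 2 planted communities to plant bridges")
    rng = np.random.default_rng(seed)
    members = {c: sorted(v for v, cc in comm.items() if cc == c) for c in range(1, C + 1)}
    if degree_cap is not None:
        for c in members:
            capped = [v for v in members[c] if net.degree(v) <= degree_cap]
            if capped:
                members[c] = capped
    bridges = []
    for i in range(n_bridges):
        c1 = (i % C) + 1
        c2 = (c1 % C) + 1
        a = members[c1][rng.integers(len(members[c1]))]
        b = members[c2][rng.integers(len(members[c2]))]
        label = f"bridge{i + 1}"
        net.add_edge(label, a)
        net.add_edge(label, b)
        truth.community[label] = 0
        bridges.append(label)
    return bridges
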