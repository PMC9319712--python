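"""Graph data model, edge-list I/O and scale-free degree statistics.

Networks are simple undirected :class:`networkx.Graph` objects whose nodes
are opaque string labels.  All file I/O goes through plain whitespace
delimited edge lists, the lingua franca of network repositories.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "EdgeListParseError",
    "GammaEstimationError",
    "PowerLawFit",
    "DegreeStats",
    "read_edge_list",
    "write_edge_list",
    "degree_sequence",
    "degree_stats",
    "estimate_gamma",
]

class EdgeListParseError(ValueError):
    """A line of an edge-list file could not be parsed."""

class GammaEstimationError(ValueError):
    """The degree sample does not support a power-law exponent estimate."""

def read_edge_list(path) -> nx.Graph:
    """Read a simple undirected network from a whitespace-delimited edge list.

    One edge per line, two node labels separated by whitespace; text after
    ``#`` is a comment.  Duplicate lines and reversed duplicates collapse to
    a single edge; self-loop lines are dropped (the endpoint is kept as an
    isolated node if it appears nowhere else).

    Raises
    ------
    EdgeListParseError
        If a non-comment line has fewer than two tokens; the message names
        the offending line number.
    """
    g = nx.Graph()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise EdgeListParseError(
                    f"{path}: line {lineno}: expected two node labels, got {line!r}"
                )
            u, v = tokens[0], tokens[1]
            if u == v:
                log.warning("%s: line %d: dropping self-loop on %r", path, lineno, u)
                g.add_node(u)
                continue
            g.add_edge(u, v)
    return g

def write_edge_list(net: nx.Graph, path) -> None:
    """Write a network as a whitespace-delimited edge list (sorted, stable)."""
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.edges()):
            fh.write(f"{u} {v}\n")
        for v in sorted(n for n in net.nodes() if net.degree(n) == 0):
            # isolated nodes are preserved as a degenerate one-token comment-free
            # convention is not standard; record them as a comment for humans
            fh.write(f"# isolated {v}\n")

def degree_sequence(net: nx.Graph) -> dict:
    """Map every node to its degree (isolated nodes map to 0)."""
    return {v: d for v, d in net.degree()}

@dataclass(frozen=True)
class PowerLawFit:
    """Continuous maximum-likelihood power-law fit of a degree tail.

    Attributes
    ----------
    gamma : float
        Exponent estimate of P(k) ~ k^-gamma over the tail k >= kmin.
    b : float
        Density normalization coefficient (gamma - 1) * kmin**(gamma - 1),
        used by the structural-hole region bounds.
    kmin : int
        Lower cutoff of the fitted tail.
    n_tail : int
        Number of degrees >= kmin that entered the fit.
    """

    gamma: float
    b: float
    kmin: int
    n_tail: int

@dataclass(frozen=True)
class DegreeStats:
    degrees: Mapping[str, int]
    kmin: int
    fit: PowerLawFit | None

def estimate_gamma(degrees: Iterable[int], kmin: int = 2) -> PowerLawFit:
    """Estimate the power-law exponent of a degree sample.

    Uses the continuous MLE with the -1/2 discreteness correction,

        gamma_hat = 1 + n / sum_i ln(k_i / (kmin - 1/2)),

    over the degrees k_i >= kmin.  Requires at least 10 usable degrees that
    are not all equal.
    """
    tail = np.asarray([k for k in degrees if k >= kmin], dtype=float)
    if tail.size < 10:
        raise GammaEstimationError(
            f"need >= 10 degrees >= kmin={kmin}, got {tail.size}"
        )
    if np.all(tail == tail[0]):
        raise GammaEstimationError("all tail degrees equal; exponent undefined")
    denom = float(np.sum(np.log(tail / (kmin - 0.5))))
    gamma = 1.0 + tail.size / denom
    b = (gamma - 1.0) * kmin ** (gamma - 1.0)
    return PowerLawFit(gamma=gamma, b=b, kmin=int(kmin), n_tail=int(tail.size))

def degree_stats(net: nx.Graph, kmin: int | None = None) -> DegreeStats:
    """Degree map plus, when possible, a power-law tail fit.

    ``kmin`` defaults to the modal positive degree (for generated
    scale-free networks this equals the attachment parameter m, where the
    power-law bulk begins), floored at 2; the minimum degree is fragile
    to a handful of pendant nodes.
    """
    degs = degree_sequence(net)
    positive = [d for d in degs.values() if d > 0]
    if kmin is None:
        if positive:
            counts: dict = {}
            for d in positive:
                counts[d] = counts.get(d, 0) + 1
            kmin = max(2, min(sorted(counts, key=lambda d: (-counts[d], d))[:1]))
        else:
            kmin = 2
    try:
        fit = estimate_gamma(degs.values(), kmin=kmin)
    except GammaEstimationError:
        fit = None
    return DegreeStats(degrees=degs, kmin=kmin, fit=fit)
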