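import math

import networkx as nx
import numpy as np
import pytest

from sdhe import cgm, npso
from tests.conftest import random_graph, two_triangles_bridge

TWO_PI = 2 * math.pi


def brute_force_modularity(net, labels):
    """O(V^2) pairwise double sum, (1/2E) sum_ij (A_ij - k_i k_j/2E) delta."""
    nodes = list(net.nodes())
    E = net.number_of_edges()
    deg = dict(net.degree())
    total = 0.0
    for u in nodes:
        for v in nodes:
            if labels[u] != labels[v]:
                continue
            a = 1.0 if net.has_edge(u, v) else 0.0
            total += a - deg[u] * deg[v] / (2.0 * E)
    return total / (2.0 * E)


# ------------------------------------------------------------- modularity

def test_trivial_partition_scores_zero():
    g = two_triangles_bridge()
    assert cgm.modularity(g, {v: 1 for v in g}) == pytest.approx(0.0, abs=1e-15)


def test_two_triangles_partition_is_5_14():
    g = two_triangles_bridge()
    labels = {v: (1 if v in "abc" else 2) for v in g}
    assert cgm.modularity(g, labels) == pytest.approx(5 / 14)
    assert brute_force_modularity(g, labels) == pytest.approx(5 / 14)


def test_disjoint_dyads_split_is_half():
    g = nx.Graph([("a", "b"), ("c", "d")])
    labels = {"a": 1, "b": 1, "c": 2, "d": 2}
    assert cgm.modularity(g, labels) == pytest.approx(0.5)


def test_modularity_matches_bruteforce_on_random_graphs():
    rng = np.random.default_rng(123)
    for _ in range(50):
        g = random_graph(rng)
        if g.number_of_edges() == 0:
            continue
        labels = {v: int(rng.integers(1, 5)) for v in g}
        assert cgm.modularity(g, labels) == pytest.approx(
            brute_force_modularity(g, labels), abs=1e-12
        )


def test_modularity_requires_edges_and_full_cover():
    g = nx.Graph()
    g.add_nodes_from("ab")
    with pytest.raises(ValueError):
        cgm.modularity(g, {"a": 1, "b": 1})
    g.add_edge("a", "b")
    with pytest.raises(ValueError):
        cgm.modularity(g, {"a": 1})


def test_printed_variant_matches_its_own_pairwise_sum():
    g = two_triangles_bridge()
    labels = {v: (1 if v in "abc" else 2) for v in g}
    V = g.number_of_nodes()
    deg = dict(g.degree())
    total = 0.0
    for u in g:
        for v in g:
            s = 1.0 if labels[u] == labels[v] else -1.0
            a = 1.0 if g.has_edge(u, v) else 0.0
            total += (a - deg[u] * deg[v] / (2.0 * V)) * (s + 1.0)
    assert cgm.modularity_as_printed(g, labels) == pytest.approx(
        total / (4.0 * V), abs=1e-12
    )


# ------------------------------------------------------------- the sweep

def _coords(theta_map, R=10.0):
    return npso.DiskCoordinates(
        r={v: 5.0 for v in theta_map}, theta=dict(theta_map), R=R
    )


def test_sweep_separates_two_angular_pairs():
    g = nx.Graph([("a", "b"), ("c", "d")])
    coords = _coords({"a": 0.0, "b": 0.1, "c": math.pi, "d": math.pi + 0.1})
    res = cgm.critical_gap_sweep(g, coords)
    assert res.n_communities == 2
    assert res.label["a"] == res.label["b"] != res.label["c"] == res.label["d"]
    assert res.Q == pytest.approx(0.5)


def test_sweep_keeps_complete_graph_whole():
    g = nx.complete_graph(6)
    g = nx.relabel_nodes(g, str)
    coords = _coords({str(i): i * TWO_PI / 6 for i in range(6)})
    res = cgm.critical_gap_sweep(g, coords)
    assert res.n_communities == 1
    assert res.Q == pytest.approx(0.0, abs=1e-15)
    # enumeration oracle: every contiguous bipartition scores < 0
    for start in range(6):
        for length in range(1, 6):
            labels = {str(i): 1 for i in range(6)}
            for off in range(length):
                labels[str((start + off) % 6)] = 2
            assert cgm.modularity(g, labels) < 0


def test_sweep_is_rotation_invariant(small_embedded):
    net, _, coords, baseline = small_embedded
    shift = 1.2345
    rotated = npso.DiskCoordinates(
        r=dict(coords.r),
        theta={v: (t + shift) % TWO_PI for v, t in coords.theta.items()},
        R=coords.R,
    )
    res = cgm.critical_gap_sweep(net, rotated)
    # identical partition up to community relabeling
    mapping = {}
    for v in net.nodes():
        mapping.setdefault(baseline.label[v], res.label[v])
        assert mapping[baseline.label[v]] == res.label[v]
    assert res.Q == pytest.approx(baseline.Q, abs=1e-9)


def test_sweep_communities_are_contiguous_arcs(small_embedded):
    net, _, coords, res = small_embedded
    order = sorted(net.nodes(), key=lambda v: (coords.theta[v], v))
    labels = [res.label[v] for v in order]
    # circular contiguity: each label occupies one run once the circle is
    # cut at any boundary between two different labels
    n = len(labels)
    start = next((i for i in range(n) if labels[i] != labels[(i - 1) % n]), 0)
    rotated = [labels[(start + i) % n] for i in range(n)]
    seen, prev = set(), None
    for lab in rotated:
        if lab != prev:
            assert lab not in seen
            seen.add(lab)
            prev = lab


def test_monotone_stop_matches_argmax_on_unimodal_profile():
    g = nx.Graph([("a", "b"), ("c", "d")])
    coords = _coords({"a": 0.0, "b": 0.1, "c": math.pi, "d": math.pi + 0.1})
    full = cgm.critical_gap_sweep(g, coords)
    stop = cgm.critical_gap_sweep(g, coords, monotone_stop=True)
    assert stop.Q == pytest.approx(full.Q)


def test_single_node_gets_single_community():
    g = nx.Graph()
    g.add_node("a")
    with pytest.raises(ValueError):
        # modularity (and hence the sweep result) undefined without edges
        cgm.critical_gap_sweep(g, _coords({"a": 0.0}))


# ------------------------------------------------------------- closed forms

def test_gpa_gap_approximation_value_and_identity():
    assert cgm.critical_gap_gpa(2000) == pytest.approx(
        TWO_PI * math.log(2000) / 2000
    )
    assert cgm.critical_gap_gpa(2000) == pytest.approx(0.0238789, abs=1e-6)
    for n in (10, 100, 5000):
        assert n * cgm.critical_gap_gpa(n) / (TWO_PI * math.log(n)) == pytest.approx(1.0)


def test_gpa_gap_quadrature_equals_expected_maximum_of_spacings():
    """The exact integral is (2 pi / n) H_n, the mean maximum of n
    exponential spacings; Monte-Carlo confirms within 2 SE."""
    for n in (100, 1000):
        H = sum(1.0 / i for i in range(1, n + 1))
        assert cgm.critical_gap_gpa(n, exact=True) == pytest.approx(
            TWO_PI * H / n, rel=1e-9
        )
    rng = np.random.default_rng(0)
    reps = 2000
    n = 1000
    maxima = np.empty(reps)
    for k in range(reps):
        th = np.sort(rng.uniform(0.0, TWO_PI, n))
        gaps = np.diff(th, append=th[0] + TWO_PI)
        maxima[k] = gaps.max()
    se = maxima.std(ddof=1) / math.sqrt(reps)
    assert abs(maxima.mean() - cgm.critical_gap_gpa(n, exact=True)) < 2 * se


def test_npso_gap_half_normal_case():
    # mu = 0: 1/lambda is the half-normal mean sigma sqrt(2/pi)
    val = cgm.critical_gap_npso(1000, 0.0, 0.1)
    assert val == pytest.approx(math.log(1000) * 0.1 * math.sqrt(2 / math.pi))
    assert val == pytest.approx(0.5512, abs=1e-4)
    with pytest.raises(ValueError):
        cgm.critical_gap_npso(1000, 0.0, 0.0)


def test_npso_gap_rate_matches_folded_normal_mc():
    rng = np.random.default_rng(1)
    for mu, sigma in ((0.0, 0.1), (0.05, 0.2)):
        sample = np.abs(rng.normal(mu, sigma, 200000))
        inv_lambda = cgm.critical_gap_npso(math.e, mu, sigma)  # ln(e) = 1
        se = sample.std(ddof=1) / math.sqrt(sample.size)
        assert abs(sample.mean() - inv_lambda) < 2 * se
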