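# Methods

## Model

The package treats a scale-free network as a sample from a latent
hyperbolic geometry.  Every node has polar coordinates `(r, θ)` on the
extended Poincaré disk; distances follow the hyperbolic law of cosines

    cosh(ζ d_ij) = cosh(ζ r_i) cosh(ζ r_j) − sinh(ζ r_i) sinh(ζ r_j) cos Δθ_ij,

evaluated in the numerically stable form
`cosh(ζ(r_i−r_j)) + sinh(ζ r_i) sinh(ζ r_j)(1 − cos Δθ)` with the
`acosh` argument clamped at 1, so coincident points give exactly 0 and
`Δθ = 0` gives exactly `|r_i − r_j|`.  Links arise with the Fermi
probability `p(d) = 1/(1 + e^{(βζ/2)(d−R)})`, `β = 1/T`.  Throughout,
`ζ = 1` and `T = 0.1` (so `β = 10`) unless overridden.

Radius encodes popularity: high-degree nodes sit near the centre.  Angle
encodes similarity: communities are angular sectors.  Everything the
package does — generation, embedding, community detection, spanner
detection — is a manipulation of this picture.

## nPSO generator

`npso.generate` grows a network of `n` nodes.  Node `t` arrives at radius
`2 ln t` with an angle drawn from an equal-proportion Gaussian mixture
with `C` components at means `2πt/C` and common standard deviation `σ`
(default `(2π/C)/6`, putting adjacent components ~6σ apart — well
separated but not degenerate).  All earlier nodes fade outward,
`r_s(t) = β_f r_s + (1−β_f) 2 ln t` with `β_f = 1/(γ−1)`, which is what
produces the power-law degree distribution with exponent `γ`.  Node `t`
connects to exactly `min(m, t−1)` distinct existing nodes, sampled
without replacement (Efraimidis–Spirakis keys) with weights given by the
Fermi probability at the current radii and the standard
popularity-similarity connection radius

    R_t = r_t − 2 ln[ 2T(1 − e^{−(1−β_f) r_t / 2}) / (sin(πT) m (1−β_f)) ].

Connecting to *exactly* `min(m, t−1)` targets makes the edge count the
deterministic identity `E = mn − m(m+1)/2` (or `C(n,2)` when
`m ≥ n−1`), for every seed — the benchmark tables' edge counts are exact
invariants, not averages.  A single seeded generator drives component
choice, angular noise and attachment, in that order, so equal seeds give
bit-identical networks.

`npso.plant_bridges` augments a generated network with known spanners
for benchmarking: each bridge is a new degree-2 node wired to one
uniformly chosen member of each of two angularly adjacent communities.

## Embedding

Radial coordinates come from degrees (`r_i` as in the README formula,
capped at the disk radius `R = 2 ln[V²(γ−1)²T/(E sin(πT)(γ−2)²)]`).  The
exponent γ is estimated from the degree tail by the continuous MLE with
the −1/2 discreteness correction, `γ̂ = 1 + n/Σ ln(k_i/(k_min−½))`, with
`k_min` the modal positive degree (on grown networks this equals the
attachment parameter `m`; the minimum degree is fragile to a handful of
pendant nodes, and `k_min = 2` badly underestimates γ on graphs whose
power-law bulk starts at `m > 2`).

Angles are found by sequential maximum-likelihood placement.  Nodes are
visited in descending degree order (ties by label); each node is placed
at the candidate angle maximizing the Bernoulli log-likelihood
`Σ_j [A_ij ln p_ij + (1−A_ij) ln(1−p_ij)]` over the already-placed
nodes.  Three design choices matter:

* **Growth-replay likelihood.**  The likelihood is *not* evaluated in
  the static snapshot geometry.  In a grown network, an edge between two
  peripheral nodes formed when both were young and central; judged at
  their final radii such an edge is essentially impossible (`d ≫ R`),
  and a likelihood built on the static geometry tears communities into
  micro-clusters (measured: coordinate descent started *from the planted
  coordinates* degrades NMI 0.99 → 0.55).  Instead, degree rank stands
  in for arrival time, and each pair is judged with the radii and
  connection radius `R_t` the growth process had when the younger
  endpoint arrived.  Under this replay likelihood the planted
  configuration is a fixed point of refinement (NMI 0.992).
* **Candidate set.**  Candidates per node are (i) a coarse 128-point
  angular grid, (ii) `±φ` placements around the 20 strongest
  common-neighbor anchors, where `φ(c_ij) = K c_ij^{1/(2−γ)}
  e^{−(r_i+r_j−R)/(2(2−4γ))}` is the common-neighbor gap estimate with
  `K` calibrated so the globally best-connected pair maps to one
  resolvable slot `2π/V`, and (iii) a fine local grid around the three
  best candidates.  The repulsion term of the likelihood (non-edges) is
  approximated by a reweighted random subsample of 600 non-neighbors —
  the repulsion field is smooth, and this keeps the per-node cost flat.
* **Polish: soft sweep + arc reordering.**  After the sequential pass,
  one full coordinate-descent sweep runs at a softened `β = 2` (the
  sharp `β = 10` landscape traps single-node moves), then two rounds of
  *arc reordering*: the circle is cut at the current community
  boundaries and the arcs re-laid in a chain ordered by mutual edge
  affinity (`edges / sqrt(n_p n_q)`), preserving each arc's internal
  layout, each round followed by a full-sharpness sweep.  Single-angle
  moves cannot merge a community split into interleaved arcs; moving
  whole arcs can.

The output is deterministic given the input graph, seed and parameters.
Disconnected inputs reduce to the largest component with a warning;
isolated nodes carry no degree information and are never embedded.

## Community detection (critical gap method)

Embedded communities are contiguous angular arcs, so detection reduces
to a one-dimensional sweep: sort nodes by angle, take the distinct
consecutive circular gaps as candidate critical gaps, cut the circle at
every gap exceeding the candidate, and score the resulting arc partition
by Newman modularity `Q = (1/2E) Σ_ij (A_ij − k_i k_j/2E) δ(c_i, c_j)`.
The arg-max over candidates is returned, ties resolved toward fewer
communities; a `monotone_stop` flag reproduces the classical
stop-at-first-decrease rule, which coincides whenever the Q-profile is
unimodal.  A variant of modularity normalized by `V` instead of `E` is
exposed as `modularity_as_printed` for auditability; the sweep always
optimizes the standard form, whose values are comparable across networks
and match the published magnitudes.

Closed-form critical gaps: for uniform angles the expected largest of
the `n` circular spacings, `Δθc ≈ 2π ln n / n`; `critical_gap_gpa(n,
exact=True)` computes the exact expectation by quadrature, which equals
`(2π/n) H_n`.  The log-approximation therefore under-shoots by the
Euler–Mascheroni constant — a relative 11% at n=100 shrinking to 6% at
n=10⁴ — so the approximation should be treated as an order-of-magnitude
guide, not a 2%-accurate value.  For Gaussian-mixture angles the gap
distribution is folded-normal, approximated as exponential with mean
`1/λ = σ√(2/π) e^{−μ²/2σ²} − μ[1 − 2Φ(μ/σ)]`, giving `Δθc ≈ ln(n)/λ`.

## Spanner detection

A structural-hole spanner bridges two communities, so on the disk it
lives near a community boundary and outside the hub core.  For every
consecutive angular gap exceeding the selected Δθc:

* the **angular window** is `sup ΔθS = 2π/C − 2σ√(−2 ln(√(2π) σ p))`
  around either boundary node's angle (σ estimated as the mean circular
  standard deviation of the detected communities; if the root argument
  is invalid or the width nonpositive, the window falls back to Δθc, the
  only remaining angular scale).  The matching lower bound
  `inf ΔθS = 2((1−a)/a)^{1/βζ} e^{R/2−R0}` — the gap width at which the
  cross-boundary Fermi probability reaches `a` (default 0.5) — is
  computed and reported;
* the **radial floor** `R0` is the empirical `(1−p)` quantile of the
  embedded radii (default `p = 0.9`: the innermost tenth — the hubs —
  are excluded as candidates);
* candidates must have **positive 2-step connectivity** (some pair of
  their neighbors not directly linked; a node with a fully wired
  neighborhood cannot span a hole);
* candidates are **ranked by ascending average connection strength**
  `w_i = Σ_j w_ij / Cnb(i)` with `w_ij = c_ij/(k_i+k_j−2−c_ij)` and
  `Cnb(i)` the number of distinct communities among i's neighbors — the
  weak-tie signature is the defining property of a spanner.  Boundary
  proximity breaks ties, then labels.  Raw 2-step is reported per node.

Ranking *by* the raw 2-step count instead was evaluated and rejected: it
selects whichever candidate has the largest open neighborhood, i.e. the
highest-degree node that survives the radial floor, whose ties are
*strong*; on planted benchmarks that inverts the expected ordering
against hub baselines and can never rank a degree-2 bridge (2-step
exactly 1) above ordinary community members.  The strength ranking
recovers planted bridges and produces spanner sets with the weak ties
the theory predicts.

## Evaluation

`metrics.evaluate` scores any ranked node set: its mean average
connection strength (lower = weaker ties = better spanners) and the
CS-score `Q / mean strength` (higher = better joint detection; a
zero-strength set reports an `inf` sentinel).  Baselines: PageRank
(damping 0.85), exact shortest-path betweenness, and global 2-step
ranking — all through networkx, ties by label.  One convention worth
flagging: the average connection strength divides by the
*neighbor-community count*, not the degree, so a node whose neighbors
concentrate in one community can score above its largest single tie; the
cross-method comparisons depend on this definition and it is kept
deliberately.

## Problem sizes and numerical choices

The shipped benchmarks use n=2000 (dense m=50/γ=2.9/C=15 and sparse
m=4/γ=3.4/C=20 rows, five seeds each), n=1000/m=8/C=8 for the
strength comparison, and n=500/m=6/C=4 (σ = (2π/4)/8) with four planted
bridges for recovery — sizes at which a full five-seed pipeline runs in
minutes on one core.  Per-network embedding cost is dominated by the
candidate-likelihood evaluations, ~30–60 s at n=2000.  Likelihood
probabilities are clamped away from 0/1 via `log1p`-safe forms; float32
is used inside the embedding inner loop (the angular argmax is far
coarser than float32 resolution).  All stochastic steps flow from
per-stage seeds derived by stable hashing from a single top-level seed.

## What the synthetic benchmarks do and do not show

The nPSO benchmarks have equal-size, equally spaced, equal-σ planted
communities and exact power-law growth.  Real networks have unequal
communities, degree-correlations, and noisy boundaries; passing the
planted benchmarks shows the pipeline recovers angular community
structure and weak-tie spanners under the model's own assumptions, not
that it does so on arbitrary real data.  The optional real-network path
(`netcore.read_edge_list`) feeds the identical pipeline.

## Known limitations

* The embedding recovers community *membership* (planted-community NMI
  0.78–0.99 across the benchmarks) but neither the fine intra-community
  angular order (~0.64 pairwise concordance; at m=6 a tight community
  simply carries little intra-order signal) nor the planted circular
  order of the communities themselves (arc reordering is driven by
  noisy inter-community edge counts).  Quantities that depend only on
  the partition — modularity, NMI, spanner regions — are unaffected.
* Degree-2 planted bridges are bistable under the sharp likelihood: the
  optimum is to sit on one of the two anchor communities rather than in
  the gap, so bridge recovery rests on the strength ranking, not on the
  bridges' embedded positions.
* The `2π ln n / n` critical-gap approximation is biased low by
  `γ_E ≈ 0.577` inside the logarithmised mean (see above); use
  `exact=True` where accuracy matters.
* `estimate_gamma` assumes a clean power-law tail above `k_min`; on
  degree distributions with a hard lower cutoff plus contamination below
  it, choose `k_min` explicitly.
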