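# Methods

## The pseudocell automaton

The simulator is a stochastic cellular automaton on a cubic lattice of
`L³` sites with at most one protein instance per site.  An input
interaction network — an undirected, unweighted simple graph over protein
species — is the rule set: two instances may bond only if their species are
adjacent in the graph.  All species are present at the same concentration
(copy numbers as equal as possible, remainder spread over uniformly chosen
species) and all pairs share the same kinetic probabilities: the model
isolates the effect of network *topology* from concentration and affinity
heterogeneity, which it deliberately does not represent.

Each step applies two phases.

**Interaction phase.**  Sites are visited in a fixed raster order (a
randomized order is available via `visit_order="random"`).  The resident
instance first breaks each of its bonds independently with probability
`p_off`, then attempts to form a bond with probability `p_on` on each free
face whose neighboring site holds an instance of an interacting species.
Formation is vetoed when either face is already bonded, when the pair is
already bonded, or when the merged complex would contain two copies of any
species — the species-uniqueness rule that caps complex growth.  Breaking
precedes formation within a visit, so a freshly broken bond can re-form in
the same visit but a freshly formed bond cannot break.  Complexes — the
connected components of the bond graph — are maintained incrementally:
bond creation unions two components (re-anchoring unwrapped coordinates so
the bonded pair is geometrically adjacent), bond deletion triggers a
connectivity recheck restricted to the affected component.

**Diffusion phase.**  Sites are visited in the same order; the first
encountered member of each complex triggers at most one move per phase.
With probability `1/diameter` (diameter = maximal Chebyshev extent + 1, so
monomers always qualify) the complex rigidly rotates 90° about one of the
six axis-senses, pivoting on the member nearest its center of mass (ties
break to the lowest instance id so trajectories are reproducible).  A
rotation is rejected wholesale if any target site is held by a non-member;
we do not push blockers out of a rotation's way because a 90° sweep assigns
no well-defined push direction to a displaced occupant — translational
pushes cover the crowding physics, and the choice is conservative (dense
regions rotate less).  The complex then translates one site in a uniform
random direction with probability `1/mass` (`move_law="diameter"` switches
the slowdown law to `1/diameter`).  A blocked translation recursively
pushes the obstructing complexes in the same direction, each push accepted
with probability `min(1, m_mover/m_blocked)` where the mover is the
immediate pusher; any failed push rejects the entire move, and all accepted
movers translate simultaneously (so chains that wrap around the periodic
boundary shift as a ring).  Pushed complexes are not charged their own
move.

**Boundaries and geometry.**  Periodic boundaries are the default — the
model is a bulk-cytoplasm idealization and walls would add artifacts; a
`closed` mode is provided for comparison.  Positions are stored unwrapped
(the grid index is the coordinate mod `L`), which keeps rigid-body motion
and Chebyshev diameters exact across the wrap; a bond between members of
the same complex that are adjacent only through the wrap is refused, since
it would tie the complex to the torus topology.  Orientations (the 24
proper cube rotations) are tracked and composed under rotations, but since
the six binding sites are the six faces with no per-face chemistry, they
are bookkeeping only.

**Parameters.**  Reference settings: `L=50` (125 000 sites), occupancy
0.20 of sites filled, `p_on=0.7`, `p_off=0.002` per visit, 150 000 steps.
The occupancy emulates cytoplasmic crowding; `p_on ≫ p_off` puts the
system deep in the association-dominated regime where complexes anneal
toward compositions the network favors.  The desk-scale profile used
throughout the test suite (`L=12`, 24–30 species, 20 000 steps) keeps every
mechanism — crowding, pushing, species saturation — active at roughly the
same occupancy and steps-per-instance while fitting in seconds to minutes
of CPU; the quantitative SSI level depends on lattice and network size, so
desk-scale results support orderings and trends, not the absolute values
of full-scale runs.

## Organization metrics

A complex composition is the set of distinct species in one complex (by
species uniqueness, its size equals the complex mass).  The Similarity
Index `S.I.(C1,C2) = |C1∩C2|²/(|C1ΔC2|+1)` scores shared cores
quadratically and penalizes unshared material.  The Self-Similarity Index
sums, over the canonically ordered complex list, each complex's best match
among its successors, divided by `n`.  The upper-triangular form is
order-dependent, so the list is first sorted by descending size and then
lexicographically; an order-free variant (each complex matched against all
others) is available via `symmetric=True` and never falls below the
literal form.  Monomers are excluded from the complex list by default — a
complex is at least two proteins, and counting the initially monomeric
cell as perfectly self-similar would be misleading; `include_monomers=True`
switches this.  Duplicate compositions are retained: identical complexes
are precisely what organization produces.  The ICSI greedily pairs the two
cells' complexes best-first on the rectangular S.I. matrix (ties to the
lowest row, column indices), averaging `min(n,m)` matched scores.  Greedy
matching is the metric's definition; the optimal-assignment value is
computed in the test suite only as an upper-bound oracle.

Note that neither index is monotone under complex replacement or
duplication in general — appending a duplicate of a small complex to a
cell dominated by large recurring complexes lowers the mean — so tests
assert exact worked values, closed forms and true bounds (literal ≤
symmetric ≤ max |C|²) rather than a monotonicity that does not hold.

## Network generators

`erdos_renyi(N, m, seed)` draws G(N, p) with `p = m/(N(N−1)/2)`: the
expected edge count matches the natural network, the realized count varies
by seed, and downstream analyses always use realized metrics.

`volz_network(degrees, t, seed)` grows a graph with a prescribed degree
sequence and tunable transitivity: nodes carry stub budgets; from a random
start, a node with free stubs is repeatedly offered every distance-2 node
with free stubs, closing each triad with probability `t`; when no triad
closes, a random unattached node is connected instead, until every
positive-degree node has a neighbor.  The closure probability is the
target value itself — the simplest monotone choice; the mapping from
target to realized transitivity is calibrated empirically, never assumed
(realized values are what enter the regression).  Leftover stubs are
resolved by uniform stub matching that skips self-loops and duplicates;
unmatchable stubs are dropped with a logged count, so the realized degree
sequence approximates the prescribed one (exact realization is not
guaranteed by the growth rule).  Realized transitivity rises monotonically
in the target (rank correlation > 0.98 on Poisson degree sequences at
N = 250–300).

## Topology metrics

Transitivity, the Watts–Strogatz average clustering coefficient (nodes of
degree < 2 contribute 0), and greedy-agglomerative Newman modularity are
computed with networkx; average path length and diameter use BFS over the
largest connected component via scipy's sparse graph machinery — sparse
random graphs at mean degree ~5 contain isolated nodes, and restricting to
the largest component is the convention the reference values follow.  The
scale-free fitting index is the R² of the OLS line through
`(log10 k, log10 P(k))` over degrees with nonzero frequency, unbinned; it
is undefined (reported as `None`) below three distinct degrees.

## Regression

Equilibrium SSI is modeled as an OLS linear function of SFFI, APL,
diameter, ACC, transitivity and modularity, one observation per simulated
network, using each network's realized metrics.  Aliased or constant
columns are dropped before fitting.  Redundant terms are removed by
backward elimination: per pass, the single term with the largest partial-F
p-value above `alpha` (default 0.05) is dropped and the model refit, until
all retained terms are significant.  For one coefficient the partial F is
the squared t statistic.  Because elimination keeps the *most* significant
of several terms, the null probability that nothing survives is roughly
`(1−alpha)^6 ≈ 0.74`, not `1−alpha` — the Monte-Carlo type-I test asserts
that regime.  "Equilibrium SSI" is operationalized as the mean over the
final 10 % of recorded snapshots; runs are long enough that the
complex-size spectrum is stationary over that window.

## Validation against an exact chain

The strongest simulator check uses the 2×2×2 lattice with one instance
each of two interacting species: all 80 configurations (ordered positions
plus bond flag) are enumerated by an independent reference module that
rebuilds the one-step transition law from the rules alone — including the
2-lattice quirks (both senses of an axis reach the same neighbor, so a
formation visit succeeds with probability `1−(1−p_on)²`; equal-mass pushes
swap the two monomers; the diffusion parity makes Hamming-distance-2
configurations transient).  Long simulator runs are compared to the exact
stationary distribution by χ² over configuration classes, after a 1000-step
burn-in (the uniform initial placement is not stationary) and with
small-expectation classes pooled, at both a well-mixed regime
(`p_on=0.5, p_off=0.3`) and the reference regime (`p_on=0.7,
p_off=0.002`).

## What the synthetic networks do and do not emulate

The fixture interactomes (rings/chains of cliques, stars, paths, a
two-clique toy) reproduce the one topological feature under study — high
transitivity with modular clique structure versus the uniform sparsity of
ER controls — at sizes where complexes can still saturate a whole clique.
They do not reproduce the heavy-tailed degree distributions, the size
(1890 species), or the weight structure of curated interactomes; tests
passing on them demonstrate the mechanism (clustering → recurring complex
types → high SSI/ICSI), not quantitative agreement with any real
interactome, which requires supplying the curated edge lists under
`data/`.

## Numerical and degenerate-input choices

Transitivity of a triple-free graph is 0 with a warning; SSI of a cell
with fewer than two complexes is 0 with a warning; path metrics on an
edgeless network and S.I. of an empty composition raise.  All randomness
flows from a single `random.Random(seed)` per simulation and per
generator, with fixed iteration orders throughout, so a (network, config,
seed) triple determines the trajectory bit-exactly.  Replicate seeds in
the study drivers derive deterministically from one master seed.

## Known limitations

On-lattice geometry quantizes rotation and diffusion; complexes cannot
deform (no torsion); kinetic heterogeneity (per-pair `p_on`/`p_off`) is
accepted in the configuration but defaults to the uniform values; the
absolute SSI scale depends on unstated discretization conventions (visit
order, move laws, rotation handling), so cross-implementation comparisons
should rely on orderings and trends; and the full-scale profile is
computationally expensive in pure Python (~hours per 150 000-step
replicate), which is why the shipped studies default to desk scale.
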