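# protnet

A pseudocell simulator: a 3-D lattice cellular automaton in which protein
instances diffuse, rotate, bind and dissociate under the rules of a
protein-interaction network, together with metrics that quantify how
*organized* the resulting ensemble of protein complexes is.

## The scientific problem

Interactomes of distantly related organisms share almost no specific edges,
yet they share global topological signatures — high clustering and
non-random degree distributions.  Are those signatures functionally
relevant?  One way to ask the question dynamically: fill a virtual cell
with protein monomers at equal concentrations, let them bind only along the
edges of a given interaction network, and measure whether the cell
converges on a small repertoire of recurring complexes (an *organized*
cell) or on an ever-changing zoo of compositions.  Clique-rich, natural
interactomes should — and in these simulations do — yield far more
organized pseudocells than degree-matched random graphs, and the effect is
driven by network transitivity rather than by the degree distribution.

## Model and metrics

**Automaton.**  An `L × L × L` cubic lattice (default 50, i.e. 125 000
sites) holds at most one protein instance per site, at 20 % occupancy.
Each step has two phases.  In the *interaction phase* the grid is visited
site by site: the resident protein breaks each existing bond with
probability `p_off` (default 0.002) and forms a bond with probability
`p_on` (default 0.7) to each face-adjacent protein whose species interacts
with its own — subject to six binding sites per protein (the cube faces)
and to the rule that a species may appear only once per complex.  In the
*diffusion phase* each complex (connected component of the bond graph) may
rigidly rotate by 90° with probability `1/diameter` and translate one site
with probability `1/mass`, recursively pushing lighter obstacles with
probability `min(1, m_mover/m_blocked)`.

**Similarity Index.**  For two complex compositions (sets of distinct
species) `C1`, `C2`:

    S.I.(C1, C2) = |C1 ∩ C2|² / (|C1 Δ C2| + 1)

**Self-Similarity Index (SSI)** of a cell with complex list `C1 … Cn`
(canonically ordered):

    SSI = (1/n) Σ_{i=1}^{n-1} max_{j>i} S.I.(Ci, Cj)

A cell of `n` identical complexes of size `k` scores `k²(n−1)/n`; a cell of
pairwise-disjoint complexes scores 0.

**Inter-Cells Similarity Index (ICSI)** compares two cells by greedily
matching their complexes best-pair-first on the rectangular S.I. matrix and
averaging the matched values — a measure of how robust the organization is
to the random initial configuration.

The package also provides the surrounding toolkit: edge-list I/O, an
Erdős–Rényi generator matched to a natural network (`p = m/(N(N−1)/2)`),
a tunable-transitivity generator in the style of Volz (prescribed degree
sequence, probabilistic closure of distance-2 triads), the topology metric
vector (SFFI, APL, diameter, ACC, transitivity, modularity), and the
backward-eliminated multiple regression of equilibrium SSI on topology.

## Worked example

Evolve a pseudocell under a clique-rich 24-species interactome (4 cliques
of 6 in a ring) and under a size-matched Erdős–Rényi control, at the
desk-scale profile (12³ lattice, 20 % occupancy, 10 000 steps):

```python
import protnet as pn

net = pn.make_fixture_network("ring_of_cliques", 4, clique_size=6)
rep = pn.topology_report(net)
print(rep.transitivity, rep.acc)        # 0.845 0.913

cfg = pn.desk_scale_config(n_steps=10000, seed=42)
trace = pn.run(net, cfg)
print(pn.ssi_timeseries(trace))
```

```
 step  n_complexes       ssi
    0            0   0.000000
 1000           43  10.563273
 3000           37  16.202513
 5000           38  16.521658
10000           30  30.447024
```

The SSI climbs as recurring near-clique complexes take over the cell.  The
same run under the Erdős–Rényi control (`pn.erdos_renyi(24, 64, seed=42)`)
plateaus at SSI ≈ 11.8: random rules support many complex types and the
cell stays disorganized, while the clique-rich rules converge on few
recurring compositions (final SSI ≈ 30.4, i.e. approaching the `k² = 36`
ceiling of identical 6-species complexes).

The same comparison is available as replicated studies
(`pn.ssi_evolution_study`, `pn.icsi_robustness_study`) and at the
full-scale profile (`pn.full_scale_config()`: 50³ lattice, 150 000 steps —
hours of CPU per replicate).  A `protnet` command-line entry point exposes
`generate`, `metrics`, `run`, `ssi`, `icsi` and `regress` subcommands.

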