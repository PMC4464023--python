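"""Random-network generators used as simulator rule sets.

Two families are provided:

* :func:`erdos_renyi` — a G(N, p) graph with p chosen so that the expected
  edge count matches a natural network, ``p = m / (N (N - 1) / 2)``.
* :func:`volz_network` — a growth process with a prescribed degree sequence
  whose transitivity is tunable: at each step the current node closes triads
  with nodes at graph distance 2 ("potential triads") with a probability set
  by the target transitivity, otherwise attaches a fresh node.  Sweeping the
  target from 0 to 1 produces graph families whose realized transitivity
  rises while the degree distribution stays fixed.
"""

from __future__ import annotations

import logging
import random
from typing import Sequence

import networkx as nx

from .network_io import InteractionNetwork

logger = logging.getLogger(__name__)

__all__ = ["erdos_renyi", "volz_network", "degree_sequence_of", "resample_degrees"]


def _names(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"N{i:0{width}d}" for i in range(n)]


def erdos_renyi(N: int, m: int, seed: int | None = None) -> InteractionNetwork:
    """G(N, p) with ``p = m / (N(N-1)/2)``; realized edge count is random.

    ``m`` is the *desired* (expected) number of edges, typically taken from
    the natural network being mimicked.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    n_pairs = N * (N - 1) // 2
    if not (0 <= m <= n_pairs):
        raise ValueError(f"m={m} outside [0, {n_pairs}]")
    p = m / n_pairs
    g = nx.fast_gnp_random_graph(N, p, seed=seed)
    return InteractionNetwork(_names(N), g.edges())


def degree_sequence_of(network: InteractionNetwork) -> list[int]:
    """Per-node degree list; sums to twice the edge count."""
    return [network.degree_of(i) for i in range(network.n_nodes)]


def resample_degrees(degrees: Sequence[int], n: int, seed: int | None = None
                     ) -> list[int]:
    """Sample ``n`` degrees with replacement from an empirical degree multiset."""
    rng = random.Random(seed)
    return [rng.choice(list(degrees)) for _ in range(n)]


def volz_network(degrees: Sequence[int], target_transitivity: float,
                 seed: int | None = None) -> InteractionNetwork:
    """Grow a network with the given degree sequence and tunable transitivity.

    Nodes start with a stub budget equal to their prescribed degree.  Growth
    begins from a random node; repeatedly, a node with free stubs is chosen
    and offered every distance-2 node with free stubs as a triad to close,
    each accepted with probability ``target_transitivity``.  If no triad is
    closed, a random not-yet-attached node is connected instead, so the
    network keeps growing until every (nonzero-degree) node has a neighbor.
    Leftover free stubs are then resolved by uniform stub matching that skips
    self-loops and duplicate edges; unmatched stubs are dropped with a logged
    count.  The realized degree sequence therefore only approximates the
    prescribed one, and the realized (not the target) transitivity is what
    downstream analyses should use.
    """
    if not (0.0 <= target_transitivity <= 1.0):
        raise ValueError("target_transitivity must be in [0, 1]")
    degrees = list(degrees)
    n = len(degrees)
    if n == 0 or all(d == 0 for d in degrees):
        raise ValueError("degree sequence must contain a positive degree")
    if any(d < 0 for d in degrees):
        raise ValueError("degrees must be non-negative")

    rng = random.Random(seed)
    free = list(degrees)                      # remaining stubs per node
    adj: list[set[int]] = [set() for _ in range(n)]
    attached = [False] * n                    # node is part of the network
    unattached = [v for v in range(n) if degrees[v] > 0]
    rng.shuffle(unattached)                   # pop() draws uniformly

    def connect(a: int, b: int) -> None:
        adj[a].add(b)
        adj[b].add(a)
        free[a] -= 1
        free[b] -= 1
        for v in (a, b):
            if not attached[v]:
                attached[v] = True

    v0 = unattached.pop()
    attached[v0] = True
    # nodes in the network that may still accept edges, visited round-robin
    frontier = [v0]
    while unattached or frontier:
        frontier = [v for v in frontier if free[v] > 0]
        if not frontier:
            if not unattached:
                break
            v = unattached.pop()
            attached[v] = True
            frontier = [v]
        vi = frontier[rng.randrange(len(frontier))]

        closed = False
        if free[vi] > 0:
            # nodes at distance exactly 2 with free stubs
            potential = sorted(
                {w for u in adj[vi] for w in adj[u]
                 if w != vi and w not in adj[vi] and free[w] > 0}
            )
            rng.shuffle(potential)
            for w in potential:
                if free[vi] == 0:
                    break
                if rng.random() < target_transitivity:
                    connect(vi, w)
                    closed = True
        if not closed and free[vi] > 0:
            if unattached:
                u = unattached.pop()
                connect(vi, u)
                frontier.append(u)
            else:
                # attach to some network node with free stubs
                candidates = [w for w in range(n)
                              if attached[w] and w != vi and free[w] > 0
                              and w not in adj[vi]]
                if candidates:
                    connect(vi, candidates[rng.randrange(len(candidates))])
                else:
                    free[vi] = 0      # stubs unmatchable; dropped below
        if free[vi] == 0:
            frontier.remove(vi)

    # resolve leftover stubs by uniform stub matching
    stubs: list[int] = []
    for v in range(n):
        stubs.extend([v] * free[v])
    rng.shuffle(stubs)
    dropped = 0
    while len(stubs) >= 2:
        a = stubs.pop()
        partners = [k for k, b in enumerate(stubs) if b != a and b not in adj[a]]
        if not partners:
            dropped += 1
            continue
        b = stubs.pop(partners[rng.randrange(len(partners))])
        connect(a, b)
    dropped += len(stubs)
    if dropped:
        logger.info("volz_network: %d unmatched stubs dropped", dropped)

    edges = {(a, b) for a in range(n) for b in adj[a] if a < b}
    return InteractionNetwork(_names(n), edges)
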