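"""Reading, writing and fixture generation of protein-interaction networks.

A network is an undirected, unweighted simple graph whose nodes are protein
species and whose edges are experimentally supported (or synthetic) binary
interactions.  Internally species carry dense 0-based integer ids for fast
array indexing in the simulator; all file I/O is by species name.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionNetwork",
    "read_edge_list",
    "write_edge_list",
    "make_fixture_network",
]


@dataclass(frozen=True)
class ProteinSpecies:
    """A protein species: dense integer id plus the label from the input file."""

    id: int
    name: str


class InteractionNetwork:
    """Undirected simple graph of protein species.

    Edges are stored once as unordered id pairs ``(a, b)`` with ``a <= b``.
    Self-loops (homodimerisation rules) are kept if present in the input and
    flagged via :attr:`has_self_loops`; note that the simulator's
    one-species-per-complex rule makes them inert in practice.
    """

    def __init__(self, names: Sequence[str], edges: Iterable[tuple[int, int]]):
        self.names: list[str] = list(names)
        if len(set(self.names)) != len(self.names):
            raise ValueError("species names must be unique")
        self.index: dict[str, int] = {n: i for i, n in enumerate(self.names)}
        canon = set()
        for a, b in edges:
            if not (0 <= a < len(self.names) and 0 <= b < len(self.names)):
                raise ValueError(f"edge ({a},{b}) references unknown species id")
            canon.add((a, b) if a <= b else (b, a))
        self.edges: set[tuple[int, int]] = canon
        # adjacency sets, used as the simulator's interaction rule table
        self.adjacency: list[set[int]] = [set() for _ in self.names]
        for a, b in self.edges:
            self.adjacency[a].add(b)
            self.adjacency[b].add(a)

    # -- basic protocol -----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.names)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def has_self_loops(self) -> bool:
        return any(a == b for a, b in self.edges)

    @property
    def species(self) -> list[ProteinSpecies]:
        return [ProteinSpecies(i, n) for i, n in enumerate(self.names)]

    def degree_of(self, node: int) -> int:
        d = len(self.adjacency[node])
        # a self-loop contributes 2 to the conventional degree
        if (node, node) in self.edges:
            d += 1
        return d

    def __eq__(self, other) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        mine = {tuple(sorted((self.names[a], self.names[b]))) for a, b in self.edges}
        theirs = {
            tuple(sorted((other.names[a], other.names[b]))) for a, b in other.edges
        }
        return set(self.names) == set(other.names) and mine == theirs

    def __repr__(self) -> str:
        return f"InteractionNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph, names: Sequence[str] | None = None
                      ) -> "InteractionNetwork":
        nodes = list(g.nodes())
        order = {n: i for i, n in enumerate(nodes)}
        if names is None:
            names = [str(n) for n in nodes]
        return cls(names, ((order[a], order[b]) for a, b in g.edges()))

    @classmethod
    def from_named_edges(cls, pairs: Iterable[tuple[str, str]]) -> "InteractionNetwork":
        """Build from name pairs; the node set is the union of the endpoints."""
        pairs = list(pairs)
        names = sorted({n for p in pairs for n in p})
        index = {n: i for i, n in enumerate(names)}
        return cls(names, ((index[a], index[b]) for a, b in pairs))


class EdgeListFormatError(ValueError):
    """Raised for malformed edge-list rows (the message names the line)."""


def read_edge_list(path: str | Path, weight_threshold: float | None = None
                   ) -> InteractionNetwork:
    """Read a whitespace/tab edge list into an :class:`InteractionNetwork`.

    The file needs two name columns; an optional third numeric column is a
    relevance score.  When ``weight_threshold`` is given, rows scoring below
    it are dropped before deduplication.  Lines starting with ``#`` and blank
    lines are ignored.  Duplicate rows (including reversed duplicates) are
    merged silently with a logged count.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    n_dropped = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 2:
                raise EdgeListFormatError(
                    f"{path}:{lineno}: expected at least 2 columns, got {len(cols)}"
                )
            if weight_threshold is not None:
                if len(cols) < 3:
                    raise EdgeListFormatError(
                        f"{path}:{lineno}: weight_threshold given but row has no "
                        "score column"
                    )
                try:
                    score = float(cols[2])
                except ValueError as exc:
                    raise EdgeListFormatError(
                        f"{path}:{lineno}: malformed score {cols[2]!r}"
                    ) from exc
                if score < weight_threshold:
                    n_dropped += 1
                    continue
            pairs.append((cols[0], cols[1]))

    net = InteractionNetwork.from_named_edges(pairs)
    n_dup = len(pairs) - net.n_edges
    if n_dropped or n_dup:
        logger.info(
            "read_edge_list(%s): %d rows below threshold dropped, "
            "%d duplicate rows merged", path, n_dropped, n_dup,
        )
    return net


def write_edge_list(network: InteractionNetwork, path: str | Path) -> None:
    """Write a two-column TSV, one unordered edge per line, species names."""
    path = Path(path)
    with path.open("w") as fh:
        for a, b in sorted(network.edges):
            fh.write(f"{network.names[a]}\t{network.names[b]}\n")


# -- deterministic fixture graphs -------------------------------------------

FIXTURE_KINDS = ("overlapping_cliques", "clique_chain", "star", "path", "ring_of_cliques")


def _species_names(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"P{i:0{width}d}" for i in range(1, n + 1)]


def make_fixture_network(kind: str, size: int, clique_size: int = 6
                         ) -> InteractionNetwork:
    """Deterministic named graphs for tests and demonstrations.

    kinds
    -----
    ``star``
        one hub plus ``size`` leaves.
    ``path``
        a simple path on ``size`` nodes.
    ``clique_chain`` / ``ring_of_cliques``
        ``size`` cliques of ``clique_size`` nodes joined consecutively by
        single edges (the ring closes the chain).  These are the clique-rich
        interactomes used as structured counterparts to Erdős–Rényi controls:
        their transitivity is high while node and edge counts stay small.
    ``overlapping_cliques``
        a fixed 8-species graph of two overlapping cliques, small enough to
        enumerate the complex types it supports by hand.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    if kind == "star":
        names = _species_names(size + 1)
        return InteractionNetwork(names, ((0, i) for i in range(1, size + 1)))
    if kind == "path":
        names = _species_names(size)
        return InteractionNetwork(names, ((i, i + 1) for i in range(size - 1)))
    if kind in ("clique_chain", "ring_of_cliques"):
        k = clique_size
        if k < 2:
            raise ValueError("clique_size must be >= 2")
        names = _species_names(size * k)
        edges: list[tuple[int, int]] = []
        for c in range(size):
            base = c * k
            edges.extend(
                (base + i, base + j) for i in range(k) for j in range(i + 1, k)
            )
        # joining edges between consecutive cliques
        for c in range(size - 1):
            edges.append((c * k, (c + 1) * k))
        if kind == "ring_of_cliques" and size > 1:
            edges.append(((size - 1) * k, 0))
        return InteractionNetwork(names, edges)
    if kind == "overlapping_cliques":
        # two 4-cliques sharing a bridge, plus a pendant dimer partner
        names = _species_names(8)
        cliq1 = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        cliq2 = [(i, j) for i in range(3, 7) for j in range(i + 1, 7)]
        return InteractionNetwork(names, cliq1 + cliq2 + [(6, 7)])
    raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
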