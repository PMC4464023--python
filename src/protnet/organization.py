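"""Pseudocell organization metrics: S.I., SSI and ICSI.

A complex composition is the set of distinct protein species in one complex.
The pairwise Similarity Index of two compositions C1, C2 is

    S.I.(C1, C2) = |C1 ∩ C2|^2 / (|C1 Δ C2| + 1)

with Δ the symmetric difference; squaring the intersection weights large
shared cores more heavily.  The Self-Similarity Index of a cell with complex
list C1..Cn is the mean of each complex's best S.I. against the later
complexes in the list,

    SSI = (1/n) * sum_{i=1}^{n-1} max_{j>i} S.I.(Ci, Cj),

so a cell of few recurring complex types scores high and a cell of many
distinct types scores near zero.  The Inter-Cells Similarity Index compares
two cells by greedily matching their complexes best-pair-first on the n x m
S.I. matrix and averaging the min(n, m) matched values.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "similarity_index",
    "similarity_matrix",
    "self_similarity_index",
    "inter_cell_similarity_index",
    "canonical_order",
    "read_complex_list",
    "ssi_timeseries",
]

Composition = frozenset


def similarity_index(c1: Iterable, c2: Iterable) -> float:
    """|C1 ∩ C2|^2 / (|C1 Δ C2| + 1); symmetric, non-negative.

    Identical compositions of size k score k^2; disjoint ones score 0.
    """
    s1, s2 = set(c1), set(c2)
    if not s1 or not s2:
        raise ValueError("compositions must be non-empty")
    inter = len(s1 & s2)
    if inter == 0:
        return 0.0
    sym_diff = len(s1) + len(s2) - 2 * inter
    return inter * inter / (sym_diff + 1)


def canonical_order(cell: Sequence[Iterable]) -> list[frozenset]:
    """Deterministic complex ordering: descending size, then sorted names."""
    return sorted((frozenset(c) for c in cell),
                  key=lambda c: (-len(c), tuple(sorted(c))))


def similarity_matrix(cell_a: Sequence[Iterable], cell_b: Sequence[Iterable]
                      ) -> np.ndarray:
    """Pairwise S.I. matrix (rows: cell_a, cols: cell_b)."""
    a = [frozenset(c) for c in cell_a]
    b = [frozenset(c) for c in cell_b]
    out = np.zeros((len(a), len(b)))
    for i, ci in enumerate(a):
        for j, cj in enumerate(b):
            out[i, j] = similarity_index(ci, cj)
    return out


def self_similarity_index(cell: Sequence[Iterable], symmetric: bool = False,
                          canonicalize: bool = True) -> float:
    """SSI of one cell's complex list (a multiset of compositions).

    The literal upper-triangular form depends on the list order, so the list
    is first put in canonical order (descending size, then lexicographic)
    unless ``canonicalize=False``.  With ``symmetric=True`` every complex is
    instead matched against *all* others ("mean of the best pairwise
    similarities"), which is order-free; both variants agree on cells of
    identical complexes.
    """
    comps = [frozenset(c) for c in cell]
    if any(not c for c in comps):
        raise ValueError("compositions must be non-empty")
    n = len(comps)
    if n < 2:
        if n <= 1:
            warnings.warn("SSI of a cell with fewer than 2 complexes is 0")
        return 0.0
    if canonicalize and not symmetric:
        comps = canonical_order(comps)
    total = 0.0
    for i in range(n - 1 if not symmetric else n):
        others = comps[i + 1:] if not symmetric else comps[:i] + comps[i + 1:]
        total += max(similarity_index(comps[i], o) for o in others)
    return total / n


def inter_cell_similarity_index(cell_a: Sequence[Iterable],
                                cell_b: Sequence[Iterable]) -> float:
    """Greedy best-match-first mean S.I. between two cells' complex lists.

    Repeatedly take the largest entry of the rectangular S.I. matrix, record
    it, and delete its row and column, until rows or columns run out; the
    ICSI is the mean of the recorded values.  Ties break on the lowest
    (row, column) pair.  Both lists are canonically ordered first so the
    result does not depend on input order.
    """
    a = canonical_order(cell_a)
    b = canonical_order(cell_b)
    if not a or not b:
        raise ValueError("both cells must contain at least one complex")
    m = similarity_matrix(a, b)
    picked = []
    for _ in range(min(len(a), len(b))):
        flat = int(np.argmax(m))          # first maximum in row-major order
        i, j = divmod(flat, m.shape[1])
        picked.append(m[i, j])
        m = np.delete(np.delete(m, i, axis=0), j, axis=1)
    return float(np.mean(picked))


# -- snapshot parsing --------------------------------------------------------

def read_complex_list(path: str | Path, include_monomers: bool = False
                      ) -> list[frozenset[str]]:
    """Parse one plain-text snapshot into a complex list.

    Each non-comment line is one complex: tab-separated species names; a
    single-column line is a monomer.  Monomers are excluded by default (a
    complex is at least two proteins).
    """
    path = Path(path)
    cell: list[frozenset[str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            names = line.split("\t")
            if any(not n for n in names):
                raise ValueError(f"{path}:{lineno}: empty species name")
            comp = frozenset(names)
            if len(comp) != len(names):
                raise ValueError(f"{path}:{lineno}: duplicate species in complex")
            if include_monomers or len(comp) > 1:
                cell.append(comp)
    return cell


def ssi_timeseries(trace, include_monomers: bool = False,
                   symmetric: bool = False) -> pd.DataFrame:
    """SSI per recorded snapshot of a simulation trace.

    Accepts any object with a ``snapshots`` attribute of ``(step,
    compositions)`` pairs (a :class:`~protnet.simulation.SimulationTrace`),
    or a directory of snapshot files.  Returns a tidy frame with columns
    ``step``, ``n_complexes``, ``ssi``.
    """
    if isinstance(trace, (str, Path)):
        rows = []
        for p in sorted(Path(trace).glob("snapshot_*.tsv")):
            step = None
            with p.open() as fh:
                for line in fh:
                    if line.startswith("#step"):
                        step = int(line.split()[1])
                        break
            if step is None:
                raise ValueError(f"{p}: missing '#step' header")
            rows.append((step, read_complex_list(p, include_monomers)))
    else:
        rows = [
            (step_no,
             [c for c in comps if include_monomers or len(c) > 1])
            for step_no, comps in trace.snapshots
        ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # n<2 cells legitimately score 0
        data = [
            (step_no, len(cell),
             self_similarity_index(cell, symmetric=symmetric) if cell else 0.0)
            for step_no, cell in rows
        ]
    return pd.DataFrame(data, columns=["step", "n_complexes", "ssi"])
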