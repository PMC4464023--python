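"""The 24 proper rotations of the cube, and their action on lattice data.

Face directions are indexed 0..5 as +x, -x, +y, -y, +z, -z; the opposite of
direction ``d`` is ``d ^ 1``.  Rotation *generators* are the six 90-degree
rotations (one per axis and sense); each is also an element of the full
24-element group used to track instance orientations.
"""

from __future__ import annotations

import itertools

# unit vectors per direction index
DIR_VECS = ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1))
DX = tuple(v[0] for v in DIR_VECS)
DY = tuple(v[1] for v in DIR_VECS)
DZ = tuple(v[2] for v in DIR_VECS)


def _matmul(a, b):
    return tuple(
        tuple(sum(a[i][k] * b[k][j] for k in range(3)) for j in range(3))
        for i in range(3)
    )


def _det(m):
    return (m[0][0] * (m[1][1] * m[2][2] - m[1][2] * m[2][1])
            - m[0][1] * (m[1][0] * m[2][2] - m[1][2] * m[2][0])
            + m[0][2] * (m[1][0] * m[2][1] - m[1][1] * m[2][0]))


def _all_rotations():
    mats = []
    for perm in itertools.permutations(range(3)):
        for signs in itertools.product((1, -1), repeat=3):
            m = [[0] * 3 for _ in range(3)]
            for i in range(3):
                m[i][perm[i]] = signs[i]
            m = tuple(tuple(r) for r in m)
            if _det(m) == 1:
                mats.append(m)
    return mats


ROTATIONS = _all_rotations()                      # all 24, identity included
assert len(ROTATIONS) == 24
IDENTITY = ROTATIONS.index(((1, 0, 0), (0, 1, 0), (0, 0, 1)))

# 90-degree generators: +x, -x, +y, -y, +z, -z senses
_GEN_MATS = (
    ((1, 0, 0), (0, 0, -1), (0, 1, 0)),
    ((1, 0, 0), (0, 0, 1), (0, -1, 0)),
    ((0, 0, 1), (0, 1, 0), (-1, 0, 0)),
    ((0, 0, -1), (0, 1, 0), (1, 0, 0)),
    ((0, -1, 0), (1, 0, 0), (0, 0, 1)),
    ((0, 1, 0), (-1, 0, 0), (0, 0, 1)),
)
GEN_MATS = _GEN_MATS
GEN_INDEX = tuple(ROTATIONS.index(m) for m in _GEN_MATS)

# COMPOSE[g][o]: orientation index after applying generator g to orientation o
COMPOSE = tuple(
    tuple(ROTATIONS.index(_matmul(g, o)) for o in ROTATIONS) for g in _GEN_MATS
)

# DIR_PERM[g][d]: image of face direction d under generator g
def _apply(m, v):
    return tuple(sum(m[i][k] * v[k] for k in range(3)) for i in range(3))


DIR_PERM = tuple(
    tuple(DIR_VECS.index(_apply(g, DIR_VECS[d])) for d in range(6))
    for g in _GEN_MATS
)
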