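"""Exact-chain reference for the 2x2x2 two-protein pseudocell.

An independent enumerator of the automaton's one-step transition law,
written from first principles over the 80 reachable configurations
(ordered positions of the two instances plus the bond flag).  It mirrors
the published dynamics — site-raster visits, break-then-form within a
visit, one action per complex per diffusion phase, monomer pushes, rigid
dimer rotation about the lower-id member — without sharing any code with
the simulator, and yields the exact stationary distribution that long
simulator runs are tested against.
"""

import numpy as np

BITS = (4, 2, 1)  # grid-site bit flipped by a move along axis x, y, z


def hamming_axes(a, b):
    """Axes along which two sites of the 2-lattice differ."""
    return [ax for ax in range(3) if (a ^ b) & BITS[ax]]


def enumerate_states():
    states = []
    for a in range(8):
        for b in range(8):
            if a == b:
                continue
            states.append((a, b, 0))
            if len(hamming_axes(a, b)) == 1:
                states.append((a, b, 1))
    return states


def interaction_dist(state, p_on, p_off):
    """Bond-flag distribution after one interaction phase (positions fixed).

    On the 2-lattice an adjacent partner is reachable through both senses of
    the differing axis, so a formation visit succeeds with probability
    q = 1 - (1 - p_on)^2; a bonded visit first breaks with p_off and may
    rebind in the same visit's form loop.
    """
    a, b, bond = state
    if len(hamming_axes(a, b)) != 1:
        return {state: 1.0}
    q = 1 - (1 - p_on) ** 2
    dist = {bond: 1.0}
    for _visit in range(2):          # both instances get visited
        new = {0: 0.0, 1: 0.0}
        for flag, p in dist.items():
            if flag:
                new[1] += p * ((1 - p_off) + p_off * q)
                new[0] += p * (p_off * (1 - q))
            else:
                new[1] += p * q
                new[0] += p * (1 - q)
        dist = new
    return {(a, b, f): p for f, p in dist.items() if p > 0}


def diffusion_dist(state):
    """Configuration distribution after one diffusion phase."""
    out = {}

    def rec(s, a, b, bond, stamped_a, stamped_b, prob):
        # when bonded, stamped_a doubles as the single dimer stamp
        if s == 8:
            key = (a, b, bond)
            out[key] = out.get(key, 0.0) + prob
            return
        if a != s and b != s:
            rec(s + 1, a, b, bond, stamped_a, stamped_b, prob)
            return
        if bond:
            if stamped_a:
                rec(s + 1, a, b, bond, stamped_a, stamped_b, prob)
                return
            bond_ax = hamming_axes(a, b)[0]
            # rotation attempted w.p. 1/2 (diameter 2); of the 6 generators,
            # the 2 about the bond axis fix B, the other 4 land B on A's
            # neighbour along the image axis (mod 2 the sense is immaterial);
            # the pivot is the lower-id member, instance A
            rot_branches = [(b, 0.5 + 0.5 * (2 / 6))]
            for g_ax in range(3):
                if g_ax == bond_ax:
                    continue
                img = 3 - g_ax - bond_ax
                rot_branches.append((a ^ BITS[img], 0.5 * (2 / 6)))
            for b1, p_rot in rot_branches:
                # translation attempted w.p. 1/2 (mass 2); never blocked
                rec(s + 1, a, b1, 1, True, True, prob * p_rot * 0.5)
                for d_ax in range(3):
                    rec(s + 1, a ^ BITS[d_ax], b1 ^ BITS[d_ax], 1, True, True,
                        prob * p_rot * 0.5 * (2 / 6))
            return
        mover_is_a = (a == s)
        if (stamped_a if mover_is_a else stamped_b):
            rec(s + 1, a, b, bond, stamped_a, stamped_b, prob)
            return
        cur, other = (a, b) if mover_is_a else (b, a)
        for d_ax in range(3):        # both senses of each axis coincide
            tgt = cur ^ BITS[d_ax]
            if tgt == other:         # push of an equal mass always succeeds
                ncur, nother = tgt, other ^ BITS[d_ax]
            else:
                ncur, nother = tgt, other
            na, nb = (ncur, nother) if mover_is_a else (nother, ncur)
            rec(s + 1, na, nb, 0,
                stamped_a or mover_is_a, stamped_b or not mover_is_a,
                prob * (2 / 6))

    rec(0, state[0], state[1], state[2], False, False, 1.0)
    return out


def transition_matrix(p_on, p_off):
    states = enumerate_states()
    idx = {s: k for k, s in enumerate(states)}
    T = np.zeros((len(states), len(states)))
    for s in states:
        for mid, p1 in interaction_dist(s, p_on, p_off).items():
            for end, p2 in diffusion_dist(mid).items():
                T[idx[s], idx[end]] += p1 * p2
    return states, T


def stationary(T):
    vals, vecs = np.linalg.eig(T.T)
    pi = np.real(vecs[:, np.argmin(np.abs(vals - 1))])
    pi = np.clip(pi / pi.sum(), 0, None)
    return pi / pi.sum()


def classify(state):
    a, b, bond = state
    return "bonded" if bond else f"free_d{len(hamming_axes(a, b))}"


def stationary_class_probs(p_on, p_off):
    states, T = transition_matrix(p_on, p_off)
    pi = stationary(T)
    agg = {}
    for s, p in zip(states, pi):
        agg[classify(s)] = agg.get(classify(s), 0.0) + p
    return agg
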