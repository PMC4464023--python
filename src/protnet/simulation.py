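"""The pseudocell cellular automaton.

A pseudocell is a cubic lattice of L^3 sites, each holding at most one
protein instance.  Instances carry a species label; an input interaction
network decides which species pairs may bond.  Each automaton step has two
phases:

* **interaction phase** — the grid is visited site by site; the resident
  instance first breaks each of its bonds independently with probability
  ``p_off``, then forms a bond with probability ``p_on`` to each face-adjacent
  instance of an interacting species, provided the merged complex would not
  contain two copies of any species and both faces are free (six binding
  sites per protein, one per cube face).

* **diffusion phase** — the grid is visited again; the first encountered
  member of each complex triggers at most one move: a rigid 90-degree
  rotation about the member nearest the centre of mass (attempted with
  probability 1/diameter) followed by a one-site translation (attempted with
  probability 1/mass, so monomers always try).  A translation may push
  blocking complexes recursively, each push accepted with probability
  ``min(1, m_mover / m_blocked)``; any failed push rejects the whole move.

Complexes are the connected components of the bond graph and are maintained
incrementally (union on bond creation, a connectivity recheck on deletion).
Positions are stored unwrapped so rigid motion is exact across periodic
boundaries; the grid index is the coordinate modulo L.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

from ._rotations import COMPOSE, DIR_PERM, DX, DY, DZ, GEN_MATS, IDENTITY
from .network_io import InteractionNetwork

__all__ = [
    "SimulationConfig",
    "SimulationState",
    "SimulationTrace",
    "ComplexRecord",
    "initialize",
    "interaction_phase",
    "diffusion_phase",
    "step",
    "run",
    "complexes",
    "write_trace",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Lattice geometry, kinetic probabilities and bookkeeping knobs.

    Defaults are the reference full-scale settings: a 50-lattice (125000
    sites) filled to 20% occupancy, uniform bond formation probability 0.7
    and breaking probability 0.002 per visit, run for 150000 steps.
    """

    L: int = 50
    occupancy: float = 0.20
    p_on: float = 0.7
    p_off: float = 0.002
    n_steps: int = 150000
    seed: int = 0
    boundary: str = "periodic"          # "periodic" | "closed"
    move_law: str = "mass"              # translation prob 1/mass | 1/diameter
    visit_order: str = "raster"         # "raster" | "random"
    record_every: int = 1000

    def __post_init__(self):
        if self.L < 2:
            raise ValueError("L must be >= 2")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError("occupancy must be in [0, 1]")
        for name in ("p_on", "p_off"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.boundary not in ("periodic", "closed"):
            raise ValueError("boundary must be 'periodic' or 'closed'")
        if self.move_law not in ("mass", "diameter"):
            raise ValueError("move_law must be 'mass' or 'diameter'")
        if self.visit_order not in ("raster", "random"):
            raise ValueError("visit_order must be 'raster' or 'random'")


class _Complex:
    """Internal record: one connected component of the bond graph."""

    __slots__ = ("members", "species", "bbox", "moved")

    def __init__(self, members, species, bbox):
        self.members: list[int] = members
        self.species: set[int] = species
        self.bbox: list[int] = bbox      # minx,maxx,miny,maxy,minz,maxz
        self.moved: int = -1             # diffusion-phase stamp

    @property
    def mass(self) -> int:
        return len(self.members)

    @property
    def diameter(self) -> int:
        b = self.bbox
        return max(b[1] - b[0], b[3] - b[2], b[5] - b[4]) + 1


@dataclass(frozen=True)
class ComplexRecord:
    """Snapshot view of one complex: members, mass, composition, extent."""

    members: tuple[int, ...]
    mass: int
    species_set: frozenset[int]
    diameter: int


class SimulationState:
    """Full mutable state of a pseudocell; create via :func:`initialize`."""

    def __init__(self, network: InteractionNetwork, config: SimulationConfig):
        self.network = network
        self.config = config
        self.rng = random.Random(config.seed)
        L = config.L
        self.L = L
        self.n_sites = L * L * L
        self.grid: list[int] = [-1] * self.n_sites
        self.px: list[int] = []
        self.py: list[int] = []
        self.pz: list[int] = []
        self.site: list[int] = []
        self.species_of: list[int] = []
        self.orient: list[int] = []
        self.bonds: list[list[int]] = []
        self.comp_of: list[int] = []
        self.complexes: dict[int, _Complex] = {}
        self._next_cid = 0
        self._diff_stamp = 0
        self.step_count = 0
        self.initial_species_counts: dict[int, int] = {}
        # neighbor table: nbr[site][dir] -> site index, or -1 past a closed wall
        periodic = config.boundary == "periodic"
        nbr = []
        for x in range(L):
            for y in range(L):
                for z in range(L):
                    row = []
                    for d in range(6):
                        nx_, ny_, nz_ = x + DX[d], y + DY[d], z + DZ[d]
                        if periodic:
                            row.append(((nx_ % L) * L + ny_ % L) * L + nz_ % L)
                        elif 0 <= nx_ < L and 0 <= ny_ < L and 0 <= nz_ < L:
                            row.append((nx_ * L + ny_) * L + nz_)
                        else:
                            row.append(-1)
                    nbr.append(row)
        self.nbr: list[list[int]] = nbr

    # -- construction helpers ----------------------------------------------
    @property
    def n_instances(self) -> int:
        return len(self.species_of)

    def _site_of_coords(self, x: int, y: int, z: int) -> int:
        L = self.L
        return ((x % L) * L + y % L) * L + z % L

    def add_instance(self, species_id: int, x: int, y: int, z: int,
                     orientation: int = IDENTITY) -> int:
        """Place one unbonded instance (used by initialize and by tests)."""
        s = self._site_of_coords(x, y, z)
        if self.grid[s] != -1:
            raise ValueError(f"site {s} already occupied")
        i = len(self.species_of)
        self.grid[s] = i
        self.px.append(x)
        self.py.append(y)
        self.pz.append(z)
        self.site.append(s)
        self.species_of.append(species_id)
        self.orient.append(orientation)
        self.bonds.append([-1] * 6)
        cid = self._next_cid
        self._next_cid += 1
        self.comp_of.append(cid)
        self.complexes[cid] = _Complex([i], {species_id}, [x, x, y, y, z, z])
        return i

    # -- bond bookkeeping ---------------------------------------------------
    def _form_bond(self, i: int, d: int, j: int) -> None:
        self.bonds[i][d] = j
        self.bonds[j][d ^ 1] = i
        ci, cj = self.comp_of[i], self.comp_of[j]
        if ci == cj:
            return
        Ci, Cj = self.complexes[ci], self.complexes[cj]
        # re-anchor so the bonded pair is adjacent in unwrapped coordinates
        ox = self.px[i] + DX[d] - self.px[j]
        oy = self.py[i] + DY[d] - self.py[j]
        oz = self.pz[i] + DZ[d] - self.pz[j]
        if Cj.mass <= Ci.mass:
            big, small, scid = Ci, Cj, cj
            shift = (ox, oy, oz)
            keep = ci
        else:
            big, small, scid = Cj, Ci, ci
            shift = (-ox, -oy, -oz)
            keep = cj
        sx, sy, sz = shift
        if sx or sy or sz:
            px, py, pz = self.px, self.py, self.pz
            for m in small.members:
                px[m] += sx
                py[m] += sy
                pz[m] += sz
            b = small.bbox
            small.bbox = [b[0] + sx, b[1] + sx, b[2] + sy, b[3] + sy,
                          b[4] + sz, b[5] + sz]
        for m in small.members:
            self.comp_of[m] = keep
        big.members.extend(small.members)
        big.species |= small.species
        bb, sb = big.bbox, small.bbox
        big.bbox = [min(bb[0], sb[0]), max(bb[1], sb[1]),
                    min(bb[2], sb[2]), max(bb[3], sb[3]),
                    min(bb[4], sb[4]), max(bb[5], sb[5])]
        if small.moved > big.moved:
            big.moved = small.moved
        del self.complexes[scid]

    def _delete_bond(self, i: int, d: int, j: int) -> None:
        self.bonds[i][d] = -1
        self.bonds[j][d ^ 1] = -1
        cid = self.comp_of[i]
        C = self.complexes[cid]
        # connectivity recheck restricted to the affected complex
        reached = {i}
        queue = [i]
        while queue:
            m = queue.pop()
            for p in self.bonds[m]:
                if p >= 0 and p not in reached:
                    reached.add(p)
                    queue.append(p)
        if len(reached) == C.mass:
            return
        stay = [m for m in C.members if m in reached]
        leave = [m for m in C.members if m not in reached]
        C.members = stay
        C.species = {self.species_of[m] for m in stay}
        C.bbox = self._bbox_of(stay)
        ncid = self._next_cid
        self._next_cid += 1
        for m in leave:
            self.comp_of[m] = ncid
        nc = _Complex(leave, {self.species_of[m] for m in leave},
                      self._bbox_of(leave))
        nc.moved = C.moved
        self.complexes[ncid] = nc

    def _bbox_of(self, members: Sequence[int]) -> list[int]:
        px, py, pz = self.px, self.py, self.pz
        xs = [px[m] for m in members]
        ys = [py[m] for m in members]
        zs = [pz[m] for m in members]
        return [min(xs), max(xs), min(ys), max(ys), min(zs), max(zs)]

    # -- diffusion moves ----------------------------------------------------
    def _try_rotate(self, cid: int, gen: int) -> bool:
        """Rigid 90-degree rotation about the member nearest the centre of
        mass; rejected if any target site is held by a non-member."""
        C = self.complexes[cid]
        members = C.members
        px, py, pz = self.px, self.py, self.pz
        n = len(members)
        sx = sum(px[m] for m in members)
        sy = sum(py[m] for m in members)
        sz = sum(pz[m] for m in members)
        best = None
        pivot = -1
        for m in sorted(members):
            ddx = n * px[m] - sx
            ddy = n * py[m] - sy
            ddz = n * pz[m] - sz
            d2 = ddx * ddx + ddy * ddy + ddz * ddz
            if best is None or d2 < best:
                best = d2
                pivot = m
        R = GEN_MATS[gen]
        pvx, pvy, pvz = px[pivot], py[pivot], pz[pivot]
        closed = self.config.boundary == "closed"
        L = self.L
        new_pos = []
        member_set = set(members)
        for m in members:
            rx, ry, rz = px[m] - pvx, py[m] - pvy, pz[m] - pvz
            nx_ = pvx + R[0][0] * rx + R[0][1] * ry + R[0][2] * rz
            ny_ = pvy + R[1][0] * rx + R[1][1] * ry + R[1][2] * rz
            nz_ = pvz + R[2][0] * rx + R[2][1] * ry + R[2][2] * rz
            if closed and not (0 <= nx_ < L and 0 <= ny_ < L and 0 <= nz_ < L):
                return False
            ns = ((nx_ % L) * L + ny_ % L) * L + nz_ % L
            occ = self.grid[ns]
            if occ >= 0 and occ not in member_set:
                return False
            new_pos.append((m, nx_, ny_, nz_, ns))
        grid, site = self.grid, self.site
        for m in members:
            grid[site[m]] = -1
        perm = DIR_PERM[gen]
        comp = COMPOSE[gen]
        for m, nx_, ny_, nz_, ns in new_pos:
            grid[ns] = m
            site[m] = ns
            px[m], py[m], pz[m] = nx_, ny_, nz_
            old = self.bonds[m]
            nb = [-1] * 6
            for d in range(6):
                if old[d] >= 0:
                    nb[perm[d]] = old[d]
            self.bonds[m] = nb
            self.orient[m] = comp[self.orient[m]]
        C.bbox = self._bbox_of(members)
        return True

    def _try_translate(self, cid: int, d: int) -> bool:
        """One-site translation with recursive pushing; all-or-nothing."""
        rng_random = self.rng.random
        nbr = self.nbr
        grid = self.grid
        site = self.site
        comp_of = self.comp_of
        complexes = self.complexes
        moving = [cid]
        moving_set = {cid}
        qi = 0
        while qi < len(moving):
            c = moving[qi]
            qi += 1
            cm = complexes[c]
            c_mass = len(cm.members)
            for m in cm.members:
                ns = nbr[site[m]][d]
                if ns < 0:
                    return False
                occ = grid[ns]
                if occ < 0:
                    continue
                oc = comp_of[occ]
                if oc in moving_set:
                    continue
                o_mass = len(complexes[oc].members)
                if o_mass > c_mass and rng_random() >= c_mass / o_mass:
                    return False
                moving_set.add(oc)
                moving.append(oc)
        px, py, pz = self.px, self.py, self.pz
        dx, dy, dz = DX[d], DY[d], DZ[d]
        all_members: list[int] = []
        for c in moving:
            all_members.extend(complexes[c].members)
        for m in all_members:
            grid[site[m]] = -1
        for m in all_members:
            ns = nbr[site[m]][d]
            grid[ns] = m
            site[m] = ns
            px[m] += dx
            py[m] += dy
            pz[m] += dz
        for c in moving:
            b = complexes[c].bbox
            complexes[c].bbox = [b[0] + dx, b[1] + dx, b[2] + dy, b[3] + dy,
                                 b[4] + dz, b[5] + dz]
        return True

    # -- integrity checks (used by tests and fuzzing) ------------------------
    def check_invariants(self) -> None:
        net = self.network
        n = self.n_instances
        assert sum(1 for g in self.grid if g >= 0) == n, "grid occupancy count"
        counts: dict[int, int] = {}
        for i in range(n):
            s = self.site[i]
            assert self.grid[s] == i, "grid/site inconsistency"
            assert s == self._site_of_coords(self.px[i], self.py[i], self.pz[i])
            counts[self.species_of[i]] = counts.get(self.species_of[i], 0) + 1
            nbonds = 0
            for d in range(6):
                j = self.bonds[i][d]
                if j < 0:
                    continue
                nbonds += 1
                assert self.bonds[j][d ^ 1] == i, "bond symmetry"
                assert (self.px[j] - self.px[i], self.py[j] - self.py[i],
                        self.pz[j] - self.pz[i]) == (DX[d], DY[d], DZ[d]), \
                    "bond partners must be face-adjacent (unwrapped)"
                a, b = self.species_of[i], self.species_of[j]
                assert b in net.adjacency[a], "bond joins non-interacting species"
            assert nbonds <= 6
        assert counts == self.initial_species_counts or not \
            self.initial_species_counts, "per-species conservation"
        seen: set[int] = set()
        for cid, C in self.complexes.items():
            assert len(C.species) == len(C.members), "species uniqueness"
            for m in C.members:
                assert self.comp_of[m] == cid
                assert m not in seen
                seen.add(m)
            # connectivity of the component
            reached = {C.members[0]}
            queue = [C.members[0]]
            while queue:
                m = queue.pop()
                for p in self.bonds[m]:
                    if p >= 0 and p not in reached:
                        reached.add(p)
                        queue.append(p)
            assert reached == set(C.members), "complex not connected"
            assert C.bbox == self._bbox_of(C.members), "stale bounding box"
        assert len(seen) == n


def initialize(network: InteractionNetwork, config: SimulationConfig
               ) -> SimulationState:
    """Distribute ``round(occupancy * L^3)`` monomers uniformly at random.

    Copy numbers are as equal as possible across species (all species at the
    same concentration); the remainder goes to species chosen uniformly
    without replacement.  Orientations are uniform over the 24 rotations.
    """
    state = SimulationState(network, config)
    n_sites = state.n_sites
    n = round(config.occupancy * n_sites)
    S = network.n_nodes
    if n < 1:
        raise ValueError("occupancy too low: no instances to place")
    if n < S:
        raise ValueError(
            f"{n} instances cannot cover {S} species at equal concentration")
    rng = state.rng
    base, rem = divmod(n, S)
    counts = [base] * S
    for sp in rng.sample(range(S), rem):
        counts[sp] += 1
    sites = rng.sample(range(n_sites), n)
    L = config.L
    k = 0
    for sp in range(S):
        for _ in range(counts[sp]):
            s = sites[k]
            k += 1
            x, r = divmod(s, L * L)
            y, z = divmod(r, L)
            state.add_instance(sp, x, y, z, orientation=rng.randrange(24))
    state.initial_species_counts = {sp: c for sp, c in enumerate(counts) if c}
    return state


def _visit_sites(state: SimulationState) -> Iterable[int]:
    if state.config.visit_order == "raster":
        return range(state.n_sites)
    occupied = [s for s in range(state.n_sites) if state.grid[s] >= 0]
    state.rng.shuffle(occupied)
    return occupied


def interaction_phase(state: SimulationState) -> SimulationState:
    """Site-by-site bond breaking (p_off) then formation (p_on)."""
    grid = state.grid
    bonds = state.bonds
    nbr = state.nbr
    species_of = state.species_of
    comp_of = state.comp_of
    complexes = state.complexes
    adjacency = state.network.adjacency
    p_on = state.config.p_on
    p_off = state.config.p_off
    rng_random = state.rng.random
    for s in _visit_sites(state):
        i = grid[s]
        if i < 0:
            continue
        bi = bonds[i]
        if p_off > 0.0:
            for d in range(6):
                j = bi[d]
                if j >= 0 and rng_random() < p_off:
                    state._delete_bond(i, d, j)
        if p_on <= 0.0:
            continue
        adj_i = adjacency[species_of[i]]
        nb = nbr[s]
        for d in range(6):
            if bi[d] != -1:
                continue
            t = nb[d]
            if t < 0:
                continue
            j = grid[t]
            if j < 0 or species_of[j] not in adj_i:
                continue
            if j in bi:                 # one bond per instance pair
                continue
            if bonds[j][d ^ 1] != -1:   # partner's facing site taken
                continue
            ci, cj = comp_of[i], comp_of[j]
            if ci != cj:
                if not complexes[ci].species.isdisjoint(complexes[cj].species):
                    continue            # would duplicate a species
            elif (state.px[j] - state.px[i] != DX[d]
                  or state.py[j] - state.py[i] != DY[d]
                  or state.pz[j] - state.pz[i] != DZ[d]):
                continue  # same complex, adjacent only through the wrap
            if rng_random() < p_on:
                state._form_bond(i, d, j)
    return state


def diffusion_phase(state: SimulationState) -> SimulationState:
    """Site-by-site rotation/translation; each complex acts at most once."""
    grid = state.grid
    comp_of = state.comp_of
    complexes = state.complexes
    rng = state.rng
    rng_random = rng.random
    rng_randrange = rng.randrange
    by_mass = state.config.move_law == "mass"
    state._diff_stamp += 1
    stamp = state._diff_stamp
    for s in _visit_sites(state):
        i = grid[s]
        if i < 0:
            continue
        cid = comp_of[i]
        C = complexes[cid]
        if C.moved == stamp:
            continue
        C.moved = stamp
        mass = len(C.members)
        if mass == 1:
            # monomers: diameter 1 -> always rotate (orientation only),
            # translation probability 1
            state.orient[i] = COMPOSE[rng_randrange(6)][state.orient[i]]
            state._try_translate(cid, rng_randrange(6))
            continue
        diam = C.diameter
        if diam == 1 or rng_random() < 1.0 / diam:
            state._try_rotate(cid, rng_randrange(6))
        p_move = 1.0 / mass if by_mass else 1.0 / C.diameter
        if rng_random() < p_move:
            state._try_translate(cid, rng_randrange(6))
    return state


def step(state: SimulationState) -> SimulationState:
    """One automaton step: interaction phase, then diffusion phase."""
    state.step_count += 1
    interaction_phase(state)
    diffusion_phase(state)
    return state


def complexes(state: SimulationState) -> list[ComplexRecord]:
    """The current complex list (monomers included), deterministic order."""
    out = []
    for _, C in sorted(state.complexes.items(), key=lambda kv: min(kv[1].members)):
        out.append(ComplexRecord(
            members=tuple(sorted(C.members)),
            mass=C.mass,
            species_set=frozenset(state.species_of[m] for m in C.members),
            diameter=C.diameter,
        ))
    return out


@dataclass
class SimulationTrace:
    """Recorded snapshots: ``(step, [composition, ...])`` per sample.

    A composition is the frozenset of species *names* in one complex;
    monomers appear as singleton sets.
    """

    config: SimulationConfig
    species_names: list[str]
    snapshots: list[tuple[int, list[frozenset[str]]]] = field(default_factory=list)
    extra: dict[str, list] = field(default_factory=dict)
    final_state: "SimulationState | None" = None

    def final_compositions(self, include_monomers: bool = False
                           ) -> list[frozenset[str]]:
        comps = self.snapshots[-1][1]
        if include_monomers:
            return list(comps)
        return [c for c in comps if len(c) > 1]


def _record(trace: SimulationTrace, state: SimulationState,
            recorders: dict[str, Callable[[SimulationState], object]] | None
            ) -> None:
    names = trace.species_names
    comps = [frozenset(names[state.species_of[m]] for m in C.members)
             for C in state.complexes.values()]
    trace.snapshots.append((state.step_count, comps))
    if recorders:
        for key, fn in recorders.items():
            trace.extra.setdefault(key, []).append((state.step_count, fn(state)))


def run(network: InteractionNetwork, config: SimulationConfig,
        recorders: dict[str, Callable[[SimulationState], object]] | None = None,
        out_dir: str | Path | None = None,
        ) -> SimulationTrace:
    """Run ``config.n_steps`` steps, sampling every ``record_every`` steps.

    The initial state and the final step are always recorded.  ``recorders``
    maps names to callables sampled on the same schedule; their outputs land
    in ``trace.extra``.  If ``out_dir`` is given, snapshots are also written
    as plain-text complex lists (see :func:`write_trace`).
    """
    state = initialize(network, config)
    trace = SimulationTrace(config=config, species_names=list(network.names))
    _record(trace, state, recorders)
    every = max(1, config.record_every)
    for k in range(config.n_steps):
        step(state)
        if (k + 1) % every == 0 or k + 1 == config.n_steps:
            _record(trace, state, recorders)
    trace.final_state = state
    if out_dir is not None:
        write_trace(trace, out_dir)
    return trace


def write_trace(trace: SimulationTrace, out_dir: str | Path) -> list[Path]:
    """Write one plain-text snapshot file per sample.

    Format: ``#`` header lines carrying the step number and the config,
    then one complex per line as tab-separated, lexicographically sorted
    species names.  Monomer lines have a single column.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    c = trace.config
    header = (f"#config L={c.L} occupancy={c.occupancy} p_on={c.p_on} "
              f"p_off={c.p_off} boundary={c.boundary} move_law={c.move_law} "
              f"visit_order={c.visit_order} seed={c.seed}")
    width = len(str(trace.snapshots[-1][0]))
    paths = []
    for step_no, comps in trace.snapshots:
        path = out_dir / f"snapshot_{step_no:0{width}d}.tsv"
        with path.open("w") as fh:
            fh.write(f"#step {step_no}\n{header}\n")
            for comp in sorted(comps, key=lambda c: (-len(c), sorted(c))):
                fh.write("\t".join(sorted(comp)) + "\n")
        paths.append(path)
    return paths
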