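"""Orchestration of the three pseudocell experiments.

* :func:`ssi_evolution_study` — SSI time series of replicate pseudocells
  evolved under a network of interest versus matched Erdős–Rényi controls.
* :func:`icsi_robustness_study` — pairwise ICSI between replicate pseudocells
  started from independent random initial configurations.
* :func:`topology_ssi_study` — families of tunable-transitivity networks,
  each simulated to equilibrium, yielding the observation table for the
  SSI ~ topology regression.

Two configuration profiles ship: ``desk_scale_config`` (a 12-lattice, 20000
steps) sized for interactive work and continuous testing, and
``full_scale_config`` (a 50-lattice, 150000 steps), the reference
full-scale setting, which takes hours of CPU per replicate.
"""

from __future__ import annotations

import dataclasses
import logging
import random
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import pandas as pd

from .generators import erdos_renyi, volz_network
from .network_io import InteractionNetwork
from .organization import inter_cell_similarity_index, ssi_timeseries
from .simulation import SimulationConfig, run
from .topology import topology_report

logger = logging.getLogger(__name__)

__all__ = [
    "desk_scale_config",
    "full_scale_config",
    "StudySpec",
    "ssi_evolution_study",
    "icsi_robustness_study",
    "topology_ssi_study",
    "equilibrium_ssi",
]


def desk_scale_config(**overrides) -> SimulationConfig:
    """Scaled-down profile: 12^3 lattice, 20% occupancy, 20000 steps."""
    base = dict(L=12, occupancy=0.20, p_on=0.7, p_off=0.002,
                n_steps=20000, record_every=500)
    base.update(overrides)
    return SimulationConfig(**base)


def full_scale_config(**overrides) -> SimulationConfig:
    """Reference full-scale profile: 50^3 lattice, 150000 steps."""
    base = dict(L=50, occupancy=0.20, p_on=0.7, p_off=0.002,
                n_steps=150000, record_every=1000)
    base.update(overrides)
    return SimulationConfig(**base)


def _replicate_seeds(master_seed: int, n: int) -> list[int]:
    rng = random.Random(master_seed)
    return [rng.randrange(2 ** 31) for _ in range(n)]


def equilibrium_ssi(trace, include_monomers: bool = False) -> float:
    """Mean SSI over the final 10% of recorded snapshots (at least one)."""
    series = ssi_timeseries(trace, include_monomers=include_monomers)
    k = max(1, len(series) // 10)
    return float(series["ssi"].tail(k).mean())


def ssi_evolution_study(network: InteractionNetwork, replicates: int = 10,
                        config: SimulationConfig | None = None,
                        seed: int = 0, control: bool = True) -> pd.DataFrame:
    """SSI time series for replicate pseudocells, with matched ER controls.

    Each replicate runs the full simulation from an independent random
    initial configuration.  The control condition uses a fresh Erdős–Rényi
    network per replicate with the same node and expected edge counts as
    ``network``.  Returns a tidy frame (condition, replicate, step,
    n_complexes, ssi).
    """
    config = config or desk_scale_config()
    seeds = _replicate_seeds(seed, 2 * replicates)
    frames = []
    for r in range(replicates):
        conditions = [("network", network)]
        if control:
            er = erdos_renyi(network.n_nodes, network.n_edges,
                             seed=seeds[replicates + r])
            conditions.append(("er_control", er))
        for label, net in conditions:
            cfg = dataclasses.replace(config, seed=seeds[r])
            trace = run(net, cfg)
            series = ssi_timeseries(trace)
            series.insert(0, "replicate", r)
            series.insert(0, "condition", label)
            frames.append(series)
            logger.info("ssi_evolution_study: %s replicate %d final SSI %.3f",
                        label, r, series["ssi"].iloc[-1])
    return pd.concat(frames, ignore_index=True)


def icsi_robustness_study(network: InteractionNetwork, replicates: int = 10,
                          config: SimulationConfig | None = None,
                          seed: int = 0, label: str = "network"
                          ) -> pd.DataFrame:
    """Pairwise ICSI between replicate pseudocells of one network.

    Runs ``replicates`` simulations from different random initial protein
    distributions and computes the ICSI between the final complex lists of
    every pair (``replicates`` choose 2 values).  Returns a long frame
    (condition, replicate_a, replicate_b, icsi) ready for boxplots.
    """
    config = config or desk_scale_config()
    seeds = _replicate_seeds(seed, replicates)
    cells = []
    for r in range(replicates):
        cfg = dataclasses.replace(config, seed=seeds[r])
        trace = run(network, cfg)
        cells.append(trace.final_compositions())
    rows = []
    for a, b in combinations(range(replicates), 2):
        if not cells[a] or not cells[b]:
            icsi = 0.0
            logger.warning("replicate %d or %d formed no complexes", a, b)
        else:
            icsi = inter_cell_similarity_index(cells[a], cells[b])
        rows.append((label, a, b, icsi))
    return pd.DataFrame(rows, columns=["condition", "replicate_a",
                                       "replicate_b", "icsi"])


@dataclass
class StudySpec:
    """Settings of a tunable-transitivity (Volz) family sweep.

    ``degree_sources`` maps a family label to the degree sequence its
    networks are grown from.  For every family, transitivity target and
    replicate, one network is generated, its realized topology measured and
    one pseudocell simulated to equilibrium.
    """

    degree_sources: dict[str, Sequence[int]]
    transitivity_grid: Sequence[float] = tuple(i / 10 for i in range(11))
    replicates: int = 1
    config: SimulationConfig = field(default_factory=desk_scale_config)
    seed: int = 0

    def __post_init__(self):
        if any(not (0.0 <= t <= 1.0) for t in self.transitivity_grid):
            raise ValueError("transitivity grid values must be in [0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def topology_ssi_study(spec: StudySpec) -> pd.DataFrame:
    """Observation table for the SSI ~ topology regression.

    One row per (family, transitivity target, replicate): the realized
    topology metrics of the generated network and the equilibrium SSI (mean
    over the final 10% of snapshots) of the pseudocell evolved under it.
    """
    n_cells = (len(spec.degree_sources) * len(spec.transitivity_grid)
               * spec.replicates)
    seeds = _replicate_seeds(spec.seed, 2 * n_cells)
    rows = []
    k = 0
    for family, degrees in spec.degree_sources.items():
        for t in spec.transitivity_grid:
            for r in range(spec.replicates):
                net = volz_network(degrees, t, seed=seeds[k])
                report = topology_report(net)
                cfg = dataclasses.replace(spec.config, seed=seeds[n_cells + k])
                trace = run(net, cfg)
                rows.append({
                    "family": family,
                    "target_transitivity": t,
                    "replicate": r,
                    "n_nodes": report.n_nodes,
                    "n_edges": report.n_edges,
                    "sffi": report.sffi,
                    "apl": report.apl,
                    "diameter": report.diameter,
                    "acc": report.acc,
                    "transitivity": report.transitivity,
                    "modularity": report.modularity,
                    "ssi": equilibrium_ssi(trace),
                })
                logger.info("topology_ssi_study: %s t=%.2f rep %d -> "
                            "transitivity %.3f, SSI %.3f", family, t, r,
                            report.transitivity, rows[-1]["ssi"])
                k += 1
    return pd.DataFrame(rows)
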