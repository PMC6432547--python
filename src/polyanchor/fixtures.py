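"""Deterministic hand-built micro-states with hand-enumerated expectations.

Each fixture is a tiny, fully explicit SimulationState on a 10x10 monolayer
whose zone memberships were enumerated by hand from the lattice geometry
(row r, column c sits at x = (c + (r mod 2)/2) d, y = r*sqrt(3)/2 d; odd rows
are offset by +d/2).  They drive the oracle-equivalence tests and give the
analysis code a known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .energy import PC, PS, PIP2
from .engine import SimulationConfig, SimulationState
from .lattice import LipidAssignment, build_lattice

ROOT3_2 = math.sqrt(3.0) / 2.0


@dataclass
class Fixture:
    name: str
    state: SimulationState
    config: SimulationConfig
    expected: dict = field(default_factory=dict)


def _site(lattice, row, col):
    return row * lattice.n_cols + col


def _assignment(lattice, placed):
    species = np.zeros(lattice.n_sites, dtype=np.int8)
    for (row, col), code in placed.items():
        species[_site(lattice, row, col)] = code
    return LipidAssignment.from_species(species)


def _one_chain_flat() -> Fixture:
    # straight 5-bead chain lying at z = d/2, beads at x = 2..6, y = 2*sqrt3/2
    # (the y of lattice row 2); lipids:
    #   PIP2 "A" at (row 2, col 3): x = 3.0, y = row-2 y  -> lateral distance 0
    #        => zones 1..8
    #   PIP2 "B" at (row 4, col 8): x = 8.0, y = 4*sqrt3/2 -> nearest bead
    #        (6, 2*sqrt3/2): dx = 2, dy = 2*sqrt3/2 = 1.732 => r = sqrt(7)
    #        = 2.646 => zones 3..8
    #   PS   "C" at (row 0, col 0): x = 0, y = 0 -> nearest bead (2, 1.732):
    #        r = sqrt(4 + 3) = sqrt(7) = 2.646 => zones 3..8
    lattice = build_lattice(10, 10)
    y0 = 2 * ROOT3_2
    chain = np.zeros((1, 5, 3))
    chain[0, :, 0] = np.arange(2.0, 7.0)
    chain[0, :, 1] = y0
    chain[0, :, 2] = 0.5
    assignment = _assignment(
        lattice, {(2, 3): PIP2, (4, 8): PIP2, (0, 0): PS}
    )
    config = SimulationConfig(
        n_chains=1, n_beads=5, n_rows=10, n_cols=10,
        steps_athermal=0, steps_equilibration=0, steps_production=0,
        n_replicas=1,
    )
    state = SimulationState(chain, lattice, assignment)
    lipid_order = {  # index within charged_sites (site-sorted)
        "C": 0,  # site 0
        "A": 1,  # site 23
        "B": 2,  # site 47
    }
    expected = {
        "lipid_order": lipid_order,
        "zone_members": {1: {"A"}, 2: {"A"}, 3: {"A", "B", "C"},
                         4: {"A", "B", "C"}},
        "min_lateral_distance": {"A": 0.0, "B": math.sqrt(7.0), "C": math.sqrt(7.0)},
        "anchored": True,
    }
    return Fixture("one_chain_flat", state, config, expected)


def _two_chain_overlap() -> Fixture:
    # two parallel 4-bead chains at z = d/2 (rows 2 and 5 in y), one PIP2
    # between them at (row 3, col 3): x = 3.5, y = 3*sqrt3/2.
    #   distance to chain 0 (y = 2*sqrt3/2, beads x = 2..5): dx = 0.5,
    #     dy = sqrt3/2 => r = 1 exactly            => zones 2.. of chain 0
    #   distance to chain 1 (y = 5*sqrt3/2): dx = 0.5, dy = 2*sqrt3/2
    #     => r = sqrt(0.25 + 3) = 1.803            => zones 2.. of chain 1
    # nearest-chain attribution: chain 0.
    # one PS far away at (row 8, col 8): x = 8, y = 8*sqrt3/2 = 6.93; with the
    # 10 x 8.66 periodic box its minimum-image distances stay > 3 to both
    # chains (nearest approach: to chain 1 beads via dy = 6.93-4.33 = 2.598,
    # dx = 3 => r = 3.97).
    lattice = build_lattice(10, 10)
    chains = np.zeros((2, 4, 3))
    chains[0, :, 0] = np.arange(2.0, 6.0)
    chains[0, :, 1] = 2 * ROOT3_2
    chains[0, :, 2] = 0.5
    chains[1, :, 0] = np.arange(2.0, 6.0)
    chains[1, :, 1] = 5 * ROOT3_2
    chains[1, :, 2] = 0.5
    assignment = _assignment(lattice, {(3, 3): PIP2, (8, 8): PS})
    config = SimulationConfig(
        n_chains=2, n_beads=4, n_rows=10, n_cols=10,
        steps_athermal=0, steps_equilibration=0, steps_production=0,
        n_replicas=1,
    )
    state = SimulationState(chains, lattice, assignment)
    expected = {
        "pip2_distance_chain0": 1.0,
        "pip2_distance_chain1": math.sqrt(0.25 + 3.0),
        "attribution": 0,
        "zone_members_chain0": {1: set(), 2: {"PIP2"}},
        "anchored": [0, 1],
    }
    return Fixture("two_chain_overlap", state, config, expected)


def _naked_monolayer() -> Fixture:
    lattice = build_lattice(10, 10)
    assignment = _assignment(lattice, {(1, 1): PIP2, (6, 4): PIP2, (3, 8): PS})
    config = SimulationConfig(
        n_chains=0, n_beads=2, n_rows=10, n_cols=10,
        steps_athermal=0, steps_equilibration=0, steps_production=0,
        n_replicas=1,
    )
    state = SimulationState(np.zeros((0, 2, 3)), lattice, assignment)
    expected = {"anchored": [], "total_energy_is_lipid_only": True}
    return Fixture("naked_monolayer", state, config, expected)


_REGISTRY = {
    "one_chain_flat": _one_chain_flat,
    "two_chain_overlap": _two_chain_overlap,
    "naked_monolayer": _naked_monolayer,
}


def fixture_names():
    return sorted(_REGISTRY)


def generate_fixture(name: str) -> Fixture:
    try:
        builder = _REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; available: {fixture_names()}"
        ) from None
    return builder()
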