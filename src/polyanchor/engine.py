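"""Metropolis engine: configuration, state, three-stage protocol, replicas.

The sampling protocol follows three stages:

1. athermal relaxation — all energies switched off; only the hard cores, the
   fixed bonds and the wall act, letting chains and lipids forget the initial
   configuration;
2. equilibration — full energy, nothing recorded;
3. production — full energy, a trajectory frame recorded every
   ``analysis_interval`` steps (the cadence at which all observables are
   defined).

All randomness flows from a single master seed through numpy SeedSequence
derivations, so identical configurations reproduce bit-identical
trajectories, and replicas are independent streams.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _kernel
from .energy import (
    PC,
    BendingParameters,
    PhysicalParameters,
    interaction_cutoff,
    total_energy,
)
from .lattice import (
    HexLattice,
    LipidAssignment,
    apply_kawasaki_swap,
    assign_composition,
    build_lattice,
)
from .chains import place_initial_chains, straight_chain

MOVE_NAMES = ("local", "crankshaft", "translate", "pivot", "kawasaki")

DEFAULT_COMPOSITION = {"PC": 98, "PS": 1, "PIP2": 1}


@dataclass
class SimulationConfig:
    """All physical and protocol parameters of one state point.

    Step counts default to the full protocol (1e6 athermal, 2e6 equilibration,
    2e6 production, 20 replicas); ``scale_factor`` divides all three step
    counts uniformly for desk-scale runs.  ``n_rows = n_cols = 0`` selects the
    bulk single-chain mode (no monolayer, no wall), used for persistence
    length measurements.
    """

    composition: dict = field(default_factory=lambda: dict(DEFAULT_COMPOSITION))
    n_chains: int = 2
    n_beads: int = 20
    rigidity: float = 0.0
    salt_concentration: float = 0.01
    steps_athermal: int = 1_000_000
    steps_equilibration: int = 2_000_000
    steps_production: int = 2_000_000
    analysis_interval: int = 50
    n_replicas: int = 20
    seed: int = 0
    n_rows: int = 50
    n_cols: int = 50
    translation_halfwidth: float = 0.5
    anchor_height: float = 2.0
    n_zones: int = 8
    scale_factor: int = 1
    bjerrum_length: float = 7.14
    segment_diameter: float = 8.66
    cutoff_debye_lengths: float = 6.0
    resync_every: int = 1000

    def __post_init__(self):
        if self.n_beads < 2:
            raise ValueError("chains need at least 2 segments")
        if self.n_chains < 0 or self.n_replicas < 1:
            raise ValueError("n_chains must be >= 0 and n_replicas >= 1")
        if self.rigidity < 0:
            raise ValueError(f"rigidity must be >= 0, got {self.rigidity}")
        if min(self.steps_athermal, self.steps_equilibration, self.steps_production) < 0:
            raise ValueError("step counts must be >= 0")
        if self.scale_factor < 1:
            raise ValueError("scale_factor must be >= 1")
        if self.analysis_interval < 1:
            raise ValueError("analysis_interval must be >= 1")
        if (self.n_rows == 0) != (self.n_cols == 0):
            raise ValueError("n_rows and n_cols must both be 0 (bulk) or both > 0")
        prod = self.steps_production // self.scale_factor
        if prod % self.analysis_interval:
            raise ValueError(
                f"analysis_interval ({self.analysis_interval}) must divide the "
                f"effective production length ({prod})"
            )

    @property
    def has_monolayer(self) -> bool:
        return self.n_rows > 0

    @property
    def physical_parameters(self) -> PhysicalParameters:
        return PhysicalParameters(
            bjerrum_length=self.bjerrum_length,
            segment_diameter=self.segment_diameter,
            salt_concentration=self.salt_concentration,
            cutoff_debye_lengths=self.cutoff_debye_lengths,
        )

    @property
    def bending_parameters(self) -> BendingParameters:
        return BendingParameters(rigidity=self.rigidity)

    def effective_steps(self) -> tuple:
        s = self.scale_factor
        return (
            self.steps_athermal // s,
            self.steps_equilibration // s,
            self.steps_production // s,
        )

    @property
    def polymer_concentration(self) -> float:
        """C_p = N_c / A_m in units of d^-2 (nan in bulk mode)."""
        if not self.has_monolayer:
            return math.nan
        area = self.n_rows * self.n_cols * math.sqrt(3.0) / 2.0
        return self.n_chains / area


@dataclass
class SimulationState:
    """Chain coordinates + lipid assignment + cached energy."""

    chain_positions: np.ndarray           # (n_chains, n_beads, 3), units of d
    lattice: HexLattice | None
    assignment: LipidAssignment | None
    cached_energy: float = 0.0
    step_counter: int = 0

    @property
    def box(self):
        return None if self.lattice is None else self.lattice.box

    @property
    def periodic(self) -> bool:
        return self.lattice is not None

    def kernel_arrays(self):
        """Views/arrays in the layout the numba kernel expects."""
        if self.assignment is not None:
            a = self.assignment
            species = a.species
            charged_sites = a.charged_sites
            site_lipid = a.site_lipid
            site_xy = self.lattice.site_positions
            neighbors = self.lattice.neighbors
            bx, by = self.lattice.box
        else:
            species = np.zeros(0, dtype=np.int8)
            charged_sites = np.zeros(0, dtype=np.int32)
            site_lipid = np.zeros(0, dtype=np.int32)
            site_xy = np.zeros((0, 2))
            neighbors = np.zeros((0, 6), dtype=np.int32)
            bx = by = 0.0
        return species, site_xy, neighbors, charged_sites, site_lipid, bx, by

    @classmethod
    def initialize(cls, config: SimulationConfig, rng_lattice, rng_chains):
        if config.has_monolayer:
            lattice = build_lattice(config.n_rows, config.n_cols)
            assignment = assign_composition(lattice, config.composition, rng_lattice)
            chains = (
                place_initial_chains(
                    config.n_chains, config.n_beads, lattice.box, rng_chains,
                    height=2.0,
                )
                if config.n_chains
                else np.zeros((0, config.n_beads, 3))
            )
        else:
            lattice = None
            assignment = None
            chains = np.stack(
                [
                    straight_chain(config.n_beads, [0.0, 0.0, 3.0 * c], [1, 0, 0])
                    for c in range(config.n_chains)
                ]
            ) if config.n_chains else np.zeros((0, config.n_beads, 3))
        state = cls(chains, lattice, assignment)
        state.cached_energy = total_energy(
            state, config.physical_parameters, config.bending_parameters
        )
        return state


# --------------------------------------------------------------------------
# move descriptors (reference path used by energy.delta_energy and tests)
# --------------------------------------------------------------------------


@dataclass
class ChainMove:
    """A proposed set of coordinates for one chain."""

    chain_id: int
    new_positions: np.ndarray

    def apply(self, state: SimulationState) -> None:
        state.chain_positions[self.chain_id] = self.new_positions


@dataclass
class KawasakiMove:
    """A proposed species exchange of two lattice sites."""

    site_a: int
    site_b: int

    def apply(self, state: SimulationState) -> None:
        apply_kawasaki_swap(state.assignment, self.site_a, self.site_b)


def metropolis_accept(delta_u: float, rng) -> bool:
    """Accept with probability min(1, exp(-delta_u)); +inf always rejected."""
    if math.isinf(delta_u) and delta_u > 0:
        return False
    if delta_u <= 0.0:
        return True
    return rng.random() < math.exp(-delta_u)


# --------------------------------------------------------------------------
# kernel driver
# --------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Frames recorded every ``analysis_interval`` production steps."""

    step_index: np.ndarray       # (F,)
    positions: np.ndarray        # (F, n_chains, n_beads, 3)
    species: np.ndarray          # (F, n_sites) int8
    lipid_sites: np.ndarray      # (F, n_charged) int32
    charged_species: np.ndarray  # (n_charged,) int8
    energy: np.ndarray           # (F,)
    site_xy: np.ndarray          # (n_sites, 2)
    box: tuple | None
    analysis_interval: int
    segment_diameter: float = 8.66

    @property
    def n_frames(self) -> int:
        return len(self.step_index)

    def lipid_positions(self, frame: int) -> np.ndarray:
        """(n_charged, 2) lateral positions of the tracked charged lipids."""
        return self.site_xy[self.lipid_sites[frame]]


def run_segment(
    state: SimulationState,
    config: SimulationConfig,
    n_steps: int,
    seed: int,
    *,
    electrostatics_on: bool = True,
    bending_on: bool = True,
    record_every: int = 0,
    static_charges: np.ndarray | None = None,
    wall: bool | None = None,
):
    """Advance ``state`` in place by ``n_steps`` MC steps.

    Returns (frames dict or None, counters dict, max_energy_drift).
    ``static_charges`` is an optional (n, 4) array of immobile test charges
    (x, y, z, Z) used by micro-system validation runs.
    """
    params = config.physical_parameters
    species, site_xy, neighbors, charged_sites, site_lipid, bx, by = (
        state.kernel_arrays()
    )
    periodic = state.periodic
    if wall is None:
        wall = state.periodic
    if static_charges is None or len(static_charges) == 0:
        static_xyz = np.zeros((0, 3))
        static_val = np.zeros(0)
    else:
        static_charges = np.asarray(static_charges, dtype=float)
        static_xyz = np.ascontiguousarray(static_charges[:, :3])
        static_val = np.ascontiguousarray(static_charges[:, 3])
    box = state.box
    rcut = interaction_cutoff(params, box)
    if math.isinf(rcut):
        rcut = 1e30
    n_frames = n_steps // record_every if record_every > 0 else 0
    n_chains, n_beads = state.chain_positions.shape[:2]
    rec_pos = np.empty((n_frames, n_chains, n_beads, 3))
    rec_species = np.empty((n_frames, len(species)), dtype=np.int8)
    rec_lipid_sites = np.empty((n_frames, len(charged_sites)), dtype=np.int32)
    rec_energy = np.empty(n_frames)
    attempts = np.zeros(5, dtype=np.int64)
    accepts = np.zeros(5, dtype=np.int64)

    n_rec, max_drift, energy = _kernel.advance(
        state.chain_positions, species, site_xy, neighbors, charged_sites,
        site_lipid, static_xyz, static_val,
        float(bx), float(by), periodic, bool(wall),
        params.bjerrum_reduced, params.inverse_debye_reduced, float(rcut),
        float(config.rigidity),
        bool(electrostatics_on), bool(bending_on),
        float(config.translation_halfwidth),
        int(n_steps), int(record_every), int(config.resync_every),
        int(seed) & 0x7FFFFFFF,
        rec_pos, rec_species, rec_lipid_sites, rec_energy,
        attempts, accepts,
    )
    state.cached_energy = energy
    state.step_counter += n_steps
    counters = {
        name: {"attempted": int(attempts[i]), "accepted": int(accepts[i])}
        for i, name in enumerate(MOVE_NAMES)
    }
    frames = None
    if record_every > 0:
        frames = {
            "positions": rec_pos[:n_rec],
            "species": rec_species[:n_rec],
            "lipid_sites": rec_lipid_sites[:n_rec],
            "energy": rec_energy[:n_rec],
        }
    return frames, counters, max_drift


def mc_step(state: SimulationState, config: SimulationConfig, seed: int):
    """One MC step (all per-step move attempts); returns acceptance counters."""
    _, counters, _ = run_segment(state, config, 1, seed)
    return counters


def derive_seeds(master_seed: int, replica: int, n: int = 8) -> np.ndarray:
    """Independent 31-bit seed streams per replica via SeedSequence."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(replica,))
    return ss.generate_state(n) & 0x7FFFFFFF


def run_protocol(config: SimulationConfig, replica: int = 0):
    """Execute athermal -> equilibration -> production; return a Trajectory
    and a run manifest dictionary."""
    seeds = derive_seeds(config.seed, replica)
    rng_lattice = np.random.default_rng(int(seeds[0]))
    rng_chains = np.random.default_rng(int(seeds[1]))
    state = SimulationState.initialize(config, rng_lattice, rng_chains)
    n_ath, n_eq, n_prod = config.effective_steps()

    from . import __version__

    manifest = {
        "config": config_to_dict(config),
        "version": __version__,
        "replica": replica,
        "master_seed": config.seed,
        "stage_seeds": [int(s) for s in seeds[2:5]],
        "effective_steps": [n_ath, n_eq, n_prod],
        "polymer_concentration": config.polymer_concentration,
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    t0 = time.perf_counter()
    if n_ath:
        _, counters, _ = run_segment(
            state, config, n_ath, int(seeds[2]),
            electrostatics_on=False, bending_on=False,
        )
        manifest["stages"]["athermal"] = {
            "steps": n_ath, "acceptance": counters,
            "seconds": round(time.perf_counter() - t0, 3),
        }
        # energies were switched off; refresh the cache for the next stage
        state.cached_energy = total_energy(
            state, config.physical_parameters, config.bending_parameters
        )
    t0 = time.perf_counter()
    if n_eq:
        _, counters, drift = run_segment(state, config, n_eq, int(seeds[3]))
        manifest["stages"]["equilibration"] = {
            "steps": n_eq, "acceptance": counters, "max_energy_drift": drift,
            "seconds": round(time.perf_counter() - t0, 3),
        }

    # production: the pre-production state is frame 0, then one frame per
    # analysis interval
    interval = config.analysis_interval
    species0, site_xy, _, charged_sites0, _, _, _ = state.kernel_arrays()
    first = {
        "positions": state.chain_positions.copy()[None],
        "species": species0.copy()[None],
        "lipid_sites": charged_sites0.copy()[None],
        "energy": np.array([state.cached_energy]),
    }
    t0 = time.perf_counter()
    if n_prod:
        frames, counters, drift = run_segment(
            state, config, n_prod, int(seeds[4]), record_every=interval
        )
        manifest["stages"]["production"] = {
            "steps": n_prod, "acceptance": counters, "max_energy_drift": drift,
            "seconds": round(time.perf_counter() - t0, 3),
        }
        stacked = {
            key: np.concatenate([first[key], frames[key]]) for key in first
        }
        steps = np.arange(0, n_prod + 1, interval, dtype=np.int64)
    else:
        stacked = first
        steps = np.zeros(1, dtype=np.int64)

    charged_species = (
        state.assignment.charged_species.copy()
        if state.assignment is not None
        else np.zeros(0, dtype=np.int8)
    )
    traj = Trajectory(
        step_index=steps,
        positions=stacked["positions"],
        species=stacked["species"],
        lipid_sites=stacked["lipid_sites"],
        charged_species=charged_species,
        energy=stacked["energy"],
        site_xy=site_xy.copy(),
        box=state.box,
        analysis_interval=interval,
        segment_diameter=config.segment_diameter,
    )
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    return traj, manifest


def run_replicas(config: SimulationConfig, n_replicas: int | None = None):
    """Independent replicas r = 0..n-1 with seeds derived from the master seed.

    Returns (list of Trajectory, list of manifests)."""
    n = config.n_replicas if n_replicas is None else n_replicas
    if n < 1:
        raise ValueError("n_replicas must be >= 1")
    out, manifests = [], []
    for r in range(n):
        traj, man = run_protocol(config, replica=r)
        out.append(traj)
        manifests.append(man)
    return out, manifests


def simulate_free_chain(
    rigidity: float,
    salt_concentration: float,
    seed: int,
    *,
    n_beads: int = 20,
    steps_equilibration: int = 100_000,
    steps_production: int = 400_000,
    sample_every: int = 100,
) -> np.ndarray:
    """Bulk single-chain run (no monolayer, no wall) for persistence length.

    Returns sampled conformations, shape (n_samples, n_beads, 3).
    """
    config = SimulationConfig(
        n_chains=1,
        n_beads=n_beads,
        rigidity=rigidity,
        salt_concentration=salt_concentration,
        n_rows=0,
        n_cols=0,
        steps_athermal=0,
        steps_equilibration=steps_equilibration,
        steps_production=steps_production,
        analysis_interval=sample_every,
        seed=seed,
        n_replicas=1,
    )
    traj, _ = run_protocol(config)
    return traj.positions[:, 0]


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
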