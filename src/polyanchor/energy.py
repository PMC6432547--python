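"""Energy model: Debye-Hückel electrostatics, hard cores, harmonic bending.

The system is a set of point charges: cationic polymer segments (valence +1,
one charge at each segment center) and anionic lipid headgroups on a plane
(PS -1, PIP2 -4; PC is neutral and never enters electrostatic sums).  Charges
interact through the screened Coulomb (Debye-Hückel) pair potential

    u(r) = Z_m Z_n l_B exp(-kappa_D r) / r   [k_B T]

with l_B the Bjerrum length and kappa_D the inverse Debye screening length set
by the 1:1 salt concentration.  Polymer segments are hard spheres of diameter
d; chain stiffness enters through a harmonic bending term
kappa * sum_i (alpha_i - pi)^2 over interior vertex angles.

Internally all lengths are expressed in units of the segment diameter d and
all energies in k_B T.  The public functions below accept lengths in Angstrom
where documented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import constants

# species codes used throughout the package
PC, PS, PIP2 = 0, 1, 2
SPECIES_NAMES = {PC: "PC", PS: "PS", PIP2: "PIP2"}
SPECIES_CODES = {v: k for k, v in SPECIES_NAMES.items()}
#: headgroup valences indexed by species code
SPECIES_VALENCE = np.array([0.0, -1.0, -4.0])
#: valence of one polymer segment
SEGMENT_VALENCE = 1.0

DEFAULT_BJERRUM = 7.14   # Angstrom, aqueous solution
DEFAULT_DIAMETER = 8.66  # Angstrom, segment and headgroup diameter
REFERENCE_TEMPERATURE = 298.15  # K, used in the Debye-length evaluation


@dataclass(frozen=True)
class PhysicalParameters:
    """Physical constants and solution conditions for one run.

    Lengths in Angstrom, concentration in mol/L.  ``dielectric_membrane`` is
    recorded for completeness but unused: all pair interactions are evaluated
    with the solution dielectric (equivalently, with ``bjerrum_length`` as
    given), since every charge sits at or above the monolayer plane.
    """

    bjerrum_length: float = DEFAULT_BJERRUM
    segment_diameter: float = DEFAULT_DIAMETER
    dielectric_solution: float = 78.5
    dielectric_membrane: float = 2.0
    salt_concentration: float = 0.01
    salt_valence: int = 1
    temperature: float = REFERENCE_TEMPERATURE
    #: electrostatic cutoff, in multiples of the Debye length
    cutoff_debye_lengths: float = 6.0

    def __post_init__(self):
        if self.bjerrum_length <= 0:
            raise ValueError("bjerrum_length must be positive")
        if self.segment_diameter <= 0:
            raise ValueError("segment_diameter must be positive")
        if self.salt_concentration < 0:
            raise ValueError(
                f"salt_concentration must be >= 0, got {self.salt_concentration}"
            )
        if self.dielectric_solution <= 0:
            raise ValueError("dielectric_solution must be positive")

    @property
    def inverse_debye_length(self) -> float:
        """kappa_D in 1/Angstrom (cached via compute_inverse_debye_length)."""
        return compute_inverse_debye_length(self)

    @property
    def debye_length(self) -> float:
        """Debye screening length in Angstrom (inf at zero salt)."""
        kd = self.inverse_debye_length
        return math.inf if kd == 0.0 else 1.0 / kd

    # reduced (units-of-d) quantities used by the simulation kernel
    @property
    def bjerrum_reduced(self) -> float:
        return self.bjerrum_length / self.segment_diameter

    @property
    def inverse_debye_reduced(self) -> float:
        return self.inverse_debye_length * self.segment_diameter


def compute_inverse_debye_length(params: PhysicalParameters) -> float:
    """Inverse Debye screening length kappa_D in 1/Angstrom.

    kappa_D = sqrt(1000 e^2 N_A sum_i Z_i^2 C_i / (eps_0 eps_r k_B T)) for a
    symmetric univalent electrolyte, where sum_i Z_i^2 C_i = 2 Z^2 C.  Returns
    0 at zero salt (unscreened Coulomb limit).  For 1:1 salt in water at
    298 K this reproduces the standard rule 1/kappa_D = 3.04 Angstrom / sqrt(C[M]).
    """
    c = params.salt_concentration
    if c < 0:
        raise ValueError(f"salt_concentration must be >= 0, got {c}")
    if c == 0.0:
        return 0.0
    z = params.salt_valence
    ionic = 2.0 * z * z * c  # mol/L, both ion species
    num = 1000.0 * constants.e**2 * constants.N_A * ionic
    den = (
        constants.epsilon_0
        * params.dielectric_solution
        * constants.k
        * params.temperature
    )
    return math.sqrt(num / den) * 1e-10  # 1/m -> 1/Angstrom


def pair_electrostatic_energy(
    z_m: float, z_n: float, r_mn: float, params: PhysicalParameters
) -> float:
    """Screened Coulomb energy of one unordered charge pair, in k_B T.

    ``r_mn`` in Angstrom.  The 1/2 prefactor of the double-sum form of the
    total electrostatic energy belongs to the sum over ordered pairs; this
    function returns the full term counted once per unordered pair.
    """
    if r_mn <= 0:
        raise ValueError(f"pair distance must be positive, got {r_mn}")
    kd = params.inverse_debye_length
    return z_m * z_n * params.bjerrum_length * math.exp(-kd * r_mn) / r_mn


@dataclass(frozen=True)
class BendingParameters:
    """Harmonic bending stiffness: U = rigidity * sum (alpha_i - rest_angle)^2.

    ``rigidity`` (kappa) is dimensionless (energy in k_B T per squared radian);
    rigidity == 0 recovers the freely-jointed chain.  ``rest_angle`` is the
    straight vertex angle pi.
    """

    rigidity: float = 0.0
    rest_angle: float = math.pi

    def __post_init__(self):
        if self.rigidity < 0:
            raise ValueError(f"rigidity must be >= 0, got {self.rigidity}")


def bending_energy(chain_angles, bend: BendingParameters) -> float:
    """Bending energy kappa * sum (alpha_i - alpha_0)^2 over interior angles.

    ``chain_angles`` are the vertex angles alpha_2..alpha_{N-1} in radians,
    each in [0, pi] (pi = straight).
    """
    angles = np.asarray(chain_angles, dtype=float)
    if angles.size and (
        angles.min() < -1e-9 or angles.max() > math.pi + 1e-9
    ):
        raise ValueError("vertex angles must lie in [0, pi]")
    if bend.rigidity == 0.0:
        return 0.0
    return float(bend.rigidity * np.sum((angles - bend.rest_angle) ** 2))


# ---------------------------------------------------------------------------
# state-level energies (vectorized reference implementations)
#
# These operate on SimulationState-like objects exposing
#   .chain_positions  (n_chains, N, 3) float, units of d
#   .lattice          HexLattice or None
#   .assignment       LipidAssignment or None
# and are the ground truth the incremental kernel bookkeeping is checked
# against.  They use the same minimum-image convention and cutoff as the
# kernel so that cached and recomputed energies agree exactly.
# ---------------------------------------------------------------------------


def interaction_cutoff(params: PhysicalParameters, box=None) -> float:
    """Reduced-units pair cutoff: cutoff_debye_lengths Debye lengths, capped
    at half the smaller box dimension when periodic."""
    kd = params.inverse_debye_reduced
    rcut = math.inf if kd == 0.0 else params.cutoff_debye_lengths / kd
    if box is not None:
        rcut = min(rcut, 0.5 * min(box))
    return rcut


def _gather_charges(state):
    """All charged sites of a state as (positions (n,3), valences (n,))."""
    pos = []
    val = []
    chains = np.asarray(state.chain_positions, dtype=float)
    if chains.size:
        flat = chains.reshape(-1, 3)
        pos.append(flat)
        val.append(np.full(len(flat), SEGMENT_VALENCE))
    if state.assignment is not None:
        species = state.assignment.species
        charged = np.nonzero(species != PC)[0]
        if charged.size:
            xy = state.lattice.site_positions[charged]
            pos.append(np.column_stack([xy, np.zeros(len(charged))]))
            val.append(SPECIES_VALENCE[species[charged]])
    if not pos:
        return np.zeros((0, 3)), np.zeros(0)
    return np.concatenate(pos), np.concatenate(val)


def _pairwise_distances(positions, box):
    delta = positions[:, None, :] - positions[None, :, :]
    if box is not None:
        for axis, length in enumerate(box):
            delta[..., axis] -= length * np.round(delta[..., axis] / length)
    return np.sqrt((delta**2).sum(axis=-1))


def hard_core_overlap(state, tol: float = 1e-9) -> bool:
    """True iff any two non-bonded segments overlap (r < d) or a segment
    violates the wall constraint z >= d/2 (when a monolayer is present)."""
    chains = np.asarray(state.chain_positions, dtype=float)
    if chains.size == 0:
        return False
    n_chains, n_beads = chains.shape[:2]
    box = state.box
    if state.lattice is not None and chains[..., 2].min() < 0.5 - tol:
        return True
    flat = chains.reshape(-1, 3)
    dist = _pairwise_distances(flat, box)
    bonded = np.zeros_like(dist, dtype=bool)
    idx = np.arange(len(flat))
    same_chain = (idx[:, None] // n_beads) == (idx[None, :] // n_beads)
    adjacent = np.abs(idx[:, None] - idx[None, :]) <= 1
    bonded = same_chain & adjacent  # includes self-pairs
    overlap = (dist < 1.0 - tol) & ~bonded
    return bool(overlap.any())


def total_energy(state, params: PhysicalParameters, bend: BendingParameters) -> float:
    """Total potential energy in k_B T: screened electrostatics over all
    unordered charged pairs (PC skipped, bonded pairs included) plus bending
    over all chains.  Infinite for states with hard-core overlap."""
    if hard_core_overlap(state):
        return math.inf
    from .chains import compute_bond_angles  # local import avoids a cycle

    pos, val = _gather_charges(state)
    energy = 0.0
    if len(pos) > 1:
        lb = params.bjerrum_reduced
        kd = params.inverse_debye_reduced
        rcut = interaction_cutoff(params, state.box)
        dist = _pairwise_distances(pos, state.box)
        iu = np.triu_indices(len(pos), k=1)
        r = dist[iu]
        zz = val[iu[0]] * val[iu[1]]
        mask = (r < rcut) & (zz != 0.0)
        energy += float(np.sum(zz[mask] * lb * np.exp(-kd * r[mask]) / r[mask]))
    chains = np.asarray(state.chain_positions, dtype=float)
    if bend.rigidity > 0.0:
        for chain in chains:
            if len(chain) >= 3:
                energy += bending_energy(compute_bond_angles(chain), bend)
    return energy


def delta_energy(state, move, params: PhysicalParameters, bend: BendingParameters):
    """Energy difference of a proposed move, by explicit before/after totals.

    ``move`` is either a ``ChainMove`` (chain_id + full proposed coordinates)
    or a ``KawasakiMove`` (two site indices whose species are exchanged).
    This reference path recomputes both totals; the simulation kernel keeps
    an equivalent incremental version that must agree with it.
    """
    import copy

    before = total_energy(state, params, bend)
    trial = copy.deepcopy(state)
    move.apply(trial)
    after = total_energy(trial, params, bend)
    if math.isinf(after):
        return math.inf
    if math.isinf(before):
        raise ValueError("delta_energy called on an overlapping state")
    return after - before
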