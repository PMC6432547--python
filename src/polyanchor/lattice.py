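"""Hexagonally close-packed, x/y-periodic lipid monolayer at z = 0.

The monolayer is a row-offset hexagonal lattice of headgroup disks of
diameter d (lattice constant d, so neighboring disks touch).  Site (r, c)
sits at x = (c + (r mod 2)/2) d, y = r (sqrt(3)/2) d; periodic wrapping in x
and y requires an even number of rows.  Lipid species live on the sites and
move by Kawasaki nearest-neighbor exchange, which conserves composition
exactly.  All lengths here are in units of d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .energy import PC, PS, PIP2, SPECIES_CODES, SPECIES_NAMES

ROOT3_2 = math.sqrt(3.0) / 2.0


@dataclass(frozen=True)
class HexLattice:
    n_rows: int
    n_cols: int
    spacing: float  # lattice constant in units of d (1.0 for touching disks)
    site_positions: np.ndarray = field(repr=False)  # (n_sites, 2)
    neighbors: np.ndarray = field(repr=False)       # (n_sites, 6) int32

    @property
    def n_sites(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def box_x(self) -> float:
        return self.n_cols * self.spacing

    @property
    def box_y(self) -> float:
        return self.n_rows * ROOT3_2 * self.spacing

    @property
    def box(self):
        return (self.box_x, self.box_y)

    @property
    def monolayer_area(self) -> float:
        """A_m in units of d^2 (n_rows * n_cols * sqrt(3)/2 * spacing^2)."""
        return self.box_x * self.box_y


def build_lattice(n_rows: int = 50, n_cols: int = 50, spacing: float = 1.0) -> HexLattice:
    """Build the periodic hexagonal monolayer lattice.

    Both dimensions must be even so the row-offset packing tiles periodically;
    every site then has exactly 6 nearest neighbors at center distance
    ``spacing``.
    """
    if n_rows <= 0 or n_cols <= 0:
        raise ValueError("lattice dimensions must be positive")
    if n_rows % 2 or n_cols % 2:
        raise ValueError(
            f"lattice dimensions must be even for periodic hexagonal packing, "
            f"got {n_rows}x{n_cols}"
        )
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    rows = np.arange(n_rows)
    cols = np.arange(n_cols)
    cc, rr = np.meshgrid(cols, rows)  # site index = r * n_cols + c
    x = (cc + 0.5 * (rr % 2)) * spacing
    y = rr * ROOT3_2 * spacing
    site_positions = np.column_stack([x.ravel(), y.ravel()]).astype(float)

    neighbors = np.empty((n_rows * n_cols, 6), dtype=np.int32)
    for r in range(n_rows):
        off = 0 if r % 2 else -1  # column shift toward adjacent rows
        for c in range(n_cols):
            s = r * n_cols + c
            rm, rp = (r - 1) % n_rows, (r + 1) % n_rows
            cm, cp = (c - 1) % n_cols, (c + 1) % n_cols
            c2 = (c + off) % n_cols
            c3 = (c + off + 1) % n_cols
            neighbors[s] = (
                r * n_cols + cm,
                r * n_cols + cp,
                rm * n_cols + c2,
                rm * n_cols + c3,
                rp * n_cols + c2,
                rp * n_cols + c3,
            )
    return HexLattice(n_rows, n_cols, spacing, site_positions, neighbors)


@dataclass
class LipidAssignment:
    """Species-per-site map plus identity tracking of the charged lipids.

    ``charged_sites[i]`` is the current site index of charged lipid i (PS or
    PIP2); ``charged_species[i]`` its species code.  ``site_lipid`` is the
    inverse map (-1 on PC sites).  Kawasaki exchanges update the maps but
    never the per-species counts.
    """

    species: np.ndarray           # (n_sites,) int8
    charged_sites: np.ndarray     # (n_charged,) int32
    charged_species: np.ndarray   # (n_charged,) int8
    site_lipid: np.ndarray        # (n_sites,) int32

    @property
    def counts(self) -> dict:
        return {
            name: int(np.sum(self.species == code))
            for code, name in SPECIES_NAMES.items()
        }

    @classmethod
    def from_species(cls, species: np.ndarray) -> "LipidAssignment":
        species = np.asarray(species, dtype=np.int8)
        charged_sites = np.nonzero(species != PC)[0].astype(np.int32)
        charged_species = species[charged_sites]
        site_lipid = np.full(len(species), -1, dtype=np.int32)
        site_lipid[charged_sites] = np.arange(len(charged_sites), dtype=np.int32)
        return cls(species, charged_sites, charged_species, site_lipid)


def composition_counts(composition: dict, n_sites: int) -> dict:
    """Exact integer species counts by the largest-remainder rule."""
    names = list(composition)
    ratios = np.array([composition[n] for n in names], dtype=float)
    if (ratios < 0).any():
        raise ValueError(f"composition ratios must be non-negative: {composition}")
    total = ratios.sum()
    if total <= 0:
        raise ValueError("composition ratios sum to zero")
    ideal = ratios / total * n_sites
    base = np.floor(ideal).astype(int)
    short = n_sites - base.sum()
    order = np.argsort(-(ideal - base), kind="stable")
    for i in order[:short]:
        base[i] += 1
    counts = {name: int(c) for name, c in zip(names, base)}
    for name in SPECIES_NAMES.values():
        counts.setdefault(name, 0)
    return counts


def assign_composition(lattice: HexLattice, composition: dict, seed) -> LipidAssignment:
    """Place the species uniformly at random at exact integer counts.

    ``composition`` maps species names (PC/PS/PIP2) to ratios summing to 100
    (or 1); ``seed`` may be an int or a numpy Generator.
    """
    unknown = set(composition) - set(SPECIES_NAMES.values())
    if unknown:
        raise ValueError(f"unknown species in composition: {sorted(unknown)}")
    counts = composition_counts(composition, lattice.n_sites)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    species = np.empty(lattice.n_sites, dtype=np.int8)
    pool = []
    for name, code in SPECIES_CODES.items():
        pool.extend([code] * counts[name])
    species[:] = pool
    rng.shuffle(species)
    return LipidAssignment.from_species(species)


def propose_kawasaki_move(assignment: LipidAssignment, lattice: HexLattice, rng):
    """One Kawasaki proposal: a uniformly random charged lipid and a uniformly
    random one of its 6 nearest-neighbor sites; the move is a species swap."""
    if len(assignment.charged_sites) == 0:
        raise ValueError("no charged lipids to move")
    i = rng.integers(len(assignment.charged_sites))
    site_a = int(assignment.charged_sites[i])
    site_b = int(lattice.neighbors[site_a, rng.integers(6)])
    return site_a, site_b


def apply_kawasaki_swap(assignment: LipidAssignment, site_a: int, site_b: int) -> None:
    """Exchange the species of two sites, updating lipid identities.

    A swap of two same-species sites leaves the state unchanged (identical
    particles are not relabelled).
    """
    sa, sb = assignment.species[site_a], assignment.species[site_b]
    if sa == sb:
        return
    la, lb_ = assignment.site_lipid[site_a], assignment.site_lipid[site_b]
    assignment.species[site_a], assignment.species[site_b] = sb, sa
    assignment.site_lipid[site_a], assignment.site_lipid[site_b] = lb_, la
    if la >= 0:
        assignment.charged_sites[la] = site_b
    if lb_ >= 0:
        assignment.charged_sites[lb_] = site_a
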