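"""Freely-jointed / semiflexible cationic chains and their trial moves.

A chain is N ordered segment centers (units of d) with every bond fixed at
length d exactly; each segment carries a +1 charge.  Conformations are
sampled with four move families, all of which preserve the bond constraint
by construction and are self-inverse in proposal density (detailed balance):

* kink-jump      - rotate one interior segment about the axis through its
                   two neighbors (chain ends instead re-draw their position
                   uniformly on the sphere around their single neighbor);
* crankshaft     - rigidly rotate an interior sub-chain about the axis
                   through its two boundary segments;
* pivot          - rigidly rotate one tail of the chain about a segment;
* translation    - rigid displacement of the whole chain.

Functions here are pure: they take a positions array and return the proposed
one; constraint checking and Metropolis acceptance live in the engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass
class PolymerChain:
    """Coordinates (N, 3) of one cationic chain; every segment has valence +1."""

    positions: np.ndarray
    chain_id: int = 0


def compute_bond_angles(positions) -> np.ndarray:
    """Vertex angles alpha_i at the interior segments, in [0, pi].

    alpha_i is the angle between the bonds (i-1 -> i) and (i -> i+1) measured
    at vertex i; alpha = pi for a locally straight chain.
    """
    p = np.asarray(positions, dtype=float)
    if len(p) < 3:
        return np.zeros(0)
    v1 = p[:-2] - p[1:-1]
    v2 = p[2:] - p[1:-1]
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    if (n1 < 1e-12).any() or (n2 < 1e-12).any():
        raise ValueError("degenerate (zero-length) bond")
    cosine = np.clip((v1 * v2).sum(axis=1) / (n1 * n2), -1.0, 1.0)
    return np.arccos(cosine)


def rotation_matrix(axis, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (not necessarily unit) axis."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise ValueError("rotation axis must be non-zero")
    x, y, z = axis / norm
    c, s = math.cos(angle), math.sin(angle)
    omc = 1.0 - c
    return np.array(
        [
            [c + x * x * omc, x * y * omc - z * s, x * z * omc + y * s],
            [y * x * omc + z * s, c + y * y * omc, y * z * omc - x * s],
            [z * x * omc - y * s, z * y * omc + x * s, c + z * z * omc],
        ]
    )


def random_unit_vector(rng) -> np.ndarray:
    """Uniform random direction (Marsaglia)."""
    while True:
        a = 2.0 * rng.random(2) - 1.0
        s = a[0] ** 2 + a[1] ** 2
        if s < 1.0:
            root = 2.0 * math.sqrt(1.0 - s)
            return np.array([a[0] * root, a[1] * root, 1.0 - 2.0 * s])


def kink_jump(positions, segment_index: int, angle: float, rng=None) -> np.ndarray:
    """Rotate one segment about the axis through its two bonded neighbors.

    For an end segment the move degenerates to an end-rotation: the segment is
    re-drawn uniformly on the unit sphere around its single neighbor (requires
    ``rng``).  Both adjacent bond lengths are preserved exactly.
    """
    p = np.asarray(positions, dtype=float).copy()
    n = len(p)
    i = segment_index
    if i in (0, n - 1):
        if rng is None:
            raise ValueError("end-rotation requires an rng")
        j = 1 if i == 0 else n - 2
        bond = np.linalg.norm(p[i] - p[j])
        p[i] = p[j] + bond * random_unit_vector(rng)
        return p
    axis = p[i + 1] - p[i - 1]
    rot = rotation_matrix(axis, angle)
    p[i] = p[i - 1] + rot @ (p[i] - p[i - 1])
    return p


def crankshaft(positions, i: int, j: int, angle: float, rng=None) -> np.ndarray:
    """Rigidly rotate segments i+1..j-1 about the axis through segments i and j."""
    p = np.asarray(positions, dtype=float).copy()
    if not (0 <= i < j < len(p)) or j - i < 2:
        raise ValueError(f"crankshaft needs 0 <= i < j with j - i >= 2, got {i}, {j}")
    axis = p[j] - p[i]
    if np.linalg.norm(axis) < 1e-12:
        return p  # degenerate axis: rotation undefined but also a no-op choice
    rot = rotation_matrix(axis, angle)
    block = p[i + 1 : j] - p[i]
    p[i + 1 : j] = block @ rot.T + p[i]
    return p


def pivot(positions, i: int, rotation: np.ndarray, side: str = "tail") -> np.ndarray:
    """Rigidly rotate one side of the chain about segment i.

    ``rotation`` is a 3x3 rotation matrix; ``side`` selects segments i+1..N-1
    ("tail") or 0..i-1 ("head").
    """
    p = np.asarray(positions, dtype=float).copy()
    if side == "tail":
        sel = slice(i + 1, len(p))
    elif side == "head":
        sel = slice(0, i)
    else:
        raise ValueError("side must be 'tail' or 'head'")
    block = p[sel] - p[i]
    p[sel] = block @ np.asarray(rotation).T + p[i]
    return p


def translate(positions, displacement) -> np.ndarray:
    """Rigid whole-chain translation (periodic wrapping is applied by the
    engine when distances are evaluated, not to the stored coordinates)."""
    return np.asarray(positions, dtype=float) + np.asarray(displacement, dtype=float)


def straight_chain(n_beads: int, start, direction) -> np.ndarray:
    """A straight rod of n_beads unit bonds from ``start`` along ``direction``."""
    start = np.asarray(start, dtype=float)
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    return start[None, :] + np.arange(n_beads)[:, None] * u[None, :]


def place_initial_chains(
    n_chains: int, n_beads: int, box, rng, height: float = 2.0, max_tries: int = 10000
) -> np.ndarray:
    """Initial conformations: straight rods parallel to the plane at z=height,
    at random (x, y) and in-plane orientation, mutually non-overlapping under
    the periodic box."""
    bx, by = box
    chains = np.empty((n_chains, n_beads, 3))
    placed = 0
    for _ in range(max_tries):
        theta = rng.uniform(0.0, 2.0 * math.pi)
        origin = np.array([rng.uniform(0, bx), rng.uniform(0, by), height])
        cand = straight_chain(
            n_beads, origin, [math.cos(theta), math.sin(theta), 0.0]
        )
        ok = True
        for c in range(placed):
            delta = cand[:, None, :] - chains[c][None, :, :]
            delta[..., 0] -= bx * np.round(delta[..., 0] / bx)
            delta[..., 1] -= by * np.round(delta[..., 1] / by)
            if (np.sqrt((delta**2).sum(-1)) < 1.0).any():
                ok = False
                break
        if ok:
            chains[placed] = cand
            placed += 1
            if placed == n_chains:
                return chains
    raise RuntimeError(
        f"could not place {n_chains} non-overlapping chains in box {box}"
    )
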