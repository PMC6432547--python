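"""Analysis statistics of the anchored-polymer/monolayer complex.

Implements the full observable suite evaluated at the 50-step analysis
cadence: nested interaction-zone sequestration (phi_s, M_s), lateral radial
distribution functions, the anchored-segment height distribution, interval
mean-square displacements of chain centers of mass, lipid micro-domains and
single sequestered lipids, and the persistence length from the bond-angle
correlation function.

Conventions, applied uniformly:

* a chain is *anchored* in a frame iff at least one segment center is below
  ``anchor_height_threshold`` (default 2 d) above the plane;
* zone k of an anchored chain is the union of lateral disks of radius k*d
  around its segment centers (minimum-image lateral distances), recomputed
  from the conformation in each frame, so zones are nested in k;
* a lipid is *sequestered* in zone k for the interval between two consecutive
  frames iff it lies inside that zone at both bounding frames; when zones of
  several chains overlap, the lipid is attributed to the chain whose nearest
  segment is closest (phi uses union membership and is unaffected).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .energy import PS, PIP2, SPECIES_NAMES
from .engine import Trajectory

ANION_SPECIES = (PIP2, PS)


@dataclass(frozen=True)
class ZoneSpec:
    """Nested interaction zones of radii k*d, k = 1..n_zones."""

    n_zones: int = 8
    anchor_height_threshold: float = 2.0

    @property
    def zone_radii(self) -> np.ndarray:
        return np.arange(1, self.n_zones + 1, dtype=float)


def anchored_chain_ids(frame_positions: np.ndarray, spec: ZoneSpec) -> np.ndarray:
    """Indices of chains with any segment below the anchoring threshold."""
    z = np.asarray(frame_positions)[..., 2]
    return np.nonzero(z.min(axis=-1) < spec.anchor_height_threshold)[0]


def _min_lateral_distances(lipid_xy, chain_xy, box):
    """(n_lipids,) minimum over segments of the minimum-image lateral
    distance from each lipid to the chain."""
    delta = lipid_xy[:, None, :] - chain_xy[None, :, :2]
    bx, by = box
    delta[..., 0] -= bx * np.round(delta[..., 0] / bx)
    delta[..., 1] -= by * np.round(delta[..., 1] / by)
    return np.sqrt((delta**2).sum(-1)).min(axis=1)


def zone_membership(
    traj: Trajectory, frame: int, chain_id: int, k: float, spec: ZoneSpec | None = None
) -> np.ndarray:
    """Charged-lipid indices inside zone k of one chain at one frame."""
    lipid_xy = traj.lipid_positions(frame)
    dmin = _min_lateral_distances(lipid_xy, traj.positions[frame, chain_id], traj.box)
    return np.nonzero(dmin < k)[0]


def _interval_tables(traj: Trajectory, spec: ZoneSpec, f: int):
    """Per-interval sequestration bookkeeping between frames f and f+1.

    Returns (anchored chain ids, min-distance tables d0/d1 of shape
    (n_lipids, n_anchored), nearest-chain attribution (n_lipids,)) or None if
    no chain is anchored at both frames.
    """
    a0 = set(anchored_chain_ids(traj.positions[f], spec).tolist())
    a1 = set(anchored_chain_ids(traj.positions[f + 1], spec).tolist())
    anchored = sorted(a0 & a1)
    if not anchored:
        return None
    xy0 = traj.lipid_positions(f)
    xy1 = traj.lipid_positions(f + 1)
    d0 = np.column_stack(
        [_min_lateral_distances(xy0, traj.positions[f, c], traj.box) for c in anchored]
    )
    d1 = np.column_stack(
        [_min_lateral_distances(xy1, traj.positions[f + 1, c], traj.box) for c in anchored]
    )
    attribution = d0.argmin(axis=1)
    return anchored, d0, d1, attribution


@dataclass
class SequestrationResult:
    """phi_s(k) and M_s(k) per species, averaged over analysis intervals."""

    zone_radii: np.ndarray
    phi: dict                      # species name -> (n_zones,) fractions
    counts_per_chain: dict         # species name -> (n_zones,) M_s
    n_intervals: int
    n_intervals_anchored: int
    species_totals: dict = field(default_factory=dict)


def sequestration_stats(traj: Trajectory, spec: ZoneSpec | None = None) -> SequestrationResult:
    """Fraction phi_s(k) of each anionic species sequestered in zone k over
    all anchored chains, and count M_s(k) per anchored chain.

    A lipid counts for an interval iff it is inside the zone at both bounding
    frames; phi uses union membership over chains, M uses nearest-chain
    attribution.  Intervals with no anchored chain contribute zero
    sequestration to phi and are excluded from the M average.
    """
    spec = spec or ZoneSpec()
    if traj.n_frames < 2:
        raise ValueError("sequestration needs at least 2 frames")
    radii = spec.zone_radii
    totals = {
        SPECIES_NAMES[s]: int(np.sum(traj.charged_species == s)) for s in ANION_SPECIES
    }
    phi_acc = {s: np.zeros(spec.n_zones) for s in ANION_SPECIES}
    m_acc = {s: np.zeros(spec.n_zones) for s in ANION_SPECIES}
    n_int = traj.n_frames - 1
    n_anch = 0
    for f in range(n_int):
        tables = _interval_tables(traj, spec, f)
        if tables is None:
            continue
        anchored, d0, d1, attribution = tables
        n_anch += 1
        worst = np.maximum(d0, d1)  # in-zone k iff worst < k
        for si, s in enumerate(ANION_SPECIES):
            mask = traj.charged_species == s
            if not mask.any():
                continue
            w = worst[mask]
            in_any = w.min(axis=1)[:, None] < radii[None, :]   # union over chains
            at_attr = w[np.arange(len(w)), attribution[mask]][:, None] < radii[None, :]
            phi_acc[s] += in_any.sum(axis=0)
            m_acc[s] += at_attr.sum(axis=0) / len(anchored)
    if n_anch == 0:
        warnings.warn("no anchored chains in any interval; phi_s = M_s = 0")
    phi = {
        SPECIES_NAMES[s]: (
            phi_acc[s] / (totals[SPECIES_NAMES[s]] * n_int)
            if totals[SPECIES_NAMES[s]]
            else np.full(spec.n_zones, np.nan)
        )
        for s in ANION_SPECIES
    }
    m = {
        SPECIES_NAMES[s]: (m_acc[s] / n_anch if n_anch else np.zeros(spec.n_zones))
        for s in ANION_SPECIES
    }
    return SequestrationResult(radii, phi, m, n_int, n_anch, totals)


# --------------------------------------------------------------------------
# radial distribution functions
# --------------------------------------------------------------------------


@dataclass
class RDFResult:
    species_pair: tuple
    bin_edges: np.ndarray
    g: np.ndarray
    n_frames: int

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def peak_position(self, r_max: float = 10.0) -> float:
        """Bin-center location of the global maximum of g(r) for r < r_max."""
        sel = self.r_centers < r_max
        if not sel.any():
            raise ValueError("no bins below r_max")
        return float(self.r_centers[sel][self.g[sel].argmax()])


def radial_distribution(
    traj: Trajectory,
    species_a: str,
    species_b: str,
    bin_width: float = 0.25,
    r_max: float | None = None,
) -> RDFResult:
    """Lateral 2D pair correlation g(r) between two lipid species.

    Normalized so a uniformly random arrangement gives g = 1; for the
    like-species case the ideal-gas density uses N-1 (the pair density seen
    from one particle).
    """
    from .energy import SPECIES_CODES

    code_a, code_b = SPECIES_CODES[species_a], SPECIES_CODES[species_b]
    bx, by = traj.box
    area = bx * by
    if r_max is None:
        r_max = 0.5 * min(bx, by)
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    hist = np.zeros(len(edges) - 1)
    ideal = np.zeros(len(edges) - 1)
    annulus = math.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    for f in range(traj.n_frames):
        species = traj.species[f]
        pa = traj.site_xy[species == code_a]
        pb = traj.site_xy[species == code_b]
        if len(pa) == 0 or len(pb) == 0:
            raise ValueError(
                f"species {species_a if len(pa) == 0 else species_b} absent from frame {f}"
            )
        delta = pa[:, None, :] - pb[None, :, :]
        delta[..., 0] -= bx * np.round(delta[..., 0] / bx)
        delta[..., 1] -= by * np.round(delta[..., 1] / by)
        r = np.sqrt((delta**2).sum(-1))
        if code_a == code_b:
            iu = np.triu_indices(len(pa), k=1)
            r = r[iu]
            n_pairs_ideal = len(pa) * (len(pa) - 1) / 2.0
        else:
            r = r.ravel()
            n_pairs_ideal = float(len(pa) * len(pb))
        hist += np.histogram(r, bins=edges)[0]
        ideal += n_pairs_ideal * annulus / area
    g = np.divide(hist, ideal, out=np.zeros_like(hist), where=ideal > 0)
    return RDFResult((species_a, species_b), edges, g, traj.n_frames)


# --------------------------------------------------------------------------
# anchored-segment height distribution
# --------------------------------------------------------------------------


@dataclass
class SegmentHeightDistribution:
    bin_edges: np.ndarray
    density: np.ndarray  # per-anchored-chain number density vs height
    n_anchored_frames: int

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def segment_height_distribution(
    traj: Trajectory,
    spec: ZoneSpec | None = None,
    bin_width: float = 0.2,
    z_max: float | None = None,
) -> SegmentHeightDistribution:
    """Histogram of segment-center heights of the anchored chains, normalized
    per anchored chain so the density integrates to the mean number of
    segments per anchored chain."""
    spec = spec or ZoneSpec()
    n_beads = traj.positions.shape[2]
    if z_max is None:
        z_max = n_beads + 1.0
    edges = np.arange(0.0, z_max + bin_width, bin_width)
    hist = np.zeros(len(edges) - 1)
    n_anchored = 0
    for f in range(traj.n_frames):
        ids = anchored_chain_ids(traj.positions[f], spec)
        for c in ids:
            hist += np.histogram(traj.positions[f, c, :, 2], bins=edges)[0]
        n_anchored += len(ids)
    if n_anchored == 0:
        warnings.warn("no anchored chains; empty height distribution")
        return SegmentHeightDistribution(edges, hist, 0)
    return SegmentHeightDistribution(edges, hist / (n_anchored * bin_width), n_anchored)


# --------------------------------------------------------------------------
# interval mean-square displacements
# --------------------------------------------------------------------------


@dataclass
class MobilityResult:
    """Interval MSDs, in d^2 per analysis interval.

    ``m_pc`` averages squared COM displacements (x, y, z) of chains anchored
    at both interval ends.  ``m_d[species][k]`` is the squared displacement of
    the micro-domain COM (the species-s lipids sequestered in zone k of one
    chain); ``m_l[species][k]`` the mean squared displacement of the single
    sequestered lipids (lateral components).  Intervals/zones with empty
    micro-domains are skipped, not counted as zero.
    """

    zone_radii: np.ndarray
    m_pc: float
    m_d: dict
    m_l: dict
    n_intervals: int
    m_pc_samples: int = 0


def _min_image_delta(delta, box):
    bx, by = box
    delta = delta.copy()
    delta[..., 0] -= bx * np.round(delta[..., 0] / bx)
    delta[..., 1] -= by * np.round(delta[..., 1] / by)
    return delta


def mobility_msd(traj: Trajectory, spec: ZoneSpec | None = None) -> MobilityResult:
    spec = spec or ZoneSpec()
    if traj.n_frames < 2:
        raise ValueError("MSDs need at least 2 frames")
    radii = spec.zone_radii
    nz = spec.n_zones
    pc_acc, pc_n = 0.0, 0
    d_acc = {s: np.zeros(nz) for s in ANION_SPECIES}
    d_n = {s: np.zeros(nz, dtype=int) for s in ANION_SPECIES}
    l_acc = {s: np.zeros(nz) for s in ANION_SPECIES}
    l_n = {s: np.zeros(nz, dtype=int) for s in ANION_SPECIES}
    for f in range(traj.n_frames - 1):
        tables = _interval_tables(traj, spec, f)
        # chain COM displacements (all three components; lateral min-image)
        if tables is not None:
            anchored, d0, d1, attribution = tables
            for c in anchored:
                dpos = traj.positions[f + 1, c] - traj.positions[f, c]
                dpos[:, :2] = _min_image_delta(dpos[:, :2], traj.box)
                com = dpos.mean(axis=0)
                pc_acc += float((com**2).sum())
                pc_n += 1
            # lipid displacements (lateral)
            dxy = _min_image_delta(
                traj.lipid_positions(f + 1) - traj.lipid_positions(f), traj.box
            )
            worst = np.maximum(d0, d1)
            for s in ANION_SPECIES:
                smask = traj.charged_species == s
                if not smask.any():
                    continue
                for ci in range(len(anchored)):
                    members = smask & (attribution == ci)
                    if not members.any():
                        continue
                    w = worst[members, ci]
                    disp = dxy[members]
                    for k in range(nz):
                        sel = w < radii[k]
                        if not sel.any():
                            continue
                        d_vec = disp[sel].mean(axis=0)
                        d_acc[s][k] += float((d_vec**2).sum())
                        d_n[s][k] += 1
                        l_acc[s][k] += float((disp[sel] ** 2).sum(axis=1).mean())
                        l_n[s][k] += 1
    def _avg(acc, n):
        return {
            SPECIES_NAMES[s]: np.divide(
                acc[s], n[s], out=np.full(nz, np.nan), where=n[s] > 0
            )
            for s in ANION_SPECIES
        }

    return MobilityResult(
        zone_radii=radii,
        m_pc=pc_acc / pc_n if pc_n else math.nan,
        m_d=_avg(d_acc, d_n),
        m_l=_avg(l_acc, l_n),
        n_intervals=traj.n_frames - 1,
        m_pc_samples=pc_n,
    )


# --------------------------------------------------------------------------
# persistence length from the bond-angle correlation function
# --------------------------------------------------------------------------


@dataclass
class PersistenceLengthResult:
    separations: np.ndarray   # contour separations D_C in bonds (j = 0..)
    bac: np.ndarray           # BAC(j) = <u_i . u_{i+j}>
    n_samples: np.ndarray     # bond-pair count per separation
    lp: float                 # persistence length, Angstrom (inf: no decay)
    lp_bonds: float           # same in bond-length units
    lp_stderr: float          # fit standard error, Angstrom
    fit_window: tuple         # (j_min, j_max) used in the fit


def bond_angle_correlation(
    conformations: np.ndarray,
    segment_diameter: float = 8.66,
    bac_floor: float = 0.2,
) -> PersistenceLengthResult:
    """BAC(D_C) = <u_i . u_{i+D_C}> and the persistence length from its
    exponential decay.

    ``conformations`` has shape (n_conf, n_beads, 3) or (n_conf, n_chains,
    n_beads, 3).  The decay BAC ~ exp(-j/L_p) is a proportionality, so the
    fit is a weighted least-squares line (slope + free amplitude) on
    ln BAC(j) over the window j = 1..j_max where BAC stays above
    ``bac_floor`` (weights: pair count x BAC^2, the delta-method inverse
    variance of ln BAC); the free amplitude absorbs the non-exponential
    single-bond drop that discrete charged chains show at j = 1.  A
    non-decaying BAC (rigid rod) reports lp = inf.
    """
    conf = np.asarray(conformations, dtype=float)
    if conf.ndim == 3:
        conf = conf[:, None, :, :]
    n_conf, n_chains, n_beads = conf.shape[:3]
    if n_beads < 3:
        raise ValueError("persistence length needs chains of >= 3 segments")
    bonds = np.diff(conf, axis=2)
    bonds /= np.linalg.norm(bonds, axis=-1, keepdims=True)
    n_bonds = n_beads - 1
    bac = np.zeros(n_bonds)
    n_samples = np.zeros(n_bonds, dtype=np.int64)
    for j in range(n_bonds):
        dots = (bonds[:, :, : n_bonds - j] * bonds[:, :, j:]).sum(-1)
        bac[j] = dots.mean()
        n_samples[j] = dots.size
    seps = np.arange(n_bonds)

    j_max = 1
    while j_max < n_bonds - 1 and bac[j_max + 1] > bac_floor:
        j_max += 1
    window = np.arange(1, j_max + 1)
    window = window[bac[window] > 0]
    if len(window) == 0:
        warnings.warn("BAC non-positive at the first separation; lp undefined")
        return PersistenceLengthResult(
            seps, bac, n_samples, math.nan, math.nan, math.nan, (1, 1)
        )
    y = np.log(bac[window])
    w = n_samples[window] * bac[window] ** 2
    x = window.astype(float)
    if len(window) == 1:
        slope = float(y[0] / x[0])  # single usable point: line through origin
        resid = np.zeros(1)
        sxx = float(w[0] * x[0] ** 2)
    else:
        wsum = w.sum()
        xbar = float((w * x).sum() / wsum)
        ybar = float((w * y).sum() / wsum)
        sxx = float((w * (x - xbar) ** 2).sum())
        slope = float((w * (x - xbar) * (y - ybar)).sum() / sxx)
        resid = y - ybar - slope * (x - xbar)
    if slope >= 0.0:
        return PersistenceLengthResult(
            seps, bac, n_samples, math.inf, math.inf, math.nan,
            (1, int(window[-1])),
        )
    lp_bonds = -1.0 / slope
    dof = max(len(window) - 2, 1)
    var_slope = float((w * resid**2).sum() / (dof * sxx))
    stderr_bonds = math.sqrt(var_slope) / slope**2
    return PersistenceLengthResult(
        seps, bac, n_samples,
        lp_bonds * segment_diameter, lp_bonds, stderr_bonds * segment_diameter,
        (1, int(window[-1])),
    )


def persistence_length_from_trajectory(
    traj: Trajectory, bac_floor: float = 0.2
) -> PersistenceLengthResult:
    return bond_angle_correlation(
        traj.positions, segment_diameter=traj.segment_diameter, bac_floor=bac_floor
    )


# --------------------------------------------------------------------------
# replica aggregation
# --------------------------------------------------------------------------


def replica_mean_se(values) -> tuple:
    """Mean and standard error across replicas (nan-aware, axis 0)."""
    arr = np.asarray(values, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(arr, axis=0)
        n = np.sum(~np.isnan(arr), axis=0)
        se = np.nanstd(arr, axis=0, ddof=1) / np.sqrt(np.maximum(n, 1))
    return mean, se


def aggregate_sequestration(results) -> dict:
    """Replica means and standard errors of phi_s(k) and M_s(k)."""
    out = {}
    for s in ANION_SPECIES:
        name = SPECIES_NAMES[s]
        phi_mean, phi_se = replica_mean_se([r.phi[name] for r in results])
        m_mean, m_se = replica_mean_se([r.counts_per_chain[name] for r in results])
        out[name] = {
            "phi_mean": phi_mean, "phi_se": phi_se,
            "M_mean": m_mean, "M_se": m_se,
        }
    out["zone_radii"] = results[0].zone_radii
    return out


def aggregate_rdf(results) -> dict:
    g_mean, g_se = replica_mean_se([r.g for r in results])
    return {
        "r_centers": results[0].r_centers,
        "bin_edges": results[0].bin_edges,
        "g_mean": g_mean,
        "g_se": g_se,
        "species_pair": results[0].species_pair,
    }


def rdf_peak_position(aggregated: dict, r_max: float = 10.0) -> float:
    """Peak location of a replica-averaged RDF over r < r_max."""
    r = aggregated["r_centers"]
    sel = r < r_max
    return float(r[sel][aggregated["g_mean"][sel].argmax()])
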