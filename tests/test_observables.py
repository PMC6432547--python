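"""Observable tests against hand enumerations and brute-force oracles."""

import math

import numpy as np
import pytest

from polyanchor.energy import PC, PS, PIP2
from polyanchor.engine import Trajectory
from polyanchor.fixtures import generate_fixture
from polyanchor import observables as obs

ROOT3_2 = math.sqrt(3.0) / 2.0


def make_traj(frames_pos, lipid_xy_frames, lipid_species, box=(20.0, 20.0),
              interval=50):
    """Hand-built trajectory: explicit chain coordinates per frame and
    explicit lateral lipid positions per frame (each lipid gets its own
    fabricated 'site')."""
    frames_pos = np.asarray(frames_pos, dtype=float)
    lipid_xy = np.asarray(lipid_xy_frames, dtype=float)  # (F, n_lipids, 2)
    n_frames, n_lipids = lipid_xy.shape[:2]
    # fabricate one site per (frame, lipid) so positions are free-form
    site_xy = lipid_xy.reshape(-1, 2)
    lipid_sites = np.arange(n_frames * n_lipids, dtype=np.int32).reshape(
        n_frames, n_lipids
    )
    species = np.zeros((n_frames, len(site_xy)), dtype=np.int8)
    for f in range(n_frames):
        species[f, lipid_sites[f]] = lipid_species
    return Trajectory(
        step_index=np.arange(n_frames, dtype=np.int64) * interval,
        positions=frames_pos,
        species=species,
        lipid_sites=lipid_sites,
        charged_species=np.asarray(lipid_species, dtype=np.int8),
        energy=np.zeros(n_frames),
        site_xy=site_xy,
        box=box,
        analysis_interval=interval,
    )


def fixture_traj(fx, n_frames=2):
    """A frozen trajectory replicating a fixture state."""
    st = fx.state
    return Trajectory(
        step_index=np.arange(n_frames, dtype=np.int64) * 50,
        positions=np.repeat(st.chain_positions[None], n_frames, axis=0),
        species=np.repeat(st.assignment.species[None], n_frames, axis=0),
        lipid_sites=np.repeat(st.assignment.charged_sites[None], n_frames, axis=0),
        charged_species=st.assignment.charged_species,
        energy=np.zeros(n_frames),
        site_xy=st.lattice.site_positions,
        box=st.lattice.box,
        analysis_interval=50,
    )


class TestAnchoring:
    def test_high_chain_not_anchored(self):
        pos = np.zeros((1, 5, 3))
        pos[0, :, 2] = 10.0
        assert len(obs.anchored_chain_ids(pos, obs.ZoneSpec())) == 0

    def test_touching_chain_anchored(self):
        pos = np.full((1, 5, 3), 5.0)
        pos[0, 2, 2] = 0.5
        assert list(obs.anchored_chain_ids(pos, obs.ZoneSpec())) == [0]

    def test_threshold_sweep_matches_segment_scan(self, rng):
        pos = rng.uniform(0.5, 6.0, size=(4, 6, 3))
        for thr in (0.7, 1.5, 2.0, 4.0):
            spec = obs.ZoneSpec(anchor_height_threshold=thr)
            expected = [
                c for c in range(4)
                if any(pos[c, i, 2] < thr for i in range(6))
            ]
            assert list(obs.anchored_chain_ids(pos, spec)) == expected


class TestZoneMembership:
    def test_one_chain_flat_hand_enumeration(self):
        fx = generate_fixture("one_chain_flat")
        traj = fixture_traj(fx)
        order = fx.expected["lipid_order"]
        for k, names in fx.expected["zone_members"].items():
            got = set(obs.zone_membership(traj, 0, 0, k))
            assert got == {order[n] for n in names}, f"zone {k}"

    def test_matches_per_segment_disk_union_oracle(self, rng):
        fx = generate_fixture("two_chain_overlap")
        traj = fixture_traj(fx)
        bx, by = traj.box
        for chain_id in (0, 1):
            for k in (1, 2, 3):
                members = set(obs.zone_membership(traj, 0, chain_id, k))
                oracle = set()
                for li, site in enumerate(traj.lipid_sites[0]):
                    x, y = traj.site_xy[site]
                    for seg in traj.positions[0, chain_id]:
                        dx = x - seg[0]
                        dy = y - seg[1]
                        dx -= bx * round(dx / bx)
                        dy -= by * round(dy / by)
                        if math.hypot(dx, dy) < k:
                            oracle.add(li)
                            break
                assert members == oracle

    def test_nested_zones(self):
        fx = generate_fixture("one_chain_flat")
        traj = fixture_traj(fx)
        prev = set()
        for k in range(1, 9):
            cur = set(obs.zone_membership(traj, 0, 0, k))
            assert prev <= cur
            prev = cur


class TestSequestration:
    def test_all_lipids_inside_zone_give_unit_fraction(self):
        # one anchored 2-bead chain, two PIP2 always within zone 3
        chain = np.zeros((3, 1, 2, 3))
        chain[..., 0, 0] = 5.0
        chain[..., 1, 0] = 6.0
        chain[..., 2] = 0.5
        chain[..., 1] = 5.0
        lipids = np.tile(np.array([[[5.5, 5.5], [6.5, 6.0]]]), (3, 1, 1))
        traj = make_traj(chain, lipids, [PIP2, PIP2])
        res = obs.sequestration_stats(traj)
        assert res.phi["PIP2"][2] == 1.0          # zone 3
        assert res.counts_per_chain["PIP2"][2] == 2.0
        assert np.isnan(res.phi["PS"]).all()      # species absent

    def test_leaving_lipid_not_sequestered(self):
        chain = np.zeros((2, 1, 2, 3))
        chain[..., 0, 0] = 5.0
        chain[..., 1, 0] = 6.0
        chain[..., 1] = 5.0
        chain[..., 2] = 0.5
        lipids = np.array([[[5.0, 5.0]], [[5.0, 14.0]]])  # in zone 1, then far
        traj = make_traj(chain, lipids, [PIP2])
        res = obs.sequestration_stats(traj)
        assert res.phi["PIP2"].sum() == 0.0

    def test_hand_enumerated_three_frame_fixture(self):
        """3 frames, 2 chains, 5 lipids; counts enumerated by hand.

        Chains: A is two beads at (5,5) and (6,5); B two beads at (15,5) and
        (16,5); both at z=0.5 in all frames.  Box 20x20.
        Lipids (PIP2 x3, PS x2) with per-frame lateral positions chosen so:
          L0 stays at (5,5):      zone 1 of A in every interval
          L1 at (7.5,5) -> dist 1.5 from A: zones >= 2 both intervals
          L2 hops (15,6)->(15,6)->(2,2): zone >=2 of B interval 1 only
          L3 (PS) at (10.5,5): dist 4.5 from both chains -> zones >= 5
             (attributed to A, nearest by 4.5 vs 4.5 tie -> argmin picks A)
          L4 (PS) far at (10,15): no zone (distance > 8)
        """
        chains = np.zeros((3, 2, 2, 3))
        chains[:, 0, 0, :2] = (5.0, 5.0)
        chains[:, 0, 1, :2] = (6.0, 5.0)
        chains[:, 1, 0, :2] = (15.0, 5.0)
        chains[:, 1, 1, :2] = (16.0, 5.0)
        chains[..., 2] = 0.5
        lip = np.array(
            [
                [[5.0, 5.0], [7.5, 5.0], [15.0, 6.0], [10.5, 5.0], [10.0, 15.0]],
                [[5.0, 5.0], [7.5, 5.0], [15.0, 6.0], [10.5, 5.0], [10.0, 15.0]],
                [[5.0, 5.0], [7.5, 5.0], [2.0, 2.0], [10.5, 5.0], [10.0, 15.0]],
            ]
        )
        traj = make_traj(chains, lip, [PIP2, PIP2, PIP2, PS, PS])
        res = obs.sequestration_stats(traj)
        # phi_PIP2: zone1: only L0, both intervals -> 1/3
        assert res.phi["PIP2"][0] == pytest.approx(1 / 3)
        # zone2: L0, L1 both intervals; L2 first interval only -> (3 + 2)/(3*2)
        assert res.phi["PIP2"][1] == pytest.approx((3 + 2) / 6)
        # zone5..8: PS L3 in both intervals -> 1/2; zone4: none
        assert res.phi["PS"][3] == 0.0
        assert res.phi["PS"][4] == pytest.approx(0.5)
        # M per anchored chain (2 anchored): zone2 interval1: L0,L1 (A) + L2
        # (B) = 3 lipids / 2 chains; interval2: 2 lipids / 2 chains
        assert res.counts_per_chain["PIP2"][1] == pytest.approx(
            (3 / 2 + 2 / 2) / 2
        )

    def test_no_anchored_chains_warns_and_zeroes(self):
        chain = np.full((2, 1, 2, 3), 10.0)
        chain[:, 0, 1, 0] = 11.0
        lipids = np.tile(np.array([[[5.0, 5.0]]]), (2, 1, 1))
        traj = make_traj(chain, lipids, [PIP2])
        with pytest.warns(UserWarning, match="no anchored"):
            res = obs.sequestration_stats(traj)
        assert res.phi["PIP2"].sum() == 0.0

    def test_monotone_in_zone_index(self, run_flexible_lowcp):
        _, trajs, _ = run_flexible_lowcp
        res = obs.sequestration_stats(trajs[0])
        for name in ("PIP2", "PS"):
            assert (np.diff(res.phi[name]) >= -1e-12).all()
            assert (np.diff(res.counts_per_chain[name]) >= -1e-12).all()


class TestRDF:
    def test_uniform_random_points_give_unit_g(self, rng):
        # continuum-uniform positions: g(r) = 1 within sampling error
        n, box = 150, (30.0, 30.0)
        frames = 40
        xy = rng.uniform(0, 30.0, size=(frames, n, 2))
        chains = np.zeros((frames, 1, 2, 3))
        chains[..., 1, 0] = 1.0
        chains[..., 2] = 10.0
        traj = make_traj(chains, xy, [PIP2] * n, box=box)
        res = obs.radial_distribution(traj, "PIP2", "PIP2", bin_width=0.5)
        sel = res.r_centers > 1.0
        counts_ideal = (
            frames * n * (n - 1) / 2
            * math.pi * (res.bin_edges[1:] ** 2 - res.bin_edges[:-1] ** 2)
            / (box[0] * box[1])
        )
        sigma = 1.0 / np.sqrt(counts_ideal)
        assert (np.abs(res.g[sel] - 1.0) < 4 * sigma[sel]).all()

    def test_fixed_pair_occupies_single_bin(self):
        chains = np.zeros((2, 1, 2, 3))
        chains[..., 1, 0] = 1.0
        chains[..., 2] = 10.0
        xy = np.tile(np.array([[[5.0, 5.0], [8.0, 5.0]]]), (2, 1, 1))
        traj = make_traj(chains, xy, [PIP2, PIP2])
        res = obs.radial_distribution(traj, "PIP2", "PIP2", bin_width=0.25)
        occupied = np.nonzero(res.g > 0)[0]
        assert len(occupied) == 1
        assert res.r_centers[occupied[0]] == pytest.approx(3.125)
        assert res.peak_position() == pytest.approx(3.125)

    def test_matches_double_loop_oracle(self):
        fx = generate_fixture("naked_monolayer")
        traj = fixture_traj(fx, n_frames=3)
        res = obs.radial_distribution(traj, "PIP2", "PIP2", bin_width=0.5)
        # brute force over all frames and ordered pairs
        bx, by = traj.box
        hist = np.zeros(len(res.bin_edges) - 1)
        npip = 0
        for f in range(3):
            sites = np.nonzero(traj.species[f] == PIP2)[0]
            npip = len(sites)
            for a in range(len(sites)):
                for b in range(a + 1, len(sites)):
                    dx = traj.site_xy[sites[a], 0] - traj.site_xy[sites[b], 0]
                    dy = traj.site_xy[sites[a], 1] - traj.site_xy[sites[b], 1]
                    dx -= bx * round(dx / bx)
                    dy -= by * round(dy / by)
                    r = math.hypot(dx, dy)
                    idx = int(r / 0.5)
                    if idx < len(hist):
                        hist[idx] += 1
        annulus = math.pi * (res.bin_edges[1:] ** 2 - res.bin_edges[:-1] ** 2)
        ideal = 3 * npip * (npip - 1) / 2 * annulus / (bx * by)
        expected = np.divide(hist, ideal, out=np.zeros_like(hist), where=ideal > 0)
        assert np.allclose(res.g, expected, atol=1e-12)

    def test_absent_species_raises_by_name(self):
        fx = generate_fixture("one_chain_flat")
        traj = fixture_traj(fx)
        traj.species[traj.species == PS] = PC
        with pytest.raises(ValueError, match="PS"):
            obs.radial_distribution(traj, "PS", "PS")


class TestSegmentHeights:
    def test_flat_chain_mass_in_first_bin(self):
        fx = generate_fixture("one_chain_flat")
        traj = fixture_traj(fx)
        res = obs.segment_height_distribution(traj, bin_width=1.0)
        assert res.density[0] * 1.0 == pytest.approx(5.0)  # 5 segments/chain
        assert res.density[1:].sum() == 0.0

    def test_vertical_rod_uniform_occupancy(self):
        pos = np.zeros((1, 1, 6, 3))
        pos[0, 0, :, 2] = 0.5 + np.arange(6)
        lipids = np.array([[[5.0, 5.0]]])
        traj = make_traj(pos, lipids, [PIP2])
        res = obs.segment_height_distribution(traj, bin_width=1.0, z_max=7.0)
        assert np.allclose(res.density[:6], 1.0)

    def test_matches_manual_histogram(self, rng):
        pos = np.zeros((2, 2, 4, 3))
        pos[..., 2] = rng.uniform(0.5, 3.0, size=(2, 2, 4))
        lipids = np.zeros((2, 1, 2))
        traj = make_traj(pos, lipids, [PIP2])
        res = obs.segment_height_distribution(traj, bin_width=0.5, z_max=4.0)
        manual = np.histogram(pos[..., 2].ravel(), bins=res.bin_edges)[0]
        assert np.allclose(res.density * 4 * 0.5, manual)  # 4 anchored chances


class TestMobility:
    def frozen(self):
        fx = generate_fixture("one_chain_flat")
        return fixture_traj(fx, n_frames=4)

    def test_frozen_trajectory_has_zero_msds(self):
        res = obs.mobility_msd(self.frozen())
        assert res.m_pc == 0.0
        assert np.nansum(res.m_d["PIP2"]) == 0.0
        assert np.nansum(res.m_l["PIP2"]) == 0.0

    def test_single_hopping_lipid_msd_is_one(self):
        chains = np.zeros((3, 1, 2, 3))
        chains[..., 1, 0] = 1.0
        chains[:, 0, :, 1] = 5.0
        chains[..., 2] = 0.5
        # lipid hops one lattice spacing per interval, staying in zone 2
        lip = np.array([[[0.0, 5.5]], [[1.0, 5.5]], [[0.0, 5.5]]])
        traj = make_traj(chains, lip, [PIP2])
        res = obs.mobility_msd(traj)
        assert res.m_l["PIP2"][1] == pytest.approx(1.0)
        assert res.m_d["PIP2"][1] == pytest.approx(1.0)

    def test_hand_computed_four_frames_with_wrap_crossing(self):
        """Two lipids near an anchored chain; one crossing the periodic x
        boundary.  MSDs hand-computed with minimum-image displacements."""
        box = (10.0, 10.0)
        chains = np.zeros((4, 1, 2, 3))
        chains[..., 0, 0] = 0.5   # chain near the boundary
        chains[..., 1, 0] = 1.5
        chains[..., 1] = 5.0
        chains[..., 2] = 0.5
        # lipid 0 wraps: x = 9.8 -> 0.2 (displacement +0.4 by minimum image)
        l0 = [[9.8, 5.0], [0.2, 5.0], [0.6, 5.0], [0.6, 5.0]]
        l1 = [[1.0, 6.0], [1.0, 7.0], [1.0, 6.0], [2.0, 6.0]]
        traj = make_traj(chains, np.stack([l0, l1], axis=1), [PIP2, PIP2], box=box)
        res = obs.mobility_msd(traj, obs.ZoneSpec(n_zones=8))
        # zone 3 contains both lipids in all intervals:
        # interval displacements lipid0: +0.4, +0.4, 0; lipid1: +1y, -1y, +1x
        # m_l(z3) per interval: (0.16+1)/2, (0.16+1)/2, (0+1)/2 -> mean 0.72
        assert res.m_l["PIP2"][2] == pytest.approx((0.58 + 0.58 + 0.5) / 3)
        # m_d: |mean disp|^2 per interval:
        # i1: ((0.4+0)/2)^2 + ((0+1)/2)^2 = 0.04+0.25 = 0.29
        # i2: (0.2)^2 + (-0.5)^2 = 0.29 ; i3: (0.5)^2 + 0 = 0.25
        assert res.m_d["PIP2"][2] == pytest.approx((0.29 + 0.29 + 0.25) / 3)
        # chain COM stays put
        assert res.m_pc == 0.0

    def test_chain_com_displacement(self):
        chains = np.zeros((2, 1, 2, 3))
        chains[..., 1, 0] = 1.0
        chains[..., 2] = 0.5
        chains[1, 0, :, 1] += 0.3   # shift chain by 0.3 in y
        chains[1, 0, :, 2] += 0.4   # and 0.4 in z
        lip = np.tile(np.array([[[0.5, 0.0]]]), (2, 1, 1))
        traj = make_traj(chains, lip, [PIP2])
        res = obs.mobility_msd(traj)
        assert res.m_pc == pytest.approx(0.09 + 0.16)


class TestPersistenceLength:
    def test_rigid_rod_reports_infinity(self):
        rod = straight = np.zeros((20, 10, 3))
        straight[..., 0] = np.arange(10)
        res = obs.bond_angle_correlation(rod)
        assert math.isinf(res.lp)
        assert np.allclose(res.bac, 1.0)

    def test_bac_starts_at_one(self, rng):
        conf = rng.normal(size=(50, 8, 3)).cumsum(axis=1)
        res = obs.bond_angle_correlation(conf)
        assert res.bac[0] == pytest.approx(1.0, abs=1e-12)

    def test_synthetic_exponential_recovered(self, rng):
        """Bond directions built as a Markov chain on the sphere: each bond is
        the previous one tilted by a fixed polar angle with uniform azimuth,
        giving exactly BAC(j) = cos(theta)^j = e^(-j/5)."""
        target = 5.0
        cos_t = math.exp(-1.0 / target)
        sin_t = math.sqrt(1 - cos_t**2)
        n_conf, n_bonds = 400, 19
        conformations = []
        for _ in range(n_conf):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            bonds = [u]
            for _ in range(n_bonds - 1):
                u = bonds[-1]
                # orthonormal frame around u
                a = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
                e1 = np.cross(u, a)
                e1 /= np.linalg.norm(e1)
                e2 = np.cross(u, e1)
                phi = rng.uniform(0, 2 * math.pi)
                v = cos_t * u + sin_t * (math.cos(phi) * e1 + math.sin(phi) * e2)
                bonds.append(v / np.linalg.norm(v))
            pos = np.vstack([np.zeros(3), np.cumsum(bonds, axis=0)])
            conformations.append(pos)
        res = obs.bond_angle_correlation(np.array(conformations), segment_diameter=1.0)
        assert res.lp_bonds == pytest.approx(target, rel=0.1)

    def test_too_short_chain_rejected(self):
        with pytest.raises(ValueError, match="3 segments"):
            obs.bond_angle_correlation(np.zeros((5, 2, 3)))
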