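"""Structural observables against analytic and brute-force oracles."""

import numpy as np
import pytest

from lamella.io import Box, Frame
from lamella.structure import (_periodic_voronoi_areas, bilayer_thickness,
                               contact_counts, density_profile, lateral_rdf,
                               like_lipid_clusters, order_parameters,
                               tilt_distribution, voronoi_apl)
from lamella.topology import LipidTopology

from conftest import build_frame

MAGIC_ANGLE = np.degrees(np.arccos(1.0 / np.sqrt(3.0)))

ONE_H_TOPO = LipidTopology(
    species_name="POPC", head_vector_atoms=("P", "N"),
    sn1_chain=("C32",), sn2_chain=("C22",),
    ch_bonds={"C32": ("H2X",)})


def ch_frame(directions, box=(50.0, 50.0, 50.0)):
    """One POPC lipid per C-H direction: carbon at a point, H displaced."""
    records = []
    for i, d in enumerate(np.atleast_2d(directions)):
        c = np.array([5.0 + 0.01 * (i % 1000), 5.0 + 0.01 * (i // 1000), 25.0])
        records.append((i + 1, "POPC", "C32", c))
        records.append((i + 1, "POPC", "H2X", c + 0.109 * np.asarray(d)))
    return build_frame(records, box)


class TestOrderParameters:
    @pytest.mark.parametrize("direction,expected", [
        ((0, 0, 1.0), 1.0),                          # parallel to the normal
        ((1.0, 0, 0), -0.5),                         # perpendicular
    ])
    def test_trivial_angles_exact(self, direction, expected):
        prof = order_parameters([ch_frame([direction] * 4)], ONE_H_TOPO,
                                sites=["C32"])
        assert prof.s_ch[0] == pytest.approx(expected, abs=1e-6)
        assert prof.s_ch_abs[0] == pytest.approx(abs(expected), abs=1e-6)

    def test_magic_angle_vanishes(self):
        t = np.radians(MAGIC_ANGLE)
        d = (np.sin(t), 0.0, np.cos(t))
        prof = order_parameters([ch_frame([d] * 4)], ONE_H_TOPO, sites=["C32"])
        assert prof.s_ch[0] == pytest.approx(0.0, abs=1e-6)

    def test_isotropic_monte_carlo(self):
        rng = np.random.default_rng(7)
        n = 100_000
        u = rng.uniform(-1.0, 1.0, size=n)          # cos(theta) uniform on sphere
        phi = rng.uniform(0.0, 2 * np.pi, size=n)
        s = np.sqrt(1 - u**2)
        dirs = np.column_stack([s * np.cos(phi), s * np.sin(phi), u])
        prof = order_parameters([ch_frame(dirs, box=(2000, 2000, 50))],
                                ONE_H_TOPO, sites=["C32"])
        se = np.sqrt(0.2 / n)                        # Var[(3u^2-1)/2] = 1/5
        assert abs(prof.s_ch[0]) < 3 * se

    def test_fixed_cone_matches_closed_form(self):
        s_target = -0.21
        theta = np.arccos(np.sqrt((2 * s_target + 1) / 3.0))
        rng = np.random.default_rng(11)
        phi = rng.uniform(0, 2 * np.pi, size=500)
        dirs = np.column_stack([np.sin(theta) * np.cos(phi),
                                np.sin(theta) * np.sin(phi),
                                np.full_like(phi, np.cos(theta))])
        prof = order_parameters([ch_frame(dirs)], ONE_H_TOPO, sites=["C32"])
        assert prof.s_ch[0] == pytest.approx(s_target, abs=1e-9)
        assert prof.s_ch_abs[0] == pytest.approx(0.21, abs=1e-3)

    def test_missing_hydrogens_error(self):
        frame = ch_frame([(0, 0, 1.0)])
        with pytest.raises(ValueError, match="C99"):
            order_parameters([frame], ONE_H_TOPO, sites=["C99"])

    def test_bounds_invariant(self):
        rng = np.random.default_rng(3)
        dirs = rng.normal(size=(200, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        prof = order_parameters([ch_frame(dirs)], ONE_H_TOPO, sites=["C32"])
        assert -0.5 - 1e-12 <= prof.s_ch[0] <= 1.0 + 1e-12


# ---------------------------------------------------------------------------
# tilt


def head_frame(angle_deg, n_per_leaflet=50, rng=None, box=(20, 20, 10)):
    """POPC head vectors on a cone at the given angle from the outward normal."""
    rng = rng or np.random.default_rng(0)
    records = []
    res = 1
    t = np.radians(angle_deg)
    for sign, z in ((1.0, 7.0), (-1.0, 3.0)):
        for _ in range(n_per_leaflet):
            p = np.array([rng.uniform(0, 20), rng.uniform(0, 20), z])
            phi = rng.uniform(0, 2 * np.pi)
            d = np.array([np.sin(t) * np.cos(phi), np.sin(t) * np.sin(phi),
                          sign * np.cos(t)])
            records.append((res, "POPC", "P", p))
            records.append((res, "POPC", "N", p + 0.45 * d))
            res += 1
    return build_frame(records, box)


class TestTiltDistribution:
    def test_outward_normal_gives_zero(self, topos):
        dist = tilt_distribution([head_frame(0.0)], topos["POPC"], "head")
        assert dist.mean == pytest.approx(0.0, abs=1e-9)

    def test_in_plane_gives_ninety(self, topos):
        dist = tilt_distribution([head_frame(90.0)], topos["POPC"], "head")
        assert dist.mean == pytest.approx(90.0, abs=1e-9)

    def test_cone_recovery_and_histogram(self, topos):
        rng = np.random.default_rng(5)
        dist = tilt_distribution([head_frame(66.0, n_per_leaflet=5000, rng=rng)],
                                 topos["POPC"], "head", bin_width=1.0)
        assert dist.mean == pytest.approx(66.0, abs=0.5)
        assert dist.mode == pytest.approx(66.5, abs=1.0)
        assert dist.probability.sum() == pytest.approx(1.0)
        assert np.all(dist.probability >= 0)

    def test_rotation_about_z_invariant(self, topos):
        frame = head_frame(40.0, n_per_leaflet=30)
        theta = np.radians(30.0)
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        rotated = Frame(frame.residue_index, frame.residue_name,
                        frame.atom_name, frame.positions @ rot.T, frame.box)
        a = tilt_distribution([frame], topos["POPC"], "head")
        b = tilt_distribution([rotated], topos["POPC"], "head")
        assert b.mean == pytest.approx(a.mean, abs=1e-9)

    def test_zero_length_vector_error(self, topos):
        records = [(1, "POPC", "P", (1, 1, 3.0)), (1, "POPC", "N", (1, 1, 3.0)),
                   (2, "POPC", "P", (2, 2, 7.0)), (2, "POPC", "N", (2, 2, 7.45))]
        with pytest.raises(ValueError, match="residue 1"):
            tilt_distribution([build_frame(records, (5, 5, 10))],
                              topos["POPC"], "head")


# ---------------------------------------------------------------------------
# Voronoi area per lipid


def lattice_xy(n_side=10, spacing=0.8):
    g = (np.arange(n_side) + 0.5) * spacing
    gx, gy = np.meshgrid(g, g, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel()])


class TestVoronoiApl:
    def test_square_lattice_exact(self):
        box = Box(np.array([8.0, 8.0, 10.0]))
        areas = _periodic_voronoi_areas(lattice_xy(), box)
        np.testing.assert_allclose(areas, 0.64, rtol=1e-9)
        assert areas.sum() == pytest.approx(64.0, rel=1e-9)

    def test_random_seeds_conserve_area(self):
        rng = np.random.default_rng(9)
        box = Box(np.array([7.0, 5.0, 10.0]))
        for _ in range(5):
            seeds = rng.uniform(0, [7.0, 5.0], size=(37, 2))
            areas = _periodic_voronoi_areas(seeds, box)
            assert areas.sum() == pytest.approx(box.cross_section, rel=1e-9)

    def test_translation_invariance(self):
        rng = np.random.default_rng(13)
        box = Box(np.array([6.0, 6.0, 10.0]))
        seeds = rng.uniform(0, 6.0, size=(40, 2))
        a = np.sort(_periodic_voronoi_areas(seeds, box))
        b = np.sort(_periodic_voronoi_areas(seeds + [1.3, -2.6], box))
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_coincident_seeds_perturbed(self):
        box = Box(np.array([4.0, 4.0, 10.0]))
        seeds = np.array([[1.0, 1.0], [1.0, 1.0], [3.0, 1.0], [1.0, 3.0],
                          [3.0, 3.0]])
        areas = _periodic_voronoi_areas(seeds, box)
        assert areas.sum() == pytest.approx(16.0, rel=1e-6)

    def test_jittered_lattice_mean(self, topos):
        rng = np.random.default_rng(21)
        frames = []
        for fi in range(50):
            records = []
            res = 1
            for z in (7.0, 3.0):
                xy = lattice_xy(6, 0.8) + rng.normal(scale=0.05, size=(36, 2))
                for k in range(36):
                    records.append((res, "POPC", "P", (xy[k, 0], xy[k, 1], z)))
                    res += 1
            frames.append(build_frame(records, (4.8, 4.8, 10.0)))
        apl = voronoi_apl(frames, {"POPC": topos["POPC"]})
        # conservation forces the per-frame mean exactly
        assert apl.per_species["POPC"] == pytest.approx(0.64, abs=1e-9)
        assert set(apl.breakdown["leaflet"]) == {"upper", "lower"}


# ---------------------------------------------------------------------------
# thickness


class TestThickness:
    def test_exact_planes(self, topos):
        records = [(i + 1, "POPC", "P", (i * 0.5, 0.3, 7.0)) for i in range(5)]
        records += [(i + 6, "POPC", "P", (i * 0.5, 0.7, 3.0)) for i in range(5)]
        result = bilayer_thickness([build_frame(records, (5, 5, 10))], topos)
        assert result.mean == pytest.approx(4.0)
        assert result.sd == 0.0

    def test_translation_invariance(self, topos):
        records = [(1, "POPC", "P", (1, 1, 7.0)), (2, "POPC", "P", (2, 2, 2.8))]
        base = bilayer_thickness([build_frame(records, (5, 5, 12))], topos)
        shifted = [(r, s, a, (x, y, z + 1.0)) for r, s, a, (x, y, z) in records]
        moved = bilayer_thickness([build_frame(shifted, (5, 5, 12))], topos)
        assert moved.mean == pytest.approx(base.mean)

    def test_gaussian_noise_unbiased(self, topos):
        rng = np.random.default_rng(17)
        frames = []
        for _ in range(100):
            records = []
            res = 1
            for z0 in (7.0, 3.0):
                for k in range(100):
                    records.append((res, "POPC", "P",
                                    (k % 10, k // 10, z0 + rng.normal(0, 0.1))))
                    res += 1
            frames.append(build_frame(records, (10, 10, 10)))
        result = bilayer_thickness(frames, topos)
        assert abs(result.mean - 4.0) < 3 * max(result.sem, 1e-4)


# ---------------------------------------------------------------------------
# density profiles


class TestDensityProfile:
    @staticmethod
    def _centered_lipids():
        return [(1, "POPC", "P", (1.0, 1.0, 7.0)), (2, "POPC", "P", (2.0, 2.0, 3.0))]

    def test_uniform_slab_is_flat(self, topos):
        lz, bw = 10.0, 0.5
        centers = np.arange(-lz / 2 + bw / 2, lz / 2, bw) + lz / 2
        records = self._centered_lipids()
        res = 3
        for z in centers:                      # one water per bin, exactly
            records.append((res, "SOL", "MW", (2.5, 2.5, z)))
            res += 1
        frame = build_frame(records, (5.0, 5.0, lz))
        prof = density_profile([frame], [("SOL", "MW")], topos, bin_width=bw)
        expected = 18.01528 * 1.66053906660 / (bw * 25.0)
        np.testing.assert_allclose(prof.density, expected, rtol=1e-6)

    def test_mass_conservation(self, topos):
        rng = np.random.default_rng(23)
        records = self._centered_lipids()
        for i in range(500):
            records.append((3 + i, "SOL", "MW",
                            tuple(rng.uniform(0, [5, 5, 10]))))
        frame = build_frame(records, (5, 5, 10))
        prof = density_profile([frame], [("SOL", "MW")], topos, bin_width=0.1)
        total = prof.density.sum() * prof.bin_width * 25.0 / 1.66053906660
        assert total == pytest.approx(500 * 18.01528, rel=1e-6)

    def test_gaussian_peaks_at_planes(self, topos):
        rng = np.random.default_rng(29)
        records = []
        res = 1
        for z0 in (7.0, 3.0):                  # center 5 -> relative +-2
            for _ in range(2000):
                records.append((res, "POPC", "P",
                                (rng.uniform(0, 5), rng.uniform(0, 5),
                                 z0 + rng.normal(0, 0.1))))
                res += 1
        frame = build_frame(records, (5, 5, 10))
        prof = density_profile([frame], [("POPC", "P")], topos, bin_width=0.1)
        pos = prof.bin_centers[prof.bin_centers > 0]
        dpos = prof.density[prof.bin_centers > 0]
        assert abs(pos[np.argmax(dpos)] - 2.0) <= 0.1 + 1e-9
        neg = prof.bin_centers[prof.bin_centers < 0]
        dneg = prof.density[prof.bin_centers < 0]
        assert abs(neg[np.argmax(dneg)] + 2.0) <= 0.1 + 1e-9

    def test_unknown_atom_error(self, topos):
        records = self._centered_lipids() + [(3, "XXX", "QQ", (1, 1, 5.0))]
        frame = build_frame(records, (5, 5, 10))
        with pytest.raises(KeyError, match="QQ"):
            density_profile([frame], [("XXX", None)], topos)


# ---------------------------------------------------------------------------
# contacts


def brute_force_pairs(frame, mask_a, mask_b, cutoff):
    """O(N^2) oracle with explicit 27-image minimum distances."""
    pos_a = frame.positions[mask_a]
    pos_b = frame.positions[mask_b]
    res_a = frame.residue_index[mask_a]
    res_b = frame.residue_index[mask_b]
    shifts = np.array([(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                       for k in (-1, 0, 1)], dtype=float) * frame.box.lengths
    pairs = set()
    for ia in range(len(pos_a)):
        delta = pos_a[ia] - (pos_b[None, :, :] + shifts[:, None, :])
        dist = np.sqrt((delta ** 2).sum(axis=-1)).min(axis=0)
        for ib in np.flatnonzero(dist < cutoff):
            if res_a[ia] != res_b[ib]:
                pairs.add((int(res_a[ia]), int(res_b[ib])))
    return pairs


class TestContacts:
    def test_two_molecules_in_contact(self):
        frame = build_frame([(1, "A", "X", (1.0, 1.0, 1.0)),
                             (2, "B", "X", (1.5, 1.0, 1.0))], (5, 5, 5))
        s = contact_counts([frame], [("A", None)], [("B", None)], cutoff=0.6)
        assert s.mean_contacts_per_a == 1.0
        assert s.mean_contacts_per_b == 1.0

    def test_beyond_cutoff_no_contact(self):
        frame = build_frame([(1, "A", "X", (1.0, 1.0, 1.0)),
                             (2, "B", "X", (1.7, 1.0, 1.0))], (5, 5, 5))
        s = contact_counts([frame], [("A", None)], [("B", None)], cutoff=0.6)
        assert s.mean_contacts_per_a == 0.0

    def test_square_lattice_four_contacts(self):
        """Multi-atom lipids on a periodic square lattice reach only their
        four nearest neighbours within 0.6 nm -> exactly 4 contacts each."""
        records = []
        res = 1
        for i in range(4):
            for j in range(4):
                c = np.array([0.4 + 0.8 * i, 0.4 + 0.8 * j, 2.5])
                records.append((res, "POPC", "C1", c))
                for arm in ([0.25, 0, 0], [-0.25, 0, 0], [0, 0.25, 0], [0, -0.25, 0]):
                    records.append((res, "POPC", "C2", c + arm))
                res += 1
        frame = build_frame(records, (3.2, 3.2, 5.0))
        s = contact_counts([frame], [("POPC", None)], [("POPC", None)], cutoff=0.6)
        assert s.mean_contacts_per_a == 4.0
        assert s.intra_species
        mask = frame.select("POPC")
        oracle = brute_force_pairs(frame, mask, mask, 0.6)
        assert len({tuple(sorted(p)) for p in oracle}) == 2 * 16

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n_mol, atoms_per = 40, 10
        records = []
        for m in range(n_mol):
            center = rng.uniform(0, 3.0, size=3)
            species = "A" if m < 20 else "B"
            for a in range(atoms_per):
                pos = center + rng.normal(0, 0.15, size=3)
                records.append((m + 1, species, f"X{a}", pos))
        frame = build_frame(records, (3.0, 3.0, 3.0))
        s = contact_counts([frame], [("A", None)], [("B", None)], cutoff=0.6)
        oracle = brute_force_pairs(frame, frame.select("A"), frame.select("B"), 0.6)
        assert s.mean_contacts_per_a == pytest.approx(len(oracle) / 20)
        # symmetry: total A-B contacts agree from both sides
        assert s.mean_contacts_per_a * 20 == pytest.approx(s.mean_contacts_per_b * 20)


# ---------------------------------------------------------------------------
# lateral RDF


class TestLateralRdf:
    def test_single_pair_occupies_one_bin(self, topos):
        r0 = 1.03
        records = [(1, "POPC", "P", (2.0, 2.0, 7.0)),
                   (2, "POPC", "P", (2.0 + r0, 2.0, 7.01)),
                   (3, "POPC", "P", (1.0, 1.0, 3.0)),
                   (4, "POPC", "P", (1.0 + r0, 1.0, 3.01))]
        frame = build_frame(records, (6.0, 6.0, 10.0))
        rdf = lateral_rdf([frame], topos, "POPC", "POPC", bin_width=0.1)
        hot = rdf.g > 0
        assert hot.sum() == 1
        assert abs(rdf.bin_centers[hot][0] - r0) <= 0.05
        assert np.all(np.diff(rdf.cumulative) >= 0)

    def test_poisson_points_give_unit_g(self, topos):
        rng = np.random.default_rng(31)
        n, frames = 400, 30
        frame_list = []
        for _ in range(frames):
            records = []
            res = 1
            for z in (7.0, 3.0):
                xy = rng.uniform(0, 10.0, size=(n, 2))
                for k in range(n):
                    records.append((res, "POPC", "P", (xy[k, 0], xy[k, 1],
                                                       z + rng.normal(0, 0.01))))
                    res += 1
            frame_list.append(build_frame(records, (10.0, 10.0, 10.0)))
        rdf = lateral_rdf(frame_list, topos, "POPC", "POPC", bin_width=0.1)
        n_events = 2 * frames * n
        rho = (n - 1) / 100.0
        annuli = np.pi * ((rdf.bin_centers + 0.05) ** 2 - (rdf.bin_centers - 0.05) ** 2)
        expected = n_events * rho * annuli
        # per-bin 4-sigma bound: ~50 bins, family-wise alpha ~ 0.3%
        z_scores = (rdf.g[1:] - 1.0) * np.sqrt(expected[1:])
        assert np.max(np.abs(z_scores)) < 4.0

    def test_cumulative_matches_disc_count_oracle(self, topos):
        rng = np.random.default_rng(37)
        records = []
        res = 1
        xy_by_leaflet = {}
        for z in (7.0, 3.0):
            xy = rng.uniform(0, 8.0, size=(60, 2))
            xy_by_leaflet[z] = xy
            for k in range(60):
                records.append((res, "POPC", "P", (xy[k, 0], xy[k, 1], z)))
                res += 1
        frame = build_frame(records, (8.0, 8.0, 10.0))
        rdf = lateral_rdf([frame], topos, "POPC", "POPC", bin_width=0.05)
        r_edge = rdf.bin_centers[-1] + 0.025
        expected = 0.0
        for xy in xy_by_leaflet.values():
            delta = xy[:, None, :] - xy[None, :, :]
            delta -= 8.0 * np.round(delta / 8.0)
            dist = np.sqrt((delta ** 2).sum(-1))
            np.fill_diagonal(dist, np.inf)
            expected += (dist < r_edge).sum()
        assert rdf.cumulative[-1] == pytest.approx(expected / 120.0)


# ---------------------------------------------------------------------------
# clusters


class TestClusters:
    def test_all_isolated(self, topos):
        records = [(i + 1, "POPC", "P", (2.0 * i + 1.0, 1.0, 7.0)) for i in range(4)]
        records += [(i + 5, "POPC", "P", (2.0 * i + 1.0, 5.0, 3.0)) for i in range(4)]
        frame = build_frame(records, (8.0, 8.0, 10.0))
        stats = like_lipid_clusters(frame, topos, "POPC", cutoff=0.6)
        assert stats.size_histogram == {1: 8}
        assert stats.max_size == 1

    def test_chain_of_five(self, topos):
        records = [(i + 1, "POPC", "P", (0.5 + 0.5 * i, 1.0, 7.0)) for i in range(5)]
        records += [(i + 6, "POPC", "P", (2.0 * i + 1.0, 6.0, 3.0)) for i in range(4)]
        frame = build_frame(records, (8.0, 8.0, 10.0))
        stats = like_lipid_clusters(frame, topos, "POPC", cutoff=0.6)
        assert stats.size_histogram[5] == 1
        assert stats.max_size == 5

    @pytest.mark.parametrize("seed", [0, 5])
    def test_partition_property(self, topos, seed):
        rng = np.random.default_rng(seed)
        records = []
        res = 1
        for z in (7.0, 3.0):
            for _ in range(30):
                records.append((res, "POPC", "P",
                                (rng.uniform(0, 6), rng.uniform(0, 6), z)))
                res += 1
        frame = build_frame(records, (6.0, 6.0, 10.0))
        stats = like_lipid_clusters(frame, topos, "POPC", cutoff=0.6)
        assert sum(size * count for size, count in stats.size_histogram.items()) == 60
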