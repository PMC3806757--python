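"""Interaction fingerprints: hydrogen bonds, coordination, dihedrals, rotamers,
kernel densities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bindmode.interactions import (
    GeometryError,
    classify_rotamer,
    coordination_numbers,
    coordination_sphere,
    detect_hbonds,
    dihedral,
    hbond_occupancy,
    kde2d,
    compute_dihedral_series,
)
from bindmode.structures import Atom, Structure, Trajectory


def donor_acceptor_structure(d_pos, a_pos, h_pos=None):
    atoms = [
        Atom(1, "N", "N", 1, "RES", "protein", tuple(d_pos), -0.3, 3.25, 0.17, 1.55,
             frozenset({"donor_heavy"})),
        Atom(2, "O", "O", 2, "LIG", "ligand", tuple(a_pos), -0.4, 3.0, 0.2, 1.5,
             frozenset({"acceptor"})),
    ]
    if h_pos is not None:
        atoms.append(
            Atom(3, "H", "H", 1, "RES", "protein", tuple(h_pos), 0.3, 2.5, 0.02, 1.2,
                 frozenset({"hydrogen"}))
        )
    return Structure(atoms)


class TestHBonds:
    def test_beyond_distance_cutoff_not_recorded(self):
        s = donor_acceptor_structure((0, 0, 0), (5.0, 0, 0))
        assert detect_hbonds(s) == []

    def test_linear_geometry_recorded_with_angle(self):
        s = donor_acceptor_structure((0, 0, 0), (2.9, 0, 0), h_pos=(1.0, 0, 0))
        (hb,) = detect_hbonds(s)
        assert hb.distance == pytest.approx(2.9)
        assert hb.angle == pytest.approx(180.0)

    def test_bent_geometry_rejected_by_angle(self):
        # H displaced so that the D–H···A angle is 90°
        s = donor_acceptor_structure((0, 0, 0), (2.9, 0, 0), h_pos=(0.0, 1.0, 0))
        assert detect_hbonds(s) == []

    def test_hydrogen_free_mode_distance_only(self):
        s = donor_acceptor_structure((0, 0, 0), (2.9, 0, 0))
        (hb,) = detect_hbonds(s)
        assert hb.angle is None

    def test_no_annotations_warns_and_returns_empty(self):
        s = Structure([Atom(1, "C", "C", 1, "X", "protein", (0, 0, 0), 0, 3.4, 0.1, 1.7)])
        with pytest.warns(UserWarning):
            assert detect_hbonds(s) == []

    def test_occupancy_counts_fraction_of_frames(self):
        s = donor_acceptor_structure((0, 0, 0), (2.9, 0, 0))
        near = s.positions.copy()
        far = near.copy()
        far[1, 0] = 9.0
        coords = np.array([near] * 250 + [far] * 750)
        traj = Trajectory(s, coords)
        assert hbond_occupancy(traj, 1, 2) == pytest.approx(0.25)

    def test_occupancy_extremes_and_bad_ids(self):
        s = donor_acceptor_structure((0, 0, 0), (2.9, 0, 0))
        traj = Trajectory(s, s.positions[None].repeat(5, axis=0))
        assert hbond_occupancy(traj, 1, 2) == 1.0
        far = s.positions.copy()
        far[1, 0] = 20.0
        assert hbond_occupancy(Trajectory(s, far[None].repeat(5, axis=0)), 1, 2) == 0.0
        with pytest.raises(KeyError):
            hbond_occupancy(traj, 1, 77)


def ion_cage(d=2.1):
    vertices = d * np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]])
    atoms = [Atom(1, "MG", "MG", 1, "MG", "ion", (0, 0, 0), 2.0, 1.9, 0.875, 1.45)]
    for k, v in enumerate(vertices):
        atoms.append(Atom(2 + k, "O", "O", 10 + k, "HOH", "water", tuple(v), -0.4, 3.0, 0.2, 1.5))
    return Structure(atoms)


class TestCoordination:
    def test_octahedral_cage_is_hexacoordinated(self):
        cs = coordination_sphere(ion_cage(), 1)
        assert cs.coordination_number == 6

    def test_empty_sphere(self):
        cs = coordination_sphere(ion_cage(d=5.0), 1)
        assert cs.coordination_number == 0

    def test_boundary_distance_included(self):
        cs = coordination_sphere(ion_cage(d=2.6), 1)
        assert cs.coordination_number == 6

    def test_non_ion_rejected(self):
        with pytest.raises(ValueError):
            coordination_sphere(ion_cage(), 2)

    def test_jittered_cage_stays_hexacoordinated(self):
        s = ion_cage()
        rng = np.random.default_rng(0)
        coords = s.positions[None] + rng.normal(0, 0.08, (500, len(s), 3))
        cn = coordination_numbers(Trajectory(s, coords), 1)
        assert np.mean(cn == 6) >= 0.99


def dihedral_oracle(theta_deg):
    """Rotation-matrix construction: far bond rotated by theta about the
    central axis, independent of the implementation's vector algebra."""
    t = np.radians(theta_deg)
    p1 = np.array([1.0, 0.0, 0.0])
    p2 = np.array([0.0, 0.0, 0.0])
    p3 = np.array([0.0, 0.0, 1.0])
    # positive = clockwise rotation viewed along p2→p3 (+z), i.e. x toward +y
    p4 = p3 + np.array([np.cos(t), np.sin(t), 0.0])
    return p1, p2, p3, p4


class TestDihedral:
    def test_cis_is_zero(self):
        assert dihedral(*dihedral_oracle(0.0)) == pytest.approx(0.0, abs=1e-9)

    def test_anti_is_180(self):
        assert dihedral(*dihedral_oracle(180.0)) == pytest.approx(180.0, abs=1e-9)

    @pytest.mark.parametrize("theta", [-150.0, -60.0, -5.0, 30.0, 60.0, 120.0, 179.0])
    def test_matches_rotation_construction(self, theta):
        assert dihedral(*dihedral_oracle(theta)) == pytest.approx(theta, abs=1e-9)

    def test_arbitrary_quadruple_matches_normal_vector_oracle(self, rng):
        for _ in range(25):
            pts = rng.normal(0, 3, (4, 3))
            b1, b2, b3 = pts[1] - pts[0], pts[2] - pts[1], pts[3] - pts[2]
            n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
            if min(np.linalg.norm(n1), np.linalg.norm(n2)) < 1e-6:
                continue
            cosv = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
            expected = np.degrees(np.arccos(np.clip(cosv, -1, 1)))
            if np.dot(np.cross(n1, n2), b2) < 0:
                expected = -expected
            assert dihedral(*pts) == pytest.approx(expected, abs=1e-9)

    def test_collinear_rejected(self):
        with pytest.raises(GeometryError):
            dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))

    def test_series_over_trajectory(self):
        s = Structure(
            [Atom(i + 1, f"A{i}", "C", 1, "LIG", "ligand", tuple(p), 0, 3.4, 0.1, 1.7)
             for i, p in enumerate(dihedral_oracle(60.0))]
        )
        traj = Trajectory(s, s.positions[None].repeat(4, axis=0))
        series = compute_dihedral_series(traj, (1, 2, 3, 4), "test")
        assert np.allclose(series.values, 60.0)


class TestRotamers:
    @pytest.mark.parametrize(
        "angle,expected",
        [(-60.0, "gauche-"), (180.0, "trans"), (60.0, "gauche+"),
         (-179.0, "trans"), (0.0, "gauche-"), (120.0, "gauche+"), (-120.0, "trans")],
    )
    def test_bin_assignment(self, angle, expected):
        assert classify_rotamer(angle) == expected

    @settings(derandomize=True, max_examples=300)
    @given(st.floats(min_value=-179.999, max_value=180.0))
    def test_bins_partition_the_circle(self, angle):
        assert classify_rotamer(angle) in {"gauche-", "trans", "gauche+"}


def kde_bruteforce(samples, hx, hy, xg, yg):
    dens = np.zeros((len(xg), len(yg)))
    for i, x in enumerate(xg):
        for j, y in enumerate(yg):
            for sx, sy in samples:
                dens[i, j] += np.exp(-0.5 * ((x - sx) / hx) ** 2) * np.exp(
                    -0.5 * ((y - sy) / hy) ** 2
                )
    return dens / (len(samples) * 2 * np.pi * hx * hy)


class TestKde2d:
    def test_mass_conserved(self, rng):
        samples = rng.normal(0, 2, (400, 2))
        xg, yg, dens = kde2d(samples, grid_size=120)
        dx, dy = xg[1] - xg[0], yg[1] - yg[0]
        assert dens.min() >= 0
        assert dens.sum() * dx * dy == pytest.approx(1.0, abs=0.01)

    def test_two_samples_argmax_near_a_sample(self):
        samples = np.array([[0.0, 0.0], [0.05, 0.05]])
        xg, yg, dens = kde2d(samples, bandwidths=(0.5, 0.5), grid_size=101)
        i, j = np.unravel_index(np.argmax(dens), dens.shape)
        assert abs(xg[i] - 0.025) < 0.06 and abs(yg[j] - 0.025) < 0.06

    def test_matches_bruteforce_double_loop(self, rng):
        samples = rng.normal(0, 1, (40, 2))
        xg, yg, dens = kde2d(samples, bandwidths=(0.7, 0.9), grid_size=50)
        brute = kde_bruteforce(samples, 0.7, 0.9, xg, yg)
        assert np.max(np.abs(dens - brute)) < 1e-12

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            kde2d(np.zeros((1, 2)))
        with pytest.raises(ValueError):
            kde2d(np.zeros((5, 2)), bandwidths=(0.0, 1.0))
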