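"""Energy engine: Coulomb, Lennard-Jones, generalized Born, SASA, binding
energy, water B-factors."""

import numpy as np
import pytest

from bindmode.energetics import (
    EnergyComponents,
    EnergyError,
    EnergyParams,
    KCAL_COULOMB,
    binding_energy,
    coulomb_energy,
    gb_polar_energy,
    lj_energy,
    protein_b_factors,
    sasa,
    select_key_waters,
    water_b_factor,
)
from bindmode.structures import Atom, BindingPartition, Structure, Trajectory


def pair_structure(q1, q2, r, sigma=3.0, eps=0.2, born=1.7):
    return Structure(
        [
            Atom(1, "A", "C", 1, "REC", "protein", (0.0, 0.0, 0.0), q1, sigma, eps, born),
            Atom(2, "B", "C", 2, "LIG", "ligand", (r, 0.0, 0.0), q2, sigma, eps, born),
        ]
    )


PARTITION = BindingPartition()


class TestCoulomb:
    def test_zero_charge_gives_zero(self):
        assert coulomb_energy(pair_structure(0.0, 1.0, 3.0), PARTITION) == 0.0

    def test_unit_charges_reference_distance(self):
        # k_e / r with r chosen to give exactly 100 kcal/mol
        s = pair_structure(1.0, 1.0, KCAL_COULOMB / 100.0)
        assert coulomb_energy(s, PARTITION) == pytest.approx(100.0, abs=1e-9)

    def test_symmetric_under_partition_swap(self):
        s = pair_structure(0.7, -0.3, 2.5)
        swapped = BindingPartition(
            ligand_entities=frozenset({"protein"}), receptor_entities=frozenset({"ligand", "ion"})
        )
        assert coulomb_energy(s, PARTITION) == pytest.approx(
            coulomb_energy(s, swapped), abs=1e-12
        )

    def test_coincident_atoms_rejected(self):
        with pytest.raises(EnergyError):
            coulomb_energy(pair_structure(1.0, 1.0, 0.0), PARTITION)


class TestLennardJones:
    def test_zero_at_sigma(self):
        assert lj_energy(pair_structure(0, 0, 3.0, sigma=3.0), PARTITION) == pytest.approx(0.0, abs=1e-12)

    def test_minimum_depth_at_r_min(self):
        s = pair_structure(0, 0, 2 ** (1 / 6) * 3.0, sigma=3.0, eps=0.25)
        assert lj_energy(s, PARTITION) == pytest.approx(-0.25, abs=1e-12)

    def test_long_range_tail_negligible(self):
        s = pair_structure(0, 0, 30.0, sigma=3.0, eps=0.25)
        e = lj_energy(s, PARTITION)
        assert e < 0
        assert abs(e) < 1e-5 * 0.25


class TestGeneralizedBorn:
    def test_zero_charges_zero_energy(self):
        assert gb_polar_energy(pair_structure(0.0, 0.0, 4.0)) == 0.0

    def test_single_atom_closed_form_born_energy(self):
        s = Structure([Atom(1, "A", "C", 1, "X", "protein", (0, 0, 0), 1.0, 3.0, 0.1, 3.0)])
        expected = -0.5 * KCAL_COULOMB * (1 - 1 / 80.0) / 3.0  # = −54.65
        assert gb_polar_energy(s) == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(-54.65, abs=0.01)

    @pytest.mark.parametrize("q,R", [(1.0, 3.0), (-0.5, 1.2), (2.0, 1.45)])
    def test_born_self_energy_any_charge_radius(self, q, R):
        s = Structure([Atom(1, "A", "C", 1, "X", "protein", (0, 0, 0), q, 3.0, 0.1, R)])
        expected = -0.5 * KCAL_COULOMB * (1 - 1 / 80.0) * q * q / R
        assert gb_polar_energy(s) == pytest.approx(expected, rel=1e-9)

    def test_far_separation_approaches_sum_of_self_energies(self):
        # cross term decays as 1/r once f_GB → r
        self_sum = -0.5 * KCAL_COULOMB * (1 - 1 / 80.0) * (1.0 / 2.0 + 1.0 / 2.0)
        prev_gap = np.inf
        for r in (1e3, 1e6, 1e9):
            gap = abs(gb_polar_energy(pair_structure(1.0, -1.0, r, born=2.0)) - self_sum)
            assert gap < prev_gap
            prev_gap = gap
        assert prev_gap < 1e-6


class TestSasa:
    def test_isolated_atom_full_sphere(self):
        a = sasa(np.array([[0.0, 0, 0]]), np.array([1.6]), probe=1.4, n_points=512)
        assert a[0] == pytest.approx(4 * np.pi * 3.0**2, rel=0.01)

    def test_distant_atoms_do_not_occlude(self):
        pos = np.array([[0.0, 0, 0], [50.0, 0, 0]])
        a = sasa(pos, np.array([1.6, 2.0]), probe=1.4, n_points=256)
        assert a[0] == pytest.approx(4 * np.pi * 3.0**2, rel=0.01)
        assert a[1] == pytest.approx(4 * np.pi * 3.4**2, rel=0.01)

    def test_caged_atom_nearly_buried(self):
        # icosahedral-ish cage of 12 large neighbours
        from bindmode.simulate import _fibonacci_sphere

        center = np.zeros((1, 3))
        cage = 3.0 * _fibonacci_sphere(12)
        pos = np.vstack([center, cage])
        radii = np.array([1.6] + [2.0] * 12)
        a = sasa(pos, radii, probe=1.4, n_points=512)
        assert a[0] < 0.01 * 4 * np.pi * 3.0**2

    def test_quadrature_converges(self, atp_complex):
        structure, _ = atp_complex
        a1 = sasa(structure.positions, structure.born_radii, n_points=256).sum()
        a2 = sasa(structure.positions, structure.born_radii, n_points=512).sum()
        assert abs(a2 - a1) / a2 < 0.005

    def test_too_few_points_rejected(self):
        with pytest.raises(EnergyError):
            sasa(np.zeros((1, 3)), np.ones(1), n_points=16)


class TestBindingEnergy:
    def test_components_sum_to_total(self, atp_complex, atp_partition):
        structure, _ = atp_complex
        ec = binding_energy(structure, atp_partition)
        assert ec.total == pytest.approx(ec.vdw + ec.ele + ec.gb_polar + ec.nonpolar, abs=1e-9)

    def test_uncharged_apolar_ligand_no_mm_terms(self):
        atoms = [
            Atom(1, "A", "C", 1, "REC", "protein", (0, 0, 0), 0.5, 3.4, 0.1, 1.7),
            Atom(2, "B", "C", 2, "LIG", "ligand", (4.0, 0, 0), 0.0, 3.4, 0.0, 1.7),
        ]
        ec = binding_energy(Structure(atoms), PARTITION)
        assert ec.vdw == 0.0
        assert ec.ele == 0.0

    def test_matches_three_state_reevaluation(self, atp_complex, atp_partition):
        """Oracle: naive per-state Coulomb/LJ/GB double loops, complex − receptor − ligand."""
        structure, _ = atp_complex
        params = EnergyParams(sasa_points=128)
        ec = binding_energy(structure, atp_partition, params)
        rec, lig = atp_partition.masks(structure)

        def naive_state(mask):
            idx = np.nonzero(mask)[0]
            pos = structure.positions
            q, sg, ep, R = (
                structure.charges,
                structure.lj_sigma,
                structure.lj_epsilon,
                structure.born_radii,
            )
            coul = vdw = 0.0
            gb = 0.0
            for i in idx:
                gb += q[i] * q[i] / R[i]
                for j in idx:
                    if j <= i:
                        continue
                    r = np.linalg.norm(pos[i] - pos[j])
                    coul += KCAL_COULOMB * q[i] * q[j] / r
                    s = 0.5 * (sg[i] + sg[j])
                    e = np.sqrt(ep[i] * ep[j])
                    vdw += 4 * e * ((s / r) ** 12 - (s / r) ** 6)
                    f = np.sqrt(r * r + R[i] * R[j] * np.exp(-r * r / (4 * R[i] * R[j])))
                    gb += 2 * q[i] * q[j] / f
            gb *= -0.5 * KCAL_COULOMB * (1 - 1 / 80.0)
            area = sasa(pos[mask], R[mask], params.probe_radius, params.sasa_points)
            return coul, vdw, gb, params.gamma * area.sum()

        both = rec | lig
        cc, vc, gc, nc = naive_state(both)
        cr, vr, gr, nr = naive_state(rec)
        cl, vl, gl, nl = naive_state(lig)
        assert ec.ele == pytest.approx(cc - cr - cl, abs=1e-6)
        assert ec.vdw == pytest.approx(vc - vr - vl, abs=1e-6)
        assert ec.gb_polar == pytest.approx(gc - gr - gl, abs=1e-6)
        assert ec.nonpolar == pytest.approx(nc - nr - nl, abs=1e-6)

    def test_favorable_electrostatics_and_burial_in_pocket(self, atp_complex, atp_partition):
        structure, _ = atp_complex
        ec = binding_energy(structure, atp_partition)
        assert ec.ele < 0
        assert ec.nonpolar < 0

    def test_separation_drives_interactions_to_zero(self, atp_complex, atp_partition):
        structure, _ = atp_complex
        rec, lig = atp_partition.masks(structure)
        base = structure.positions.copy()
        prev = None
        for shift in (15.0, 20.0, 30.0, 45.0):
            coords = base.copy()
            coords[lig] += np.array([0.0, 0.0, shift + 25.0])
            ec = binding_energy(structure, atp_partition, coords=coords)
            mags = (abs(ec.ele), abs(ec.vdw), abs(ec.nonpolar))
            if prev is not None:
                assert all(m <= p + 1e-9 for m, p in zip(mags, prev))
            prev = mags
        assert prev[1] < 1e-3 and prev[2] < 1e-6

    def test_empty_ligand_side_rejected(self):
        atoms = [Atom(1, "A", "C", 1, "REC", "protein", (0, 0, 0), 0.5, 3.4, 0.1, 1.7)]
        with pytest.raises(Exception):
            binding_energy(Structure(atoms), PARTITION)

    def test_total_additivity_enforced_in_type(self):
        with pytest.raises(EnergyError):
            EnergyComponents(1.0, 1.0, 1.0, 1.0, 5.0)


def water_structure(n_protein=5, waters=()):
    atoms = []
    aid = 1
    for i in range(n_protein):
        atoms.append(Atom(aid, "CA", "C", 100 + i, "RES", "protein", (i * 4.0, 0, 0), 0, 3.4, 0.1, 1.7))
        aid += 1
    for j, _ in enumerate(waters):
        atoms.append(Atom(aid, "O", "O", 200 + j, "HOH", "water", (j * 4.0, 8.0, 0), -0.4, 3.0, 0.2, 1.5))
        aid += 1
    return Structure(atoms)


def jittered_trajectory(structure, sigmas, n_frames=2000, seed=0):
    rng = np.random.default_rng(seed)
    base = structure.positions
    coords = base[None] + rng.normal(0, 1, (n_frames, len(structure), 3)) * np.asarray(sigmas)[None, :, None]
    return Trajectory(structure, coords)


class TestWaterBFactors:
    def test_immobile_water_zero_b(self):
        s = water_structure(waters=[0])
        traj = Trajectory(s, np.repeat(s.positions[None], 12, axis=0))
        assert water_b_factor(traj)[200] == 0.0

    def test_isotropic_jitter_matches_moment_identity(self):
        s = water_structure(waters=[0])
        sig = [0.1] * 5 + [0.5]
        traj = jittered_trajectory(s, sig, n_frames=2000, seed=1)
        expected = (8 * np.pi**2 / 3) * 3 * 0.25
        assert water_b_factor(traj)[200] == pytest.approx(expected, rel=0.1)

    def test_constant_offset_leaves_b_unchanged(self):
        s = water_structure(waters=[0])
        traj = jittered_trajectory(s, [0.1] * 5 + [0.4], n_frames=500, seed=2)
        shifted = Trajectory(s, traj.coords + np.array([5.0, -3.0, 2.0]))
        assert water_b_factor(shifted)[200] == pytest.approx(water_b_factor(traj)[200], abs=1e-9)

    def test_too_few_frames_rejected(self):
        s = water_structure(waters=[0])
        traj = Trajectory(s, np.repeat(s.positions[None], 5, axis=0))
        with pytest.raises(EnergyError):
            water_b_factor(traj)


class TestKeyWaterSelection:
    def test_three_ordered_waters_kept_among_mobile_bulk(self):
        s = water_structure(n_protein=8, waters=range(53))
        sig = [0.15] * 8 + [0.08] * 3 + [1.0] * 50
        traj = jittered_trajectory(s, sig, n_frames=400, seed=3)
        assert sorted(select_key_waters(traj)) == [200, 201, 202]

    def test_single_key_water_inhibitor_like(self):
        s = water_structure(n_protein=8, waters=range(31))
        sig = [0.15] * 8 + [0.08] + [1.0] * 30
        traj = jittered_trajectory(s, sig, n_frames=400, seed=4)
        assert select_key_waters(traj) == [200]

    def test_all_mobile_waters_none_kept(self):
        s = water_structure(n_protein=8, waters=range(10))
        sig = [0.15] * 8 + [1.5] * 10
        traj = jittered_trajectory(s, sig, n_frames=400, seed=5)
        assert select_key_waters(traj) == []

    def test_selection_sorted_by_mobility(self, atp_complex):
        _, traj = atp_complex
        kept = select_key_waters(traj)
        b = water_b_factor(traj)
        assert kept == sorted(kept, key=lambda r: b[r])
        assert sorted(kept) == sorted(traj.meta["key_water_residues"])
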