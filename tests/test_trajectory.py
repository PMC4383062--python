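"""Superposition, RMSD/RMSF, hydrogen bonds and contacts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pbsakit.structure import (
    MolecularSystem,
    SelectionSpec,
    Snapshot,
    Trajectory,
    split_complex,
)
from pbsakit.synthetic import ComplexRecipe, build_complex, generate_trajectory
from pbsakit.trajectory import (
    FitError,
    TopologyError,
    hbond_occupancy,
    hbond_strength,
    hydrophobic_contacts,
    kabsch_superpose,
    rmsd_series,
    rmsf_profile,
)

from conftest import make_atom


def quaternion_grid_rmsd(mobile, reference, n_coarse=40000, seed=5):
    """Brute-force best-fit RMSD: dense random quaternion search followed by
    a local simplex refinement. Independent of the SVD path it checks."""
    from scipy.optimize import minimize

    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)

    def rot_from_q(q):
        q = q / np.linalg.norm(q)
        w, x, y, z = q
        return np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ]
        )

    def cost(q):
        r = rot_from_q(q)
        return np.sqrt(((mob @ r.T - ref) ** 2).sum() / len(mob))

    rng = np.random.default_rng(seed)
    qs = rng.normal(size=(n_coarse, 4))
    best = min(qs, key=cost)
    res = minimize(cost, best, method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000})
    return res.fun


class TestKabsch:
    def test_pure_translation_removed(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(size=(10, 3))
        _, _, rmsd = kabsch_superpose(ref + np.array([5.0, 0, 0]), ref)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_pure_rotation_removed(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(10, 3))
        rot = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1.0]])  # 90 deg about z
        _, _, rmsd = kabsch_superpose(ref @ rot.T, ref)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_matches_quaternion_grid_brute_force(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(size=(10, 3)) * 3.0
        mobile = ref + rng.normal(scale=0.3, size=ref.shape)
        _, _, rmsd = kabsch_superpose(mobile, ref)
        brute = quaternion_grid_rmsd(mobile, ref)
        assert rmsd == pytest.approx(brute, abs=1e-6)

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(size=(6, 3))
        mobile = -ref  # mirror image: best fit must still be det +1
        rot, _, _ = kabsch_superpose(mobile, ref)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(FitError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0.0]])
        with pytest.raises(FitError):
            kabsch_superpose(line, line)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_fit_never_increases_rmsd(self, seed):
        rng = np.random.default_rng(seed)
        ref = rng.normal(size=(8, 3)) * 2
        mobile = ref + rng.normal(scale=0.5, size=ref.shape)
        before = np.sqrt(((mobile - ref) ** 2).sum() / 8)
        _, _, after = kabsch_superpose(mobile, ref)
        assert after <= before + 1e-12


class TestRmsd:
    def test_static_trajectory_zero(self, toy_complex):
        system, ref, _ = toy_complex
        frames = [Snapshot(i, float(i), ref.coordinates.copy()) for i in range(5)]
        traj = Trajectory(system=system, snapshots=frames)
        np.testing.assert_allclose(rmsd_series(traj), 0.0, atol=1e-12)

    def test_rigid_shift_removed(self, toy_complex):
        system, ref, _ = toy_complex
        shifted = ref.coordinates + np.array([3.0, 0, 0])
        traj = Trajectory(
            system=system,
            snapshots=[Snapshot(0, 0.0, ref.coordinates), Snapshot(1, 1.0, shifted)],
        )
        series = rmsd_series(traj)
        assert series[1] == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_jitter_closed_form(self):
        """Mean superposed RMSD over backbone atoms ~ sigma*sqrt(3) with a
        (3N-6)/3N degree-of-freedom deflation from the rigid-body fit."""
        sigma = 0.25
        recipe = ComplexRecipe(
            receptor_size=6, peptide_size=4, core_sigma=sigma, loop_sigma=sigma,
            n_frames=400, seed=9,
        )
        system, ref, _ = build_complex(recipe)
        traj = generate_trajectory(system, ref, recipe)
        series = rmsd_series(traj, reference=ref)
        n_sel = len(
            [a for a in system.atoms if a.name in ("CA", "N", "O")]
        )
        expected = sigma * np.sqrt(3.0) * np.sqrt(1.0 - 6.0 / (3.0 * n_sel))
        assert series.mean() == pytest.approx(expected, rel=0.10)


class TestRmsf:
    def test_static_zero(self, toy_complex):
        system, ref, _ = toy_complex
        traj = Trajectory(
            system=system,
            snapshots=[Snapshot(i, float(i), ref.coordinates.copy()) for i in range(4)],
        )
        prof = rmsf_profile(traj)
        np.testing.assert_allclose(prof.rmsf, 0.0, atol=1e-12)

    def test_loop_ranks_above_core(self, toy_trajectory, toy_recipe):
        prof = rmsf_profile(toy_trajectory)
        values = prof.as_dict()
        loop = {tuple(k) for k in toy_recipe.loop_residues}
        loop_vals = [v for k, v in values.items() if (k[0], k[1]) in loop]
        core_vals = [v for k, v in values.items() if (k[0], k[1]) not in loop]
        assert min(loop_vals) > max(core_vals)

    def test_uniform_jitter_closed_form(self):
        sigma = 0.2
        recipe = ComplexRecipe(
            receptor_size=6, peptide_size=4, core_sigma=sigma, loop_sigma=sigma,
            n_frames=1000, seed=4,
        )
        system, ref, _ = build_complex(recipe)
        traj = generate_trajectory(system, ref, recipe)
        prof = rmsf_profile(traj, reference=ref)
        assert prof.rmsf.mean() == pytest.approx(sigma * np.sqrt(3), rel=0.12)


class TestHBonds:
    def test_collinear_geometry_qualifies(self):
        atoms = [
            make_atom(serial=1, name="N", element="N", position=(0, 0, 0)),
            make_atom(serial=2, name="H", element="H", position=(1, 0, 0),
                      mass=1.008),
            make_atom(serial=3, name="O", element="O", residue_seq=2,
                      position=(2.8, 0, 0)),
        ]
        s = MolecularSystem(atoms=atoms)
        from pbsakit.structure import BondTerm

        s.bonds.append(BondTerm(0, 1, 434.0, 1.0))
        traj = Trajectory(system=s, snapshots=[Snapshot(0, 0.0, s.coordinates())])
        bonds = hbond_occupancy(traj)
        assert len(bonds) == 1
        assert bonds[0].occupancy == 100.0
        assert bonds[0].distances[0] == pytest.approx(2.8)
        assert bonds[0].angles[0] == pytest.approx(180.0)

    def test_occupancy_arithmetic_and_classes(self, toy_complex):
        system, ref, _ = toy_complex
        # designed strong bond B1->A1: break it in 60 of 300 frames
        coords = ref.coordinates
        idx = {(a.chain_id, a.residue_seq, a.name): i for i, a in enumerate(system.atoms)}
        frames = []
        for f in range(300):
            c = coords.copy()
            if f % 5 == 0:  # 60 broken frames -> 80% occupancy
                c[idx[("B", 1, "OG")], 2] += 3.0
                c[idx[("B", 1, "HG")], 2] += 3.0
            frames.append(Snapshot(f, float(f), c))
        traj = Trajectory(system=system, snapshots=frames)
        bonds = hbond_occupancy(traj, across_only=True)
        target = [b for b in bonds if b.donor[:2] == ("B", 1)][0]
        assert target.occupancy == pytest.approx(80.0)
        assert target.strength == "strong"

    def test_strength_class_boundaries(self):
        assert hbond_strength(75.0) == "medium"
        assert hbond_strength(75.01) == "strong"
        assert hbond_strength(50.0) == "medium"
        assert hbond_strength(49.99) == "weak"
        assert hbond_strength(69.90) == "medium"
        assert hbond_strength(24.33) == "weak"
        with pytest.raises(ValueError):
            hbond_strength(101.0)

    def test_frame_order_independence(self, toy_trajectory):
        bonds = hbond_occupancy(toy_trajectory, across_only=True)
        reversed_traj = Trajectory(
            system=toy_trajectory.system,
            snapshots=[
                Snapshot(i, float(i), s.coordinates)
                for i, s in enumerate(reversed(toy_trajectory.snapshots))
            ],
        )
        bonds_r = hbond_occupancy(reversed_traj, across_only=True)
        occ = {(b.donor, b.acceptor): b.occupancy for b in bonds}
        occ_r = {(b.donor, b.acceptor): b.occupancy for b in bonds_r}
        assert occ == occ_r

    def test_orphan_hydrogen_raises(self):
        atoms = [
            make_atom(serial=1, name="HX", element="H", mass=1.008),
            make_atom(serial=2, name="O", element="O", residue_seq=2,
                      position=(3, 0, 0)),
        ]
        s = MolecularSystem(atoms=atoms)
        traj = Trajectory(system=s, snapshots=[Snapshot(0, 0.0, s.coordinates())])
        with pytest.raises(TopologyError):
            hbond_occupancy(traj)


class TestContacts:
    def test_separated_complex_empty(self, toy_complex):
        system, ref, _ = toy_complex
        _, _, rec_idx, lig_idx = split_complex(system, {"A"}, {"B"})
        coords = ref.coordinates.copy()
        coords[lig_idx] += np.array([0.0, 80.0, 0.0])
        assert hydrophobic_contacts(system, coords, rec_idx, lig_idx) == []

    def test_designed_pocket_contacts(self, toy_complex):
        system, ref, _ = toy_complex
        _, _, rec_idx, lig_idx = split_complex(system, {"A"}, {"B"})
        contacts = hydrophobic_contacts(system, ref, rec_idx, lig_idx)
        partners = {r[:2] for r, l, _ in contacts if l[:2] == ("B", 3)}
        assert {("A", 2), ("A", 3), ("A", 4)} <= partners

    def test_matches_brute_force_scan(self, toy_complex):
        system, ref, _ = toy_complex
        _, _, rec_idx, lig_idx = split_complex(system, {"A"}, {"B"})
        contacts = hydrophobic_contacts(system, ref, rec_idx, lig_idx, cutoff=4.5)
        got = {(r[:2], l[:2]) for r, l, _ in contacts}
        coords = ref.coordinates
        expected = set()
        for i in rec_idx:
            for j in lig_idx:
                ai, aj = system.atoms[i], system.atoms[j]
                if ai.is_hydrogen or aj.is_hydrogen:
                    continue
                if np.linalg.norm(coords[i] - coords[j]) <= 4.5:
                    expected.add(
                        ((ai.chain_id, ai.residue_seq), (aj.chain_id, aj.residue_seq))
                    )
        assert got == expected
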