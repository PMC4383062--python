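"""Molecular-mechanics energy terms against closed forms and brute-force
pair-sum oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pbsakit.constants import COULOMB_CONSTANT
from pbsakit.energy import (
    NonbondedTables,
    SingularityError,
    bonded_energy,
    interaction_energy,
    nonbonded_energy,
)
from pbsakit.structure import (
    AngleTerm,
    BondTerm,
    MolecularSystem,
    PartitionError,
    TorsionTerm,
)

from conftest import make_atom


def _pair(r, q1=0.0, q2=0.0, eps=0.2, rmin_half=1.7, bonded=False):
    atoms = [
        make_atom(serial=1, name="X1", charge=q1, rmin_half=rmin_half, epsilon=eps),
        make_atom(serial=2, name="X2", position=(r, 0, 0), charge=q2,
                  rmin_half=rmin_half, epsilon=eps),
    ]
    s = MolecularSystem(atoms=atoms)
    if bonded:
        s.bonds.append(BondTerm(0, 1, 300.0, r))
    return s


def brute_force_nonbonded(system, coords, scee=1.2, scnb=2.0):
    """Independent O(n^2) pair sum with path-length exclusions via BFS."""
    import collections

    n = system.n_atoms
    graph = system.bond_graph()

    def path_length(i, j, cap=4):
        seen = {i: 0}
        queue = collections.deque([i])
        while queue:
            u = queue.popleft()
            if seen[u] >= cap:
                continue
            for v in graph[u]:
                if v not in seen:
                    seen[v] = seen[u] + 1
                    if v == j:
                        return seen[v]
                    queue.append(v)
        return seen.get(j, 99)

    e_vdw = e_ele = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            nb = path_length(i, j)
            if nb <= 2:
                continue
            s_e, s_v = (1.0 / scee, 1.0 / scnb) if nb == 3 else (1.0, 1.0)
            r = np.linalg.norm(coords[j] - coords[i])
            ai, aj = system.atoms[i], system.atoms[j]
            e_ele += s_e * COULOMB_CONSTANT * ai.charge * aj.charge / r
            rmin = ai.lj_rmin_half + aj.lj_rmin_half
            eps = np.sqrt(ai.lj_epsilon * aj.lj_epsilon)
            sr6 = (rmin / r) ** 6
            e_vdw += s_v * eps * (sr6 * sr6 - 2 * sr6)
    return e_vdw, e_ele


class TestBonded:
    def test_bond_zero_at_equilibrium_and_quadratic(self):
        s = _pair(1.5, bonded=True)
        e_bond, _, _ = bonded_energy(s, s.coordinates())
        assert e_bond == pytest.approx(0.0, abs=1e-12)
        coords = s.coordinates()
        coords[1, 0] += 0.2
        e_bond, _, _ = bonded_energy(s, coords)
        assert e_bond == pytest.approx(300.0 * 0.2**2, rel=1e-10)

    def test_bond_force_matches_finite_difference(self):
        # pins the k*(dr)^2 (no 1/2) convention: dE/dr = 2k*dr
        s = _pair(1.5, bonded=True)
        coords = s.coordinates()
        coords[1, 0] += 0.17
        h = 1e-6
        cp, cm = coords.copy(), coords.copy()
        cp[1, 0] += h
        cm[1, 0] -= h
        force = (bonded_energy(s, cp)[0] - bonded_energy(s, cm)[0]) / (2 * h)
        assert force == pytest.approx(2 * 300.0 * 0.17, rel=1e-6)

    def test_angle_quadratic(self):
        atoms = [
            make_atom(serial=1, name="A1", position=(1.0, 0, 0)),
            make_atom(serial=2, name="A2", position=(0, 0, 0)),
            make_atom(serial=3, name="A3", position=(0, 1.0, 0)),
        ]
        s = MolecularSystem(atoms=atoms,
                            angles=[AngleTerm(0, 1, 2, 50.0, np.pi / 2)])
        assert bonded_energy(s, s.coordinates())[1] == pytest.approx(0.0, abs=1e-12)
        coords = s.coordinates()
        coords[2] = [np.sin(0.1), np.cos(0.1), 0.0]  # close the angle by 0.1 rad
        assert bonded_energy(s, coords)[1] == pytest.approx(50.0 * 0.01, rel=1e-6)

    def test_torsion_minimum_value(self):
        # V/2 * (1 + cos(n*phi - gamma)) vanishes where cos = -1
        atoms = [
            make_atom(serial=i + 1, name=f"T{i}", position=p)
            for i, p in enumerate(
                [(0, 1, 0), (0, 0, 0), (1.5, 0, 0), (1.5, 1, 0)]
            )
        ]
        s = MolecularSystem(
            atoms=atoms, torsions=[TorsionTerm(0, 1, 2, 3, 2.0, 1, np.pi)]
        )
        # cis geometry: phi = 0, E = V/2*(1+cos(-pi)) = 0
        assert bonded_energy(s, s.coordinates())[2] == pytest.approx(0.0, abs=1e-9)
        coords = s.coordinates()
        coords[3] = [1.5, -1.0, 0.0]  # trans: phi = pi -> maximum V
        assert bonded_energy(s, coords)[2] == pytest.approx(2.0, rel=1e-9)


class TestNonbonded:
    def test_lj_minimum(self):
        s = _pair(3.4, eps=0.2, rmin_half=1.7)
        e = nonbonded_energy(s, s.coordinates())
        assert e.e_vdw == pytest.approx(-0.2, rel=1e-12)
        assert e.e_ele == 0.0

    def test_coulomb_constant_arithmetic(self):
        s = _pair(3.0, q1=1.0, q2=1.0, eps=0.0)
        e = nonbonded_energy(s, s.coordinates())
        assert e.e_ele == pytest.approx(332.0636 / 3.0, rel=1e-12)
        assert e.e_ele == pytest.approx(110.69, abs=0.01)

    def test_brute_force_oracle_random_toy(self):
        rng = np.random.default_rng(7)
        atoms = []
        for i in range(20):
            atoms.append(
                make_atom(
                    serial=i + 1,
                    name=f"C{i}",
                    residue_seq=1 + i // 5,
                    position=rng.uniform(0, 8, 3),
                    charge=rng.uniform(-0.5, 0.5),
                    rmin_half=rng.uniform(1.2, 2.0),
                    epsilon=rng.uniform(0.05, 0.3),
                )
            )
        s = MolecularSystem(atoms=atoms)
        for i in range(0, 19, 2):  # a sparse bond graph incl. chains
            s.bonds.append(BondTerm(i, i + 1, 300.0, 1.5))
        for i in range(1, 18, 4):
            s.bonds.append(BondTerm(i, i + 2, 300.0, 1.5))
        coords = s.coordinates()
        e = nonbonded_energy(s, coords)
        bf_vdw, bf_ele = brute_force_nonbonded(s, coords)
        assert e.e_vdw == pytest.approx(bf_vdw, rel=1e-10)
        assert e.e_ele == pytest.approx(bf_ele, rel=1e-10)

    def test_pair_map_additivity(self, toy_complex):
        system, ref, _ = toy_complex
        e = nonbonded_energy(system, ref.coordinates)
        assert sum(e.per_residue_pair_vdw.values()) == pytest.approx(
            e.e_vdw, abs=1e-6
        )
        assert sum(e.per_residue_pair_ele.values()) == pytest.approx(
            e.e_ele, abs=1e-6
        )

    def test_two_residue_inter_equals_total_minus_intra(self, dipeptide):
        rng = np.random.default_rng(3)
        for i, a in enumerate(dipeptide.atoms):
            object.__setattr__(a, "charge", float(rng.uniform(-0.3, 0.3)))
        e = nonbonded_energy(dipeptide, dipeptide.coordinates())
        k1, k2 = ("A", 1, "ALA"), ("A", 2, "ALA")
        inter = e.per_residue_pair_ele.get((k1, k2), 0.0)
        intra = sum(
            v for (a, b), v in e.per_residue_pair_ele.items() if a == b
        )
        assert inter == pytest.approx(e.e_ele - intra, abs=1e-9)

    def test_coincident_atoms_raise(self):
        s = _pair(0.0, q1=0.1, q2=0.1)
        with pytest.raises(SingularityError, match="X1"):
            nonbonded_energy(s, s.coordinates())


class TestInteractionEnergy:
    def test_far_separation_vanishes(self, toy_complex):
        system, ref, _ = toy_complex
        from pbsakit.structure import split_complex

        _, _, rec_idx, lig_idx = split_complex(system, {"A"}, {"B"})
        coords = ref.coordinates.copy()
        coords[lig_idx] += np.array([0.0, 100.0, 0.0])
        vdw, ele = interaction_energy(system, rec_idx, lig_idx, coords)
        assert abs(vdw) < 1e-3
        assert abs(ele) < 0.2  # net-neutral species, dipolar tail

    def test_brute_force_cross_pairs(self, toy_complex):
        system, ref, _ = toy_complex
        from pbsakit.structure import split_complex

        _, _, rec_idx, lig_idx = split_complex(system, {"A"}, {"B"})
        vdw, ele = interaction_energy(system, rec_idx, lig_idx, ref.coordinates)
        bf_vdw = bf_ele = 0.0
        coords = ref.coordinates
        for i in rec_idx:
            for j in lig_idx:
                ai, aj = system.atoms[i], system.atoms[j]
                r = np.linalg.norm(coords[j] - coords[i])
                bf_ele += COULOMB_CONSTANT * ai.charge * aj.charge / r
                rmin = ai.lj_rmin_half + aj.lj_rmin_half
                eps = np.sqrt(ai.lj_epsilon * aj.lj_epsilon)
                sr6 = (rmin / r) ** 6
                bf_vdw += eps * (sr6 * sr6 - 2 * sr6)
        assert vdw == pytest.approx(bf_vdw, rel=1e-10)
        assert ele == pytest.approx(bf_ele, rel=1e-10)

    def test_symmetry_and_partition_check(self, toy_complex):
        system, ref, _ = toy_complex
        from pbsakit.structure import split_complex

        _, _, rec_idx, lig_idx = split_complex(system, {"A"}, {"B"})
        a = interaction_energy(system, rec_idx, lig_idx, ref.coordinates)
        b = interaction_energy(system, lig_idx, rec_idx, ref.coordinates)
        assert a == pytest.approx(b)
        with pytest.raises(PartitionError):
            interaction_energy(system, rec_idx[:-1], lig_idx, ref.coordinates)


@settings(deadline=None, max_examples=15, derandomize=True)
@given(
    shift=st.tuples(*[st.floats(-50, 50) for _ in range(3)]),
    angle=st.floats(0, 2 * np.pi),
)
def test_rigid_motion_invariance(shift, angle):
    """Translations and rigid rotations leave every energy term unchanged."""
    rng = np.random.default_rng(11)
    grid = [(x, y, z) for x in (0, 4) for y in (0, 4) for z in (0, 4)]
    atoms = [
        make_atom(serial=i + 1, name=f"C{i}",
                  position=np.asarray(g) + rng.uniform(-0.4, 0.4, 3),
                  charge=rng.uniform(-0.4, 0.4), epsilon=0.15)
        for i, g in enumerate(grid)
    ]
    s = MolecularSystem(atoms=atoms, bonds=[BondTerm(0, 1, 300.0, 1.5)])
    coords = s.coordinates()
    c, sn = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -sn, 0], [sn, c, 0], [0, 0, 1.0]])
    moved = coords @ rot.T + np.asarray(shift)
    e0 = nonbonded_energy(s, coords)
    e1 = nonbonded_energy(s, moved)
    assert e1.e_vdw == pytest.approx(e0.e_vdw, abs=1e-8)
    assert e1.e_ele == pytest.approx(e0.e_ele, abs=1e-8)
    b0, b1 = bonded_energy(s, coords), bonded_energy(s, moved)
    assert b1[0] == pytest.approx(b0[0], abs=1e-8)
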