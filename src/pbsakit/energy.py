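"""Gas-phase molecular-mechanics energy with pairwise bookkeeping.

Terms follow the AMBER-style conventions pinned by the package's tests:

- harmonic bonds/angles ``E = k (x - x0)^2`` (no 1/2),
- periodic torsions ``E = (V/2) (1 + cos(n*phi - gamma))``,
- 12-6 Lennard-Jones in Rmin/epsilon form with Lorentz-Berthelot-style
  combination (``Rmin_ij = rmin_half_i + rmin_half_j``,
  ``eps_ij = sqrt(eps_i eps_j)``),
- Coulomb with k_C = 332.0636 kcal*A/(mol*e^2), no distance cutoff
  (post-processing convention),
- 1-2 and 1-3 pairs excluded; 1-4 pairs divided by 1.2 (electrostatic) and
  2.0 (Lennard-Jones), both configurable.

Nonbonded energies are also accumulated per residue pair (and per atom) so
the per-residue decomposition and the receptor-ligand interaction energy are
exact partitions of the totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import COULOMB_CONSTANT, SCEE, SCNB
from .structure import MolecularSystem, PartitionError, PBSAKitError, Snapshot

__all__ = [
    "GasPhaseEnergy",
    "NonbondedTables",
    "SingularityError",
    "bonded_energy",
    "nonbonded_energy",
    "interaction_energy",
    "total_energy",
]


class SingularityError(PBSAKitError):
    """Two interacting atoms coincide (r = 0)."""


@dataclass
class GasPhaseEnergy:
    """Per-term gas-phase energy ledger for one snapshot."""

    e_bond: float
    e_angle: float
    e_torsion: float
    e_vdw: float
    e_ele: float
    per_residue_pair_vdw: dict[tuple, float] = field(default_factory=dict)
    per_residue_pair_ele: dict[tuple, float] = field(default_factory=dict)

    @property
    def e_int(self) -> float:
        return self.e_bond + self.e_angle + self.e_torsion

    @property
    def e_gas(self) -> float:
        return self.e_int + self.e_vdw + self.e_ele


@dataclass
class NonbondedTables:
    """Precomputed pairwise scale factors and parameters for one topology.

    ``scale_ele``/``scale_vdw`` are dense (n, n) matrices: 0 for self, 1-2
    and 1-3 pairs, the 1-4 divisor inverse for 1-4 pairs, 1 elsewhere.
    """

    scale_ele: np.ndarray
    scale_vdw: np.ndarray
    qq: np.ndarray
    rmin: np.ndarray
    eps: np.ndarray
    residue_ids: np.ndarray
    residue_keys: list[tuple]

    @classmethod
    def from_system(
        cls, system: MolecularSystem, scee: float = SCEE, scnb: float = SCNB
    ) -> "NonbondedTables":
        n = system.n_atoms
        graph = system.bond_graph()
        scale_ele = np.ones((n, n))
        scale_vdw = np.ones((n, n))
        np.fill_diagonal(scale_ele, 0.0)
        np.fill_diagonal(scale_vdw, 0.0)
        for i in range(n):
            for j in graph[i]:  # 1-2
                scale_ele[i, j] = scale_vdw[i, j] = 0.0
                for k in graph[j]:  # 1-3
                    if k == i:
                        continue
                    scale_ele[i, k] = scale_vdw[i, k] = 0.0
        # 1-4: only where not already excluded by a shorter path
        for i in range(n):
            for j in graph[i]:
                for k in graph[j]:
                    if k == i:
                        continue
                    for l in graph[k]:
                        if l in (i, j):
                            continue
                        if scale_ele[i, l] == 1.0:
                            scale_ele[i, l] = 1.0 / scee
                            scale_vdw[i, l] = 1.0 / scnb
        q = system.charges()
        qq = COULOMB_CONSTANT * np.outer(q, q)
        rh = system.radii()
        rmin = rh[:, None] + rh[None, :]
        e = np.array([a.lj_epsilon for a in system.atoms])
        eps = np.sqrt(np.outer(e, e))
        keys = system.residue_keys
        key_pos = {k: i for i, k in enumerate(keys)}
        rid = np.array([key_pos[a.residue_key] for a in system.atoms])
        return cls(scale_ele, scale_vdw, qq, rmin, eps, rid, keys)


def _pair_matrices(
    system: MolecularSystem,
    coords: np.ndarray,
    tables: NonbondedTables,
) -> tuple[np.ndarray, np.ndarray]:
    """Dense symmetric matrices of pair energies (each pair counted once when
    the upper triangle is summed; entries hold the full pair energy)."""
    coords = np.asarray(coords, dtype=float)
    diff = coords[:, None, :] - coords[None, :, :]
    r2 = np.einsum("ijk,ijk->ij", diff, diff)
    np.fill_diagonal(r2, 1.0)
    active = (tables.scale_ele > 0) | (tables.scale_vdw > 0)
    zero = (r2 <= 1e-12) & active
    if np.any(zero):
        i, j = np.argwhere(zero)[0]
        a, b = system.atoms[i], system.atoms[j]
        raise SingularityError(
            f"coincident atoms {a.chain_id}:{a.residue_seq}:{a.name} and "
            f"{b.chain_id}:{b.residue_seq}:{b.name}"
        )
    r = np.sqrt(r2)
    ele = tables.qq / r * tables.scale_ele
    sr = tables.rmin / r
    sr6 = sr**6
    vdw = tables.eps * (sr6 * sr6 - 2.0 * sr6) * tables.scale_vdw
    return vdw, ele


def _residue_pair_map(
    matrix: np.ndarray, tables: NonbondedTables
) -> dict[tuple, float]:
    """Aggregate an atom-pair energy matrix into residue-pair sums.

    Keys are ``(residue_key_a, residue_key_b)`` with a <= b in residue order;
    the sum of all values equals the total energy.
    """
    rid = tables.residue_ids
    n_res = len(tables.residue_keys)
    acc = np.zeros((n_res, n_res))
    iu, ju = np.triu_indices(matrix.shape[0], k=1)
    np.add.at(acc, (rid[iu], rid[ju]), matrix[iu, ju])
    acc = acc + acc.T - np.diag(np.diag(acc))
    out: dict[tuple, float] = {}
    for a in range(n_res):
        for b in range(a, n_res):
            val = acc[a, b]
            if val != 0.0:
                out[(tables.residue_keys[a], tables.residue_keys[b])] = float(val)
    return out


def bonded_energy(
    system: MolecularSystem, snapshot: Snapshot | np.ndarray
) -> tuple[float, float, float]:
    """Harmonic bond/angle and periodic torsion energies, kcal/mol."""
    coords = snapshot.coordinates if isinstance(snapshot, Snapshot) else np.asarray(snapshot)
    e_bond = 0.0
    for b in system.bonds:
        r = float(np.linalg.norm(coords[b.j] - coords[b.i]))
        e_bond += b.force_constant * (r - b.r0) ** 2
    e_angle = 0.0
    for a in system.angles:
        v1 = coords[a.i] - coords[a.j]
        v2 = coords[a.k] - coords[a.j]
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        theta = float(np.arccos(np.clip(cosang, -1.0, 1.0)))
        e_angle += a.force_constant * (theta - a.theta0) ** 2
    e_torsion = 0.0
    for t in system.torsions:
        b1 = coords[t.j] - coords[t.i]
        b2 = coords[t.k] - coords[t.j]
        b3 = coords[t.l] - coords[t.k]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        m1 = np.cross(n1, b2 / np.linalg.norm(b2))
        x = np.dot(n1, n2)
        y = np.dot(m1, n2)
        phi = float(np.arctan2(y, x))
        e_torsion += 0.5 * t.barrier * (1.0 + np.cos(t.periodicity * phi - t.phase))
    return e_bond, e_angle, e_torsion


def nonbonded_energy(
    system: MolecularSystem,
    snapshot: Snapshot | np.ndarray,
    tables: NonbondedTables | None = None,
    with_pair_maps: bool = True,
) -> GasPhaseEnergy:
    """Lennard-Jones and Coulomb energies (and bonded terms) for one frame.

    Returns a full :class:`GasPhaseEnergy`; residue-pair maps are attached
    unless ``with_pair_maps`` is False.
    """
    coords = snapshot.coordinates if isinstance(snapshot, Snapshot) else np.asarray(snapshot)
    if tables is None:
        tables = NonbondedTables.from_system(system)
    vdw_m, ele_m = _pair_matrices(system, coords, tables)
    iu, ju = np.triu_indices(system.n_atoms, k=1)
    e_vdw = float(vdw_m[iu, ju].sum())
    e_ele = float(ele_m[iu, ju].sum())
    e_bond, e_angle, e_torsion = bonded_energy(system, coords)
    out = GasPhaseEnergy(e_bond, e_angle, e_torsion, e_vdw, e_ele)
    if with_pair_maps:
        out.per_residue_pair_vdw = _residue_pair_map(vdw_m, tables)
        out.per_residue_pair_ele = _residue_pair_map(ele_m, tables)
    return out


def total_energy(system: MolecularSystem, coords: np.ndarray,
                 tables: NonbondedTables | None = None) -> float:
    """Total MM gas-phase energy; the function normal-mode analysis
    differentiates."""
    e = nonbonded_energy(system, coords, tables=tables, with_pair_maps=False)
    return e.e_gas


def interaction_energy(
    complex_system: MolecularSystem,
    receptor_idx,
    ligand_idx,
    snapshot: Snapshot | np.ndarray,
    tables: NonbondedTables | None = None,
) -> tuple[float, float]:
    """Cross (receptor x ligand) vdW and electrostatic energies, kcal/mol.

    In the single-trajectory protocol these two numbers are the whole
    gas-phase binding difference: bonded terms cancel exactly and
    intra-species nonbonded pairs appear identically in complex and species
    energies.
    """
    coords = snapshot.coordinates if isinstance(snapshot, Snapshot) else np.asarray(snapshot)
    rec = np.asarray(list(receptor_idx), dtype=int)
    lig = np.asarray(list(ligand_idx), dtype=int)
    n = complex_system.n_atoms
    combined = np.concatenate([rec, lig])
    if len(np.unique(combined)) != n or len(combined) != n:
        raise PartitionError("receptor/ligand index sets must partition the complex")
    if tables is None:
        tables = NonbondedTables.from_system(complex_system)
    vdw_m, ele_m = _pair_matrices(complex_system, coords, tables)
    block_vdw = vdw_m[np.ix_(rec, lig)]
    block_ele = ele_m[np.ix_(rec, lig)]
    return float(block_vdw.sum()), float(block_ele.sum())
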