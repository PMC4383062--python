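"""Trajectory descriptors: Kabsch superposition, RMSD/RMSF, hydrogen-bond
occupancy and hydrophobic contacts.

Hydrogen-bond criteria follow the standard post-processing convention: a
frame counts when the donor-heavy-atom to acceptor distance is <= 3.5 A
and the donor-hydrogen-acceptor angle is >= 120 deg. Occupancy classes:
strong > 75%, medium 50-75% (inclusive at both bounds), weak < 50%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import (
    CONTACT_CUTOFF,
    HBOND_ANGLE_CUTOFF,
    HBOND_DISTANCE_CUTOFF,
)
from .structure import (
    MolecularSystem,
    PBSAKitError,
    SelectionSpec,
    Snapshot,
    Trajectory,
    select_atoms,
)

__all__ = [
    "HBondSeries",
    "FluctuationProfile",
    "FitError",
    "TopologyError",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf_profile",
    "hbond_occupancy",
    "hbond_strength",
    "hydrophobic_contacts",
]


class FitError(PBSAKitError):
    """Superposition impossible: too few or degenerate points."""


class TopologyError(PBSAKitError):
    """Hydrogen-bond analysis found a hydrogen with no bonded heavy atom."""


@dataclass
class HBondSeries:
    """One donor-hydrogen-acceptor triple over a frame window."""

    donor: tuple  # (chain, resseq, resname, atom name)
    hydrogen: tuple
    acceptor: tuple
    distances: np.ndarray  # donor heavy atom - acceptor, per frame
    angles: np.ndarray  # donor-H-acceptor, degrees, per frame
    occupancy: float  # percent of frames satisfying both cutoffs

    @property
    def qualifying(self) -> np.ndarray:
        return (self.distances <= HBOND_DISTANCE_CUTOFF) & (
            self.angles >= HBOND_ANGLE_CUTOFF
        )

    @property
    def mean_distance(self) -> float:
        q = self.qualifying
        return float(self.distances[q].mean()) if q.any() else float("nan")

    @property
    def distance_sd(self) -> float:
        q = self.qualifying
        return float(self.distances[q].std(ddof=0)) if q.any() else float("nan")

    @property
    def strength(self) -> str:
        return hbond_strength(self.occupancy)


def hbond_strength(occupancy: float) -> str:
    """Occupancy class: strong > 75, medium in [50, 75], weak < 50."""
    if not 0.0 <= occupancy <= 100.0:
        raise ValueError(f"occupancy {occupancy} outside [0, 100]")
    if occupancy > 75.0:
        return "strong"
    if occupancy >= 50.0:
        return "medium"
    return "weak"


@dataclass
class FluctuationProfile:
    """Per-residue C-alpha RMSF (A) after per-frame superposition."""

    residue_keys: list[tuple]
    rmsf: np.ndarray

    def as_dict(self) -> dict[tuple, float]:
        return {k: float(v) for k, v in zip(self.residue_keys, self.rmsf)}


# --------------------------------------------------------------------------
# superposition
# --------------------------------------------------------------------------


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal least-squares rigid superposition of ``mobile`` onto
    ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference``; the
    rotation is proper (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise FitError("coordinate arrays must both be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise FitError("need at least 3 points to superpose")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    wsum = w.sum()
    mob_c = (mobile * w[:, None]).sum(axis=0) / wsum
    ref_c = (reference * w[:, None]).sum(axis=0) / wsum
    x = mobile - mob_c
    y = reference - ref_c
    if np.linalg.matrix_rank(x) < 2:
        raise FitError("degenerate (collinear) geometry")
    cov = (x * w[:, None]).T @ y
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = ref_c - rotation @ mob_c
    fitted = mobile @ rotation.T + translation
    rmsd = float(np.sqrt((w[:, None] * (fitted - reference) ** 2).sum() / wsum))
    return rotation, translation, rmsd


def rmsd_series(
    trajectory: Trajectory,
    selection: SelectionSpec | None = None,
    reference: Snapshot | np.ndarray | None = None,
    frame_window=None,
) -> np.ndarray:
    """Per-frame superposed RMSD (A) over a selection.

    The default selection is the backbone (CA, N, O) set and the default
    reference is the first snapshot (standing in for the minimized initial
    structure).
    """
    sel = selection or SelectionSpec(mode="backbone_CNO")
    idx = select_atoms(trajectory.system, sel)
    if reference is None:
        ref = trajectory.snapshots[0].coordinates
    else:
        ref = reference.coordinates if isinstance(reference, Snapshot) else np.asarray(reference)
    if ref.shape[0] != trajectory.system.n_atoms:
        raise FitError("reference atom count does not match trajectory")
    ref_sel = ref[idx]
    out = []
    for f in trajectory.frame_window(frame_window):
        coords = trajectory.snapshots[f].coordinates[idx]
        _, _, rmsd = kabsch_superpose(coords, ref_sel)
        out.append(rmsd)
    return np.array(out)


def rmsf_profile(
    trajectory: Trajectory,
    reference: Snapshot | np.ndarray | None = None,
    frame_window=None,
    chain_id: str | None = None,
) -> FluctuationProfile:
    """Per-residue C-alpha RMSF relative to the starting structure.

    Frames are first superposed on the reference over the C-alpha set, then
    each residue's RMSF is the root-mean-square displacement of its CA from
    the reference position.
    """
    sel = SelectionSpec(mode="calpha", chain_id=chain_id)
    idx = select_atoms(trajectory.system, sel)
    if reference is None:
        ref = trajectory.snapshots[0].coordinates
    else:
        ref = reference.coordinates if isinstance(reference, Snapshot) else np.asarray(reference)
    ref_sel = ref[idx]
    frames = trajectory.frame_window(frame_window)
    sq = np.zeros(len(idx))
    for f in frames:
        coords = trajectory.snapshots[f].coordinates[idx]
        rot, trans, _ = kabsch_superpose(coords, ref_sel)
        fitted = coords @ rot.T + trans
        sq += ((fitted - ref_sel) ** 2).sum(axis=1)
    rmsf = np.sqrt(sq / len(frames))
    keys = [trajectory.system.residue_of(i) for i in idx]
    return FluctuationProfile(residue_keys=keys, rmsf=rmsf)


# --------------------------------------------------------------------------
# hydrogen bonds
# --------------------------------------------------------------------------

_POLAR_ELEMENTS = {"N", "O", "S"}


def _atom_label(system: MolecularSystem, i: int) -> tuple:
    a = system.atoms[i]
    return (a.chain_id, a.residue_seq, a.residue_name, a.name)


def hbond_occupancy(
    trajectory: Trajectory,
    frame_window=None,
    donor_chains: set[str] | None = None,
    acceptor_chains: set[str] | None = None,
    across_only: bool = False,
    min_occupancy: float = 0.0,
) -> list[HBondSeries]:
    """Detect donor-H...acceptor bonds and their occupancies over a window.

    Donors are N/O/S heavy atoms with a bonded hydrogen; acceptors are N/O/S
    heavy atoms. Same-residue pairs are skipped. With ``across_only`` the
    donor and acceptor must sit on different chains (optionally restricted to
    the given chain sets). Series are returned sorted by descending
    occupancy; ``min_occupancy`` (percent) drops never-formed pairs.
    """
    system = trajectory.system
    graph = system.bond_graph()
    donors: list[tuple[int, int]] = []  # (heavy, hydrogen)
    for i, atom in enumerate(system.atoms):
        if not atom.is_hydrogen:
            continue
        heavies = [j for j in graph[i] if not system.atoms[j].is_hydrogen]
        if not heavies:
            raise TopologyError(
                f"hydrogen {_atom_label(system, i)} has no bonded heavy atom"
            )
        heavy = heavies[0]
        if system.atoms[heavy].element.upper() in _POLAR_ELEMENTS:
            donors.append((heavy, i))
    acceptors = [
        i
        for i, a in enumerate(system.atoms)
        if a.element.upper() in _POLAR_ELEMENTS
    ]
    frames = trajectory.frame_window(frame_window)
    coords = np.array([trajectory.snapshots[f].coordinates for f in frames])

    out: list[HBondSeries] = []
    for heavy, hyd in donors:
        d_chain = system.atoms[heavy].chain_id
        if donor_chains is not None and d_chain not in donor_chains:
            continue
        for acc in acceptors:
            if acc == heavy:
                continue
            a_atom = system.atoms[acc]
            if a_atom.residue_key == system.atoms[heavy].residue_key:
                continue
            if acceptor_chains is not None and a_atom.chain_id not in acceptor_chains:
                continue
            if across_only and a_atom.chain_id == d_chain:
                continue
            dvec = coords[:, acc] - coords[:, heavy]
            dist = np.linalg.norm(dvec, axis=1)
            v1 = coords[:, heavy] - coords[:, hyd]
            v2 = coords[:, acc] - coords[:, hyd]
            cosang = np.einsum("ij,ij->i", v1, v2) / (
                np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
            )
            ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            qual = (dist <= HBOND_DISTANCE_CUTOFF) & (ang >= HBOND_ANGLE_CUTOFF)
            occupancy = 100.0 * qual.sum() / len(frames)
            if not qual.any() or occupancy < min_occupancy:
                continue
            out.append(
                HBondSeries(
                    donor=_atom_label(system, heavy),
                    hydrogen=_atom_label(system, hyd),
                    acceptor=_atom_label(system, acc),
                    distances=dist,
                    angles=ang,
                    occupancy=occupancy,
                )
            )
    out.sort(key=lambda s: -s.occupancy)
    return out


# --------------------------------------------------------------------------
# hydrophobic contacts
# --------------------------------------------------------------------------


def hydrophobic_contacts(
    system: MolecularSystem,
    snapshot: Snapshot | np.ndarray,
    receptor_idx,
    ligand_idx,
    cutoff: float = CONTACT_CUTOFF,
    carbon_only: bool = False,
) -> list[tuple[tuple, tuple, float]]:
    """Cross-interface residue pairs with any heavy-atom pair within
    ``cutoff`` (A); returns (receptor residue, ligand residue, min distance).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    coords = snapshot.coordinates if isinstance(snapshot, Snapshot) else np.asarray(snapshot)

    def keep(i: int) -> bool:
        a = system.atoms[i]
        if a.is_hydrogen:
            return False
        if carbon_only and a.element.upper() not in {"C", "S"}:
            return False
        return True

    rec = [i for i in receptor_idx if keep(i)]
    lig = [i for i in ligand_idx if keep(i)]
    if not rec or not lig:
        return []
    d = np.linalg.norm(
        coords[np.asarray(rec)][:, None, :] - coords[np.asarray(lig)][None, :, :],
        axis=2,
    )
    best: dict[tuple[tuple, tuple], float] = {}
    for ri, rg in enumerate(rec):
        for li, lg in enumerate(lig):
            if d[ri, li] <= cutoff:
                key = (system.residue_of(rg), system.residue_of(lg))
                if d[ri, li] < best.get(key, np.inf):
                    best[key] = float(d[ri, li])
    return sorted(
        [(r, l, v) for (r, l), v in best.items()], key=lambda t: t[2]
    )
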