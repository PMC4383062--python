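"""Molecular data model, PDB I/O, atom selection, complex splitting and
alanine-truncation geometry.

The in-memory model is deliberately engine-free: a ``MolecularSystem`` holds
atoms with point charges, 12-6 Lennard-Jones parameters and masses together
with explicit harmonic bond/angle and periodic torsion terms, all read from a
plain-text parameter table (see :func:`read_parameters` for the format).
Coordinates live in ``Snapshot`` objects so a single parameterised topology
can be shared by every frame of a trajectory.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .constants import BACKBONE_ATOM_NAMES, CB_H_BOND_LENGTH, GLY_PRO

__all__ = [
    "AtomRecord",
    "BondTerm",
    "AngleTerm",
    "TorsionTerm",
    "MolecularSystem",
    "Snapshot",
    "Trajectory",
    "SelectionSpec",
    "ParameterSet",
    "AlanineMutation",
    "PBSAKitError",
    "ParameterizationError",
    "FormatError",
    "SelectionError",
    "PartitionError",
    "UnsupportedResidueError",
    "read_parameters",
    "read_pdb",
    "write_pdb",
    "select_atoms",
    "parse_selection",
    "split_complex",
    "extract_subsystem",
    "truncate_to_alanine",
]


class PBSAKitError(Exception):
    """Base class for package errors."""


class ParameterizationError(PBSAKitError):
    """An atom or atom type has no entry in the parameter table."""


class FormatError(PBSAKitError):
    """Malformed PDB or parameter-table input."""


class SelectionError(PBSAKitError):
    """A selection resolved to zero atoms or is otherwise invalid."""


class PartitionError(PBSAKitError):
    """Receptor/ligand chain sets do not partition the complex."""


class UnsupportedResidueError(PBSAKitError):
    """Alanine truncation requested for GLY, PRO or a missing residue."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AtomRecord:
    """One atom with coordinates and force-field parameters.

    ``position`` is the reference geometry (typically the first frame read);
    per-frame coordinates live in :class:`Snapshot`.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    position: np.ndarray
    charge: float
    lj_rmin_half: float
    lj_epsilon: float
    mass: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "position", np.asarray(self.position, dtype=float)
        )
        if self.lj_epsilon < 0:
            raise ValueError(f"negative LJ epsilon for atom {self.name}")
        if self.mass <= 0:
            raise ValueError(f"non-positive mass for atom {self.name}")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.name}")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.residue_name)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"


@dataclass(frozen=True)
class BondTerm:
    i: int
    j: int
    force_constant: float  # kcal/(mol*A^2), E = k * (r - r0)^2
    r0: float


@dataclass(frozen=True)
class AngleTerm:
    i: int
    j: int
    k: int
    force_constant: float  # kcal/(mol*rad^2), E = k * (theta - theta0)^2
    theta0: float  # radians


@dataclass(frozen=True)
class TorsionTerm:
    i: int
    j: int
    k: int
    l: int
    barrier: float  # kcal/mol, E = (V/2) * (1 + cos(n*phi - gamma))
    periodicity: int
    phase: float  # radians


@dataclass
class MolecularSystem:
    """Atoms plus bonded terms and a residue index.

    The residue index maps ``(chain_id, residue_seq, residue_name)`` to the
    (ordered) atom indices of that residue; it always partitions the atom
    list.
    """

    atoms: list[AtomRecord]
    bonds: list[BondTerm] = field(default_factory=list)
    angles: list[AngleTerm] = field(default_factory=list)
    torsions: list[TorsionTerm] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for term in self.bonds:
            if not (0 <= term.i < n and 0 <= term.j < n):
                raise FormatError("bond index out of range")
        for term in self.angles:
            if not all(0 <= x < n for x in (term.i, term.j, term.k)):
                raise FormatError("angle index out of range")
        for term in self.torsions:
            if not all(0 <= x < n for x in (term.i, term.j, term.k, term.l)):
                raise FormatError("torsion index out of range")
        self._residue_index: dict[tuple[str, int, str], list[int]] = {}
        for idx, atom in enumerate(self.atoms):
            self._residue_index.setdefault(atom.residue_key, []).append(idx)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def residue_index(self) -> dict[tuple[str, int, str], list[int]]:
        return self._residue_index

    @property
    def residue_keys(self) -> list[tuple[str, int, str]]:
        return list(self._residue_index)

    def coordinates(self) -> np.ndarray:
        """Reference coordinates, shape (n_atoms, 3)."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    def radii(self) -> np.ndarray:
        """Atomic radii (LJ Rmin/2-derived set) for PB and SASA."""
        return np.array([a.lj_rmin_half for a in self.atoms], dtype=float)

    def bond_graph(self) -> dict[int, set[int]]:
        graph: dict[int, set[int]] = {i: set() for i in range(self.n_atoms)}
        for b in self.bonds:
            graph[b.i].add(b.j)
            graph[b.j].add(b.i)
        return graph

    def residue_of(self, atom_index: int) -> tuple[str, int, str]:
        return self.atoms[atom_index].residue_key


@dataclass
class Snapshot:
    """One coordinate set aligned to a MolecularSystem atom order."""

    frame_id: int
    time_ps: float
    coordinates: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise FormatError("snapshot coordinates must have shape (n, 3)")
        if self.time_ps < 0:
            raise FormatError("snapshot time must be >= 0")


@dataclass
class Trajectory:
    """Ordered snapshots over one system."""

    system: MolecularSystem
    snapshots: list[Snapshot]

    def __post_init__(self) -> None:
        n = self.system.n_atoms
        last_t = -np.inf
        for snap in self.snapshots:
            if snap.coordinates.shape[0] != n:
                raise FormatError(
                    f"snapshot {snap.frame_id} has {snap.coordinates.shape[0]}"
                    f" atoms, system has {n}"
                )
            if snap.time_ps < last_t:
                raise FormatError("snapshot times must be nondecreasing")
            last_t = snap.time_ps

    @property
    def n_frames(self) -> int:
        return len(self.snapshots)

    def coordinate_array(self) -> np.ndarray:
        """All frames stacked, shape (n_frames, n_atoms, 3)."""
        return np.array([s.coordinates for s in self.snapshots], dtype=float)

    def frame_window(self, window: str | Sequence[int] | None) -> list[int]:
        """Resolve a frame-window spec to snapshot indices.

        ``window`` may be None (all frames), a list of indices, or a string
        ``"last:N"`` (last N frames) / ``"last-ps:T"`` (frames with
        time >= t_end - T).
        """
        if window is None:
            return list(range(self.n_frames))
        if isinstance(window, str):
            kind, _, value = window.partition(":")
            if kind == "last":
                n = int(value)
                if n <= 0:
                    raise SelectionError("frame window must be positive")
                return list(range(max(0, self.n_frames - n), self.n_frames))
            if kind == "last-ps":
                span = float(value)
                t_end = self.snapshots[-1].time_ps
                idx = [
                    i
                    for i, s in enumerate(self.snapshots)
                    if s.time_ps >= t_end - span
                ]
                if not idx:
                    raise SelectionError("empty frame window")
                return idx
            raise SelectionError(f"unknown frame window {window!r}")
        idx = list(window)
        if not idx:
            raise SelectionError("empty frame window")
        return idx


@dataclass(frozen=True)
class SelectionSpec:
    """Atom selection: a mode plus optional chain and residue-range filters."""

    mode: str = "all"  # backbone_CNO | calpha | heavy | all | residue_range
    chain_id: str | None = None
    residue_start: int | None = None
    residue_end: int | None = None

    _MODES = ("backbone_CNO", "calpha", "heavy", "all", "residue_range")

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise SelectionError(f"unknown selection mode {self.mode!r}")
        if (
            self.residue_start is not None
            and self.residue_end is not None
            and self.residue_start > self.residue_end
        ):
            raise SelectionError("residue interval start > end")


# --------------------------------------------------------------------------
# parameter table
# --------------------------------------------------------------------------


@dataclass
class ParameterSet:
    """Parsed plain-text parameter table.

    Atom parameters are residue-template based, keyed by
    ``(residue_name, atom_name)``; bonded terms are explicit per-system
    records keyed by ``chain:resseq:atomname`` references.
    """

    atom_params: dict[tuple[str, str], dict[str, float | str]]
    bond_records: list[tuple[str, str, float, float]]
    angle_records: list[tuple[str, str, str, float, float]]
    torsion_records: list[tuple[str, str, str, str, float, int, float]]

    def lookup_atom(self, residue_name: str, atom_name: str) -> dict:
        try:
            return self.atom_params[(residue_name, atom_name)]
        except KeyError:
            raise ParameterizationError(
                f"no parameters for atom {atom_name!r} in residue "
                f"{residue_name!r}"
            ) from None


def read_parameters(source: str) -> ParameterSet:
    """Read the package's TSV parameter table.

    ``source`` is a path or the table text itself. Line formats
    (tab- or whitespace-separated, ``#`` comments):

    - ``atom  RESNAME  ATOMNAME  ELEMENT  charge  rmin_half  epsilon  mass``
    - ``bond  A:1:CA  A:1:CB  k  r0``
    - ``angle  A:1:N  A:1:CA  A:1:C  k  theta0_deg``
    - ``torsion  ref ref ref ref  barrier  periodicity  phase_deg``

    Angles/phases are degrees in the file, radians in memory.
    """
    if "\n" in source or "\t" in source:
        text = source
    else:
        with open(source) as fh:
            text = fh.read()
    atom_params: dict[tuple[str, str], dict] = {}
    bonds: list[tuple[str, str, float, float]] = []
    angles: list[tuple[str, str, str, float, float]] = []
    torsions: list[tuple[str, str, str, str, float, int, float]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        kind = parts[0].lower()
        try:
            if kind == "atom":
                resname, name, element = parts[1], parts[2], parts[3]
                charge, rmin_half, eps, mass = map(float, parts[4:8])
                atom_params[(resname, name)] = {
                    "element": element,
                    "charge": charge,
                    "lj_rmin_half": rmin_half,
                    "lj_epsilon": eps,
                    "mass": mass,
                }
            elif kind == "bond":
                bonds.append((parts[1], parts[2], float(parts[3]), float(parts[4])))
            elif kind == "angle":
                angles.append(
                    (parts[1], parts[2], parts[3], float(parts[4]),
                     np.deg2rad(float(parts[5])))
                )
            elif kind == "torsion":
                torsions.append(
                    (parts[1], parts[2], parts[3], parts[4], float(parts[5]),
                     int(parts[6]), np.deg2rad(float(parts[7])))
                )
            else:
                raise FormatError(
                    f"unknown record type {kind!r} on line {lineno}"
                )
        except (IndexError, ValueError) as exc:
            raise FormatError(
                f"malformed parameter record on line {lineno}: {raw!r}"
            ) from exc
    return ParameterSet(atom_params, bonds, angles, torsions)


def _atom_ref(ref: str) -> tuple[str, int, str]:
    chain, resseq, name = ref.split(":")
    return chain, int(resseq), name


# --------------------------------------------------------------------------
# PDB I/O
# --------------------------------------------------------------------------


def read_pdb(source: str, params: ParameterSet) -> tuple[MolecularSystem, Trajectory]:
    """Read a (possibly multi-MODEL) PDB file into a system and trajectory.

    ``source`` is a path or PDB-format text. Every atom must resolve in the
    parameter table by ``(residue_name, atom_name)``. Each MODEL becomes one
    snapshot; atom identity and order must be identical across models.
    """
    from Bio.PDB import PDBParser

    if "\n" in source:
        handle: io.StringIO | str = io.StringIO(source)
    else:
        handle = source
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("pbsakit", handle)
    models = list(structure)
    if not models:
        raise FormatError("PDB input contains no coordinates")

    def model_atoms(model):
        out = []
        for chain in model:
            for residue in chain:
                for atom in residue:
                    out.append(
                        (
                            atom.serial_number,
                            atom.get_name(),
                            residue.get_resname().strip(),
                            residue.id[1],
                            chain.id,
                            np.asarray(atom.coord, dtype=float),
                            (atom.element or "").strip(),
                        )
                    )
        return out

    first = model_atoms(models[0])
    atoms: list[AtomRecord] = []
    for serial, name, resname, resseq, chain_id, pos, element in first:
        p = params.lookup_atom(resname, name)
        atoms.append(
            AtomRecord(
                serial=serial,
                name=name,
                element=element or str(p["element"]),
                residue_name=resname,
                residue_seq=resseq,
                chain_id=chain_id,
                position=pos,
                charge=float(p["charge"]),
                lj_rmin_half=float(p["lj_rmin_half"]),
                lj_epsilon=float(p["lj_epsilon"]),
                mass=float(p["mass"]),
            )
        )

    system = MolecularSystem(atoms=atoms)
    _attach_bonded_terms(system, params)

    snapshots = []
    ident = [(a[1], a[2], a[3], a[4]) for a in first]
    for m_i, model in enumerate(models):
        rows = model_atoms(model)
        if [(a[1], a[2], a[3], a[4]) for a in rows] != ident:
            raise FormatError(
                f"MODEL {m_i + 1} atom list differs from MODEL 1"
            )
        coords = np.array([a[5] for a in rows], dtype=float)
        snapshots.append(Snapshot(frame_id=m_i, time_ps=float(m_i), coordinates=coords))
    return system, Trajectory(system=system, snapshots=snapshots)


def _attach_bonded_terms(system: MolecularSystem, params: ParameterSet) -> None:
    index: dict[tuple[str, int, str], int] = {}
    for i, atom in enumerate(system.atoms):
        index[(atom.chain_id, atom.residue_seq, atom.name)] = i

    def resolve(ref: str) -> int:
        key = _atom_ref(ref)
        try:
            return index[key]
        except KeyError:
            raise ParameterizationError(
                f"bonded term references missing atom {ref!r}"
            ) from None

    for a, b, k, r0 in params.bond_records:
        system.bonds.append(BondTerm(resolve(a), resolve(b), k, r0))
    for a, b, c, k, t0 in params.angle_records:
        system.angles.append(AngleTerm(resolve(a), resolve(b), resolve(c), k, t0))
    for a, b, c, d, v, n, ph in params.torsion_records:
        system.torsions.append(
            TorsionTerm(resolve(a), resolve(b), resolve(c), resolve(d), v, n, ph)
        )


def write_pdb(
    system: MolecularSystem,
    snapshots: Snapshot | Iterable[Snapshot] | None = None,
    path: str | None = None,
) -> str:
    """Write the system (optionally multi-MODEL) as PDB text.

    Returns the text; also writes it to ``path`` when given. Coordinates are
    written to 3 decimals, preserving atom order and names exactly.
    """
    if snapshots is None:
        frames = [Snapshot(0, 0.0, system.coordinates())]
    elif isinstance(snapshots, Snapshot):
        frames = [snapshots]
    else:
        frames = list(snapshots)
    multi = len(frames) > 1
    lines: list[str] = []
    for m, snap in enumerate(frames, start=1):
        if multi:
            lines.append(f"MODEL     {m:4d}")
        for i, atom in enumerate(system.atoms):
            x, y, z = snap.coordinates[i]
            name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
            lines.append(
                f"ATOM  {atom.serial % 100000:5d} {name:<4s} "
                f"{atom.residue_name:<3s} {atom.chain_id:1s}"
                f"{atom.residue_seq:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {atom.element:>2s}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# --------------------------------------------------------------------------
# selections
# --------------------------------------------------------------------------


def select_atoms(system: MolecularSystem, spec: SelectionSpec) -> list[int]:
    """Resolve a selection to an ordered list of atom indices.

    Raises :class:`SelectionError` on an empty result so callers can never
    silently compute on zero atoms.
    """
    out: list[int] = []
    for i, atom in enumerate(system.atoms):
        if spec.chain_id is not None and atom.chain_id != spec.chain_id:
            continue
        if spec.residue_start is not None and atom.residue_seq < spec.residue_start:
            continue
        if spec.residue_end is not None and atom.residue_seq > spec.residue_end:
            continue
        if spec.mode == "backbone_CNO" and atom.name not in ("CA", "N", "O"):
            continue
        if spec.mode == "calpha" and atom.name != "CA":
            continue
        if spec.mode == "heavy" and atom.is_hydrogen:
            continue
        out.append(i)
    if not out:
        raise SelectionError(f"selection {spec} matched no atoms")
    return out


def parse_selection(text: str) -> SelectionSpec:
    """Parse a CLI selection string, e.g. ``"chain=B and resid 337-362"``.

    Clauses joined by ``and``: ``chain=X``, ``resid a-b`` (or ``resid a``),
    and a bare mode keyword (``backbone``, ``calpha``, ``heavy``, ``all``).
    """
    mode = None
    chain = None
    start = end = None
    aliases = {
        "backbone": "backbone_CNO",
        "backbone_cno": "backbone_CNO",
        "calpha": "calpha",
        "ca": "calpha",
        "heavy": "heavy",
        "all": "all",
    }
    for clause in (c.strip() for c in text.split(" and ")):
        if not clause:
            continue
        low = clause.lower()
        if low.startswith("chain"):
            chain = clause.replace("=", " ").split()[1]
        elif low.startswith("resid"):
            rng = clause.replace("=", " ").split()[1]
            if "-" in rng[1:]:
                a, _, b = rng[1:].partition("-")
                start, end = int(rng[0] + a), int(b)
            else:
                start = end = int(rng)
            if mode is None:
                mode = "residue_range"
        elif low in aliases:
            mode = aliases[low]
        else:
            raise SelectionError(f"cannot parse selection clause {clause!r}")
    return SelectionSpec(
        mode=mode or "all", chain_id=chain, residue_start=start, residue_end=end
    )


# --------------------------------------------------------------------------
# complex splitting
# --------------------------------------------------------------------------


def extract_subsystem(
    system: MolecularSystem, indices: Sequence[int]
) -> MolecularSystem:
    """Subsystem over ``indices`` (order preserved), remapping bonded terms.

    Bonded terms with some but not all atoms inside the subset raise
    :class:`PartitionError` — a valid receptor/ligand split must not cut
    through bonds.
    """
    indices = list(indices)
    inside = {old: new for new, old in enumerate(indices)}
    atoms = [system.atoms[i] for i in indices]
    sub = MolecularSystem(atoms=atoms)

    def keep(term_atoms: tuple[int, ...]) -> bool:
        hits = sum(1 for a in term_atoms if a in inside)
        if hits == 0:
            return False
        if hits < len(term_atoms):
            raise PartitionError(
                f"bonded term {term_atoms} spans the subsystem boundary"
            )
        return True

    for b in system.bonds:
        if keep((b.i, b.j)):
            sub.bonds.append(replace(b, i=inside[b.i], j=inside[b.j]))
    for a in system.angles:
        if keep((a.i, a.j, a.k)):
            sub.angles.append(
                replace(a, i=inside[a.i], j=inside[a.j], k=inside[a.k])
            )
    for t in system.torsions:
        if keep((t.i, t.j, t.k, t.l)):
            sub.torsions.append(
                replace(
                    t, i=inside[t.i], j=inside[t.j], k=inside[t.k], l=inside[t.l]
                )
            )
    return sub


def split_complex(
    system: MolecularSystem,
    receptor_chains: Iterable[str],
    ligand_chains: Iterable[str],
) -> tuple[MolecularSystem, MolecularSystem, list[int], list[int]]:
    """Split a complex into receptor and ligand subsystems by chain sets.

    Returns ``(receptor, ligand, receptor_indices, ligand_indices)`` where the
    index lists map subsystem atom order back into the complex.
    """
    rec = set(receptor_chains)
    lig = set(ligand_chains)
    if rec & lig:
        raise PartitionError(f"chain sets overlap: {sorted(rec & lig)}")
    chains_present = {a.chain_id for a in system.atoms}
    uncovered = chains_present - rec - lig
    if uncovered:
        raise PartitionError(f"chains not assigned to either side: {sorted(uncovered)}")
    rec_idx = [i for i, a in enumerate(system.atoms) if a.chain_id in rec]
    lig_idx = [i for i, a in enumerate(system.atoms) if a.chain_id in lig]
    if not rec_idx or not lig_idx:
        raise PartitionError("receptor and ligand must both be non-empty")
    return (
        extract_subsystem(system, rec_idx),
        extract_subsystem(system, lig_idx),
        rec_idx,
        lig_idx,
    )


# --------------------------------------------------------------------------
# alanine truncation
# --------------------------------------------------------------------------


@dataclass
class AlanineMutation:
    """A side-chain-to-alanine truncation of one residue.

    ``system`` is the mutant topology (reference geometry already mapped).
    ``kept_wild_indices[i]`` gives, for every mutant atom except the cap
    hydrogen, the wild-type atom it came from; ``cap_index`` is the mutant
    index of the cap hydrogen (or None when the residue was already alanine
    -like and nothing was removed). :meth:`map_coordinates` re-derives mutant
    coordinates — including the frame-dependent cap-hydrogen position along
    the removed C(beta)->C(gamma) direction — from any wild-type frame.
    """

    system: MolecularSystem
    residue_key: tuple[str, int, str]
    kept_wild_indices: list[int]
    cap_index: int | None
    cb_wild_index: int | None
    gamma_wild_index: int | None
    identical: bool

    def map_coordinates(self, wild_coords: np.ndarray) -> np.ndarray:
        wild_coords = np.asarray(wild_coords, dtype=float)
        if self.identical:
            return wild_coords.copy()
        coords = np.empty((self.system.n_atoms, 3), dtype=float)
        mut_positions = [i for i in range(self.system.n_atoms) if i != self.cap_index]
        for mut_i, wild_i in zip(mut_positions, self.kept_wild_indices):
            coords[mut_i] = wild_coords[wild_i]
        cb = wild_coords[self.cb_wild_index]
        gamma = wild_coords[self.gamma_wild_index]
        direction = gamma - cb
        norm = np.linalg.norm(direction)
        if norm == 0:
            raise FormatError("degenerate CB->Cgamma direction")
        coords[self.cap_index] = cb + CB_H_BOND_LENGTH * direction / norm
        return coords

    def map_snapshot(self, snap: Snapshot) -> Snapshot:
        return Snapshot(snap.frame_id, snap.time_ps, self.map_coordinates(snap.coordinates))


def truncate_to_alanine(
    system: MolecularSystem,
    residue_key: tuple[str, int, str],
    params: ParameterSet | None = None,
) -> AlanineMutation:
    """Truncate one residue's side chain to alanine.

    Atoms beyond C(beta) are removed; C(beta) is retained (reassigned the
    alanine-template parameters when ``params`` provides an ``(ALA, CB)``
    entry) and capped with one hydrogen placed along the removed
    C(beta)->C(gamma) unit vector at the standard 1.09 A bond length.
    Backbone atoms and every other residue are untouched. GLY and PRO
    targets raise :class:`UnsupportedResidueError`.
    """
    if residue_key not in system.residue_index:
        raise UnsupportedResidueError(f"residue {residue_key} not in system")
    resname = residue_key[2]
    if resname in GLY_PRO:
        raise UnsupportedResidueError(
            f"{resname} cannot be alanine-scanned (backbone conformation differs)"
        )
    res_atoms = system.residue_index[residue_key]
    by_name = {system.atoms[i].name: i for i in res_atoms}
    graph = system.bond_graph()

    removed = [
        i
        for i in res_atoms
        if system.atoms[i].name not in BACKBONE_ATOM_NAMES
        and system.atoms[i].name != "CB"
    ]
    if not removed:
        # already alanine-like: identity mutation
        return AlanineMutation(
            system=system,
            residue_key=residue_key,
            kept_wild_indices=list(range(system.n_atoms)),
            cap_index=None,
            cb_wild_index=by_name.get("CB"),
            gamma_wild_index=None,
            identical=True,
        )
    if "CB" not in by_name:
        raise UnsupportedResidueError(
            f"residue {residue_key} has side-chain atoms but no CB"
        )
    cb = by_name["CB"]
    gamma_candidates = [i for i in sorted(graph[cb]) if i in removed]
    gamma = gamma_candidates[0] if gamma_candidates else removed[0]

    removed_set = set(removed)
    kept = [i for i in range(system.n_atoms) if i not in removed_set]

    def ala_param(atom_name: str, fallback: AtomRecord) -> dict:
        if params is not None and ("ALA", atom_name) in params.atom_params:
            return params.atom_params[("ALA", atom_name)]
        return {
            "element": fallback.element,
            "charge": fallback.charge,
            "lj_rmin_half": fallback.lj_rmin_half,
            "lj_epsilon": fallback.lj_epsilon,
            "mass": fallback.mass,
        }

    atoms: list[AtomRecord] = []
    new_index_of: dict[int, int] = {}
    cap_index = None
    cb_new = None
    chain_id, resseq, _ = residue_key
    for old in kept:
        a = system.atoms[old]
        if old in res_atoms:
            a = replace(a, residue_name="ALA")
            if a.name == "CB":
                p = ala_param("CB", a)
                a = replace(
                    a,
                    charge=float(p["charge"]),
                    lj_rmin_half=float(p["lj_rmin_half"]),
                    lj_epsilon=float(p["lj_epsilon"]),
                    mass=float(p["mass"]),
                )
        new_index_of[old] = len(atoms)
        atoms.append(a)
        if old == cb:
            cb_new = len(atoms) - 1
    # cap hydrogen appended at the end of the mutated residue's atom block
    h_template = AtomRecord(
        serial=max(a.serial for a in system.atoms) + 1,
        name="HB1",
        element="H",
        residue_name="ALA",
        residue_seq=resseq,
        chain_id=chain_id,
        position=np.zeros(3),
        charge=0.09,
        lj_rmin_half=1.387,
        lj_epsilon=0.016,
        mass=1.008,
    )
    if params is not None and ("ALA", "HB1") in params.atom_params:
        p = params.atom_params[("ALA", "HB1")]
        h_template = replace(
            h_template,
            charge=float(p["charge"]),
            lj_rmin_half=float(p["lj_rmin_half"]),
            lj_epsilon=float(p["lj_epsilon"]),
            mass=float(p["mass"]),
        )
    cap_index = len(atoms)
    atoms.append(h_template)

    mutant = MolecularSystem(atoms=atoms)
    for b in system.bonds:
        if b.i in removed_set or b.j in removed_set:
            continue
        mutant.bonds.append(replace(b, i=new_index_of[b.i], j=new_index_of[b.j]))
    for an in system.angles:
        if {an.i, an.j, an.k} & removed_set:
            continue
        mutant.angles.append(
            replace(an, i=new_index_of[an.i], j=new_index_of[an.j], k=new_index_of[an.k])
        )
    for t in system.torsions:
        if {t.i, t.j, t.k, t.l} & removed_set:
            continue
        mutant.torsions.append(
            replace(
                t,
                i=new_index_of[t.i],
                j=new_index_of[t.j],
                k=new_index_of[t.k],
                l=new_index_of[t.l],
            )
        )
    mutant.bonds.append(
        BondTerm(i=new_index_of[cb], j=cap_index, force_constant=340.0, r0=CB_H_BOND_LENGTH)
    )

    mutation = AlanineMutation(
        system=mutant,
        residue_key=residue_key,
        kept_wild_indices=kept,
        cap_index=cap_index,
        cb_wild_index=cb,
        gamma_wild_index=gamma,
        identical=False,
    )
    # materialise reference geometry on the mutant atoms
    ref = mutation.map_coordinates(system.coordinates())
    mutation.system.atoms = [
        replace(a, position=ref[i]) for i, a in enumerate(mutant.atoms)
    ]
    return mutation
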