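"""Translational, rotational and vibrational entropy from normal-mode
analysis — the -T*dS term of the binding free energy.

The Hessian is built by central finite differences of the total
molecular-mechanics gas-phase energy, mass-weighted, and diagonalised;
rigid-body modes (6 for a nonlinear molecule) are identified by magnitude
and removed. Statistical-mechanics closed forms then give S_trans
(Sackur-Tetrode at 1 atm), S_rot (classical rigid rotor) and S_vib
(quantum harmonic oscillator summed over the positive modes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.constants as sc

from .constants import (
    AMU_TO_KG,
    ANGSTROM_TO_M,
    C_CM,
    KCAL_PER_MOL_TO_J,
    PRESSURE_ATM,
    R_CAL,
    TEMPERATURE,
)
from .energy import NonbondedTables, total_energy
from .structure import MolecularSystem, PBSAKitError, Snapshot

__all__ = [
    "EntropyResult",
    "EntropyQualityError",
    "mass_weighted_hessian",
    "mode_frequencies",
    "inertia_tensor",
    "entropy_from_modes",
    "molecule_entropy",
]

log = logging.getLogger("pbsakit.entropy")


class EntropyQualityError(PBSAKitError):
    """Too large a fraction of imaginary modes for a trustworthy entropy."""


@dataclass
class EntropyResult:
    """Entropy components in cal/(mol*K) and their -T*S in kcal/mol."""

    s_trans: float
    s_rot: float
    s_vib: float
    temperature: float
    frequencies_cm: np.ndarray = field(default_factory=lambda: np.zeros(0))
    n_imaginary: int = 0

    @property
    def s_total(self) -> float:
        return self.s_trans + self.s_rot + self.s_vib

    @property
    def minus_t_s(self) -> float:
        """-T*S in kcal/mol."""
        return -self.temperature * self.s_total / 1000.0


def mass_weighted_hessian(
    system: MolecularSystem,
    snapshot: Snapshot | np.ndarray,
    displacement: float = 1e-4,
) -> np.ndarray:
    """Mass-weighted Hessian of the MM energy, (3n, 3n), by central
    finite differences; symmetrised.

    The caller is responsible for supplying a near-minimum geometry;
    elsewhere the harmonic frequencies are not meaningful.
    """
    coords = (
        snapshot.coordinates if isinstance(snapshot, Snapshot) else np.asarray(snapshot)
    ).astype(float)
    n = system.n_atoms
    tables = NonbondedTables.from_system(system)

    def grad(x: np.ndarray) -> np.ndarray:
        g = np.zeros(3 * n)
        flat = x.ravel()
        for d in range(3 * n):
            xp = flat.copy()
            xm = flat.copy()
            xp[d] += displacement
            xm[d] -= displacement
            ep = total_energy(system, xp.reshape(n, 3), tables)
            em = total_energy(system, xm.reshape(n, 3), tables)
            if not (np.isfinite(ep) and np.isfinite(em)):
                raise PBSAKitError("non-finite energy during Hessian displacement")
            g[d] = (ep - em) / (2.0 * displacement)
        return g

    hess = np.zeros((3 * n, 3 * n))
    flat = coords.ravel()
    for d in range(3 * n):
        xp = flat.copy()
        xm = flat.copy()
        xp[d] += displacement
        xm[d] -= displacement
        gp = grad(xp.reshape(n, 3).ravel().reshape(n, 3))
        gm = grad(xm.reshape(n, 3))
        hess[d] = (gp - gm) / (2.0 * displacement)
    hess = 0.5 * (hess + hess.T)
    masses = np.repeat(system.masses(), 3)
    weight = 1.0 / np.sqrt(np.outer(masses, masses))
    return hess * weight


def mode_frequencies(hessian_mw: np.ndarray, n_rigid: int = 6) -> np.ndarray:
    """Vibrational wavenumbers (cm^-1) from a mass-weighted Hessian.

    The ``n_rigid`` eigenvalues of smallest magnitude are dropped as
    translation/rotation. Negative eigenvalues map to negative wavenumbers
    (imaginary modes) so callers can count and exclude them.
    """
    eigvals = np.linalg.eigvalsh(hessian_mw)
    order = np.argsort(np.abs(eigvals))
    kept = eigvals[order[n_rigid:]]
    # eigenvalue units: kcal/(mol A^2 amu) -> s^-2
    conv = KCAL_PER_MOL_TO_J / (AMU_TO_KG * ANGSTROM_TO_M**2)
    omega = np.sign(kept) * np.sqrt(np.abs(kept) * conv)
    return np.sort(omega / (2.0 * np.pi * C_CM))


def inertia_tensor(system: MolecularSystem, coords: np.ndarray) -> np.ndarray:
    """Inertia tensor about the centre of mass, amu*A^2."""
    m = system.masses()
    com = (coords * m[:, None]).sum(axis=0) / m.sum()
    x = coords - com
    tensor = np.zeros((3, 3))
    for mi, xi in zip(m, x):
        tensor += mi * (np.dot(xi, xi) * np.eye(3) - np.outer(xi, xi))
    return tensor


def entropy_from_modes(
    frequencies_cm: np.ndarray,
    mass_amu: float,
    inertia: np.ndarray,
    temperature: float = TEMPERATURE,
    pressure_atm: float = PRESSURE_ATM,
    symmetry_number: int = 1,
    max_imaginary_fraction: float = 0.25,
) -> EntropyResult:
    """Assemble S_trans + S_rot + S_vib from modes and rigid-body data.

    Imaginary (negative) modes are excluded with a logged count; more than
    ``max_imaginary_fraction`` of them raises :class:`EntropyQualityError`.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    freqs = np.asarray(frequencies_cm, dtype=float)
    imaginary = freqs[freqs <= 0.0]
    real = freqs[freqs > 0.0]
    if len(freqs) and len(imaginary) / len(freqs) > max_imaginary_fraction:
        raise EntropyQualityError(
            f"{len(imaginary)}/{len(freqs)} imaginary modes"
        )
    if len(imaginary):
        log.info("excluding %d imaginary modes from S_vib", len(imaginary))

    kT = sc.k * temperature
    # Sackur-Tetrode, 1 atm standard state
    m_kg = mass_amu * AMU_TO_KG
    p = pressure_atm * sc.atm
    lam3 = (2.0 * np.pi * m_kg * kT / sc.h**2) ** 1.5
    s_trans = R_CAL * (np.log(lam3 * kT / p) + 2.5)

    # classical rigid rotor (nonlinear)
    evals = np.linalg.eigvalsh(np.asarray(inertia, dtype=float))
    evals_si = np.clip(evals, 0.0, None) * AMU_TO_KG * ANGSTROM_TO_M**2
    rot_const = 8.0 * np.pi**2 * kT / sc.h**2
    if np.all(evals_si > 0):
        z_rot = (np.sqrt(np.pi) / symmetry_number) * np.sqrt(
            rot_const**3 * np.prod(evals_si)
        )
        s_rot = R_CAL * (np.log(z_rot) + 1.5)
    elif np.count_nonzero(evals_si > 0) == 2:  # linear molecule
        i_val = evals_si[evals_si > 0].mean()
        s_rot = R_CAL * (np.log(rot_const * i_val / symmetry_number) + 1.0)
    else:
        s_rot = 0.0

    # quantum harmonic oscillator
    s_vib = 0.0
    for nu in real:
        x = sc.h * nu * C_CM / kT
        s_vib += R_CAL * (x / np.expm1(x) - np.log1p(-np.exp(-x)))

    return EntropyResult(
        s_trans=float(s_trans),
        s_rot=float(s_rot),
        s_vib=float(s_vib),
        temperature=temperature,
        frequencies_cm=freqs,
        n_imaginary=len(imaginary),
    )


def molecule_entropy(
    system: MolecularSystem,
    snapshot: Snapshot | np.ndarray,
    temperature: float = TEMPERATURE,
    symmetry_number: int = 1,
) -> EntropyResult:
    """End-to-end entropy of one molecule at one (near-minimum) geometry."""
    coords = (
        snapshot.coordinates if isinstance(snapshot, Snapshot) else np.asarray(snapshot)
    )
    n_rigid = 5 if _is_linear(coords) else 6
    hess = mass_weighted_hessian(system, coords)
    freqs = mode_frequencies(hess, n_rigid=n_rigid)
    return entropy_from_modes(
        freqs,
        mass_amu=float(system.masses().sum()),
        inertia=inertia_tensor(system, coords),
        temperature=temperature,
        symmetry_number=symmetry_number,
    )


def _is_linear(coords: np.ndarray, tol: float = 1e-8) -> bool:
    if len(coords) < 3:
        return True
    centered = coords - coords.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    return bool(svals[1] < tol * max(svals[0], 1.0))
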