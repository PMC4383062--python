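"""Shared fixtures: tiny hand-built systems and the designed toy complex."""

from __future__ import annotations

import numpy as np
import pytest

from pbsakit.structure import (
    AtomRecord,
    BondTerm,
    MolecularSystem,
    ParameterSet,
    Snapshot,
)
from pbsakit.pipeline import MMPBSAConfig
from pbsakit.solvation import PBGridConfig
from pbsakit.synthetic import build_complex, default_recipe, generate_trajectory


def make_atom(
    serial=1,
    name="CA",
    element="C",
    residue_name="ALA",
    residue_seq=1,
    chain_id="A",
    position=(0.0, 0.0, 0.0),
    charge=0.0,
    rmin_half=1.908,
    epsilon=0.1094,
    mass=12.01,
):
    return AtomRecord(
        serial=serial,
        name=name,
        element=element,
        residue_name=residue_name,
        residue_seq=residue_seq,
        chain_id=chain_id,
        position=np.asarray(position, dtype=float),
        charge=charge,
        lj_rmin_half=rmin_half,
        lj_epsilon=epsilon,
        mass=mass,
    )


def shrake_rupley(coords, radii, probe=1.4, npts=2000):
    """Numerical surface-sampling SASA oracle (golden-spiral points)."""
    coords = np.asarray(coords, dtype=float)
    i = np.arange(npts)
    phi = np.arccos(1 - 2 * (i + 0.5) / npts)
    theta = np.pi * (1 + 5**0.5) * i
    sph = np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], 1
    )
    expanded = np.asarray(radii) + probe
    per = np.zeros(len(coords))
    for a in range(len(coords)):
        pts = coords[a] + expanded[a] * sph
        ok = np.ones(npts, bool)
        for b in range(len(coords)):
            if b == a:
                continue
            ok &= ((pts - coords[b]) ** 2).sum(1) > expanded[b] ** 2
        per[a] = 4 * np.pi * expanded[a] ** 2 * ok.mean()
    return per


@pytest.fixture(scope="session")
def toy_recipe():
    return default_recipe(n_frames=300, seed=2024)


@pytest.fixture(scope="session")
def toy_complex(toy_recipe):
    """(system, reference snapshot, template parameter set)."""
    return build_complex(toy_recipe)


@pytest.fixture(scope="session")
def toy_trajectory(toy_recipe, toy_complex):
    system, ref, _ = toy_complex
    return generate_trajectory(system, ref, toy_recipe)


@pytest.fixture(scope="session")
def met_scan(toy_trajectory, toy_complex, fast_config):
    """Alanine scan of the designed buried MET, on a 5-frame subsample."""
    from pbsakit.alascan import scan_residue

    _, _, params = toy_complex
    return scan_residue(
        toy_trajectory, {"A"}, {"B"}, ("B", 3, "MET"),
        config=fast_config, params=params, frames=[0, 60, 120, 180, 240],
    )


@pytest.fixture(scope="session")
def fast_config():
    """PB grid coarse enough for desk-scale test runs."""
    return MMPBSAConfig(pb=PBGridConfig(spacing=0.8, margin=5.0))


@pytest.fixture()
def dipeptide():
    """Two-residue single-chain toy with full backbone names."""
    atoms = []
    serial = 0
    for seq in (1, 2):
        x0 = 3.8 * (seq - 1)
        for name, element, off in (
            ("N", "N", (0.0, 0.0, 0.0)),
            ("CA", "C", (1.3, 0.0, 0.0)),
            ("C", "C", (2.5, 0.0, 0.0)),
            ("O", "O", (2.5, -1.2, 0.0)),
            ("CB", "C", (1.3, 1.5, 0.0)),
        ):
            serial += 1
            atoms.append(
                make_atom(
                    serial=serial,
                    name=name,
                    element=element,
                    residue_seq=seq,
                    position=(x0 + off[0], off[1], off[2]),
                )
            )
    return MolecularSystem(atoms=atoms)


@pytest.fixture()
def born_ion():
    """Single +1e charge of radius 2.0 A."""
    a = make_atom(name="X", element="X", residue_name="ION",
                  charge=1.0, rmin_half=2.0, epsilon=0.1, mass=40.0)
    return MolecularSystem(atoms=[a])
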