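"""Computational alanine scanning: mutant generation on existing frames,
per-term binding double-differences and hot/warm/null classification.

For each scanned residue the side chain is truncated to alanine on every
frame of the wild-type trajectory (no re-sampling, no repacking), the
single-trajectory binding terms are recomputed for the mutant, and

    ddG(term) = dG_wild(term) - dG_mutant(term)

is averaged over frames. On this scale a more-negative subtotal marks a
residue whose side chain contributes more to binding: hot spot at
<= -4 kcal/mol, warm spot in (-4, -2], otherwise null. Glycine and proline
are excluded (their backbone conformational role makes the truncation
ill-posed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import GLY_PRO, HOT_SPOT_THRESHOLD, WARM_SPOT_THRESHOLD
from .energy import NonbondedTables, interaction_energy
from .pipeline import MMPBSAConfig
from .solvation import fd_pb_solve, lcpo_sasa
from .structure import (
    MolecularSystem,
    Trajectory,
    split_complex,
    truncate_to_alanine,
)

__all__ = [
    "AlaScanRecord",
    "classify",
    "scan_residue",
    "scan_interface",
    "scan_table",
]


@dataclass
class AlaScanRecord:
    """Per-term binding double-differences for one alanine substitution."""

    residue_key: tuple
    side: str  # receptor | ligand
    dd_e_vdw: float = 0.0
    dd_e_ele: float = 0.0
    dd_g_np: float = 0.0
    dd_g_pb: float = 0.0
    classification: str = "null"

    @property
    def dd_e_gas(self) -> float:
        return self.dd_e_vdw + self.dd_e_ele

    @property
    def dd_g_solv(self) -> float:
        return self.dd_g_np + self.dd_g_pb

    @property
    def dd_g_subtotal(self) -> float:
        return self.dd_e_gas + self.dd_g_solv


def classify(dd_g_subtotal: float, residue_name: str) -> str:
    """hot <= -4 < warm <= -2 < null; GLY/PRO always excluded."""
    if residue_name.upper() in GLY_PRO:
        return "excluded"
    if not np.isfinite(dd_g_subtotal):
        raise ValueError("non-finite ddG subtotal")
    if dd_g_subtotal <= HOT_SPOT_THRESHOLD:
        return "hot"
    if dd_g_subtotal <= WARM_SPOT_THRESHOLD:
        return "warm"
    return "null"


def _binding_terms(system, rec_idx, lig_idx, coords, tables, pb_cfg, gamma, probe,
                   rec_sys, lig_sys):
    """Single-trajectory per-frame binding deltas (vdw, ele, np, pb)."""
    e_vdw, e_ele = interaction_energy(system, rec_idx, lig_idx, coords, tables)
    g_pb = (
        fd_pb_solve(system, coords, pb_cfg)
        - fd_pb_solve(rec_sys, coords[rec_idx], pb_cfg)
        - fd_pb_solve(lig_sys, coords[lig_idx], pb_cfg)
    )
    sasa_c, _ = lcpo_sasa(system, coords, probe)
    sasa_r, _ = lcpo_sasa(rec_sys, coords[rec_idx], probe)
    sasa_l, _ = lcpo_sasa(lig_sys, coords[lig_idx], probe)
    g_np = gamma * (sasa_c - sasa_r - sasa_l)
    return e_vdw, e_ele, g_np, g_pb


def scan_residue(
    trajectory: Trajectory,
    receptor_chains,
    ligand_chains,
    residue_key: tuple,
    config: MMPBSAConfig | None = None,
    params=None,
    frames=None,
) -> AlaScanRecord:
    """Alanine-scan one residue over the trajectory's frame window.

    GLY/PRO targets return an ``excluded`` record without energies. A
    residue already alanine-like yields exact zeros (identity control).
    """
    config = config or MMPBSAConfig()
    system = trajectory.system
    rec_chain_set = set(receptor_chains)
    side = "receptor" if residue_key[0] in rec_chain_set else "ligand"
    if residue_key[2].upper() in GLY_PRO:
        return AlaScanRecord(residue_key, side, classification="excluded")

    mutation = truncate_to_alanine(system, residue_key, params=params)
    frame_ids = trajectory.frame_window(
        frames if frames is not None else config.frame_window
    )
    if mutation.identical:
        return AlaScanRecord(residue_key, side, classification="null")

    rec_sys, lig_sys, rec_idx, lig_idx = split_complex(
        system, receptor_chains, ligand_chains
    )
    mut = mutation.system
    m_rec_sys, m_lig_sys, m_rec_idx, m_lig_idx = split_complex(
        mut, receptor_chains, ligand_chains
    )
    wt_tab = NonbondedTables.from_system(system)
    mut_tab = NonbondedTables.from_system(mut)
    # one grid covering both topologies (mutant atoms are a subset plus a cap
    # hydrogen on the CB-Cgamma axis, safely inside the wild-type envelope)
    pb_cfg = config.pb.pinned_to(
        trajectory.snapshots[frame_ids[0]].coordinates, system.radii()
    )
    dd = np.zeros((len(frame_ids), 4))
    for row, f in enumerate(frame_ids):
        coords = trajectory.snapshots[f].coordinates
        wild = _binding_terms(
            system, rec_idx, lig_idx, coords, wt_tab, pb_cfg,
            config.gamma, config.probe_radius, rec_sys, lig_sys,
        )
        mcoords = mutation.map_coordinates(coords)
        mutant = _binding_terms(
            mut, m_rec_idx, m_lig_idx, mcoords, mut_tab, pb_cfg,
            config.gamma, config.probe_radius, m_rec_sys, m_lig_sys,
        )
        dd[row] = np.array(wild) - np.array(mutant)
    mean = dd.mean(axis=0)
    rec = AlaScanRecord(
        residue_key=residue_key,
        side=side,
        dd_e_vdw=float(mean[0]),
        dd_e_ele=float(mean[1]),
        dd_g_np=float(mean[2]),
        dd_g_pb=float(mean[3]),
    )
    rec.classification = classify(rec.dd_g_subtotal, residue_key[2])
    return rec


def scan_interface(
    trajectory: Trajectory,
    receptor_chains,
    ligand_chains,
    residue_keys,
    config: MMPBSAConfig | None = None,
    params=None,
    frames=None,
) -> tuple[list[AlaScanRecord], dict[str, int]]:
    """Scan a candidate list; returns records plus hot/warm counts per side.

    Candidates are typically pre-filtered at the per-residue decomposition
    cutoff (<= -1 kcal/mol); GLY/PRO entries come back ``excluded``.
    """
    records = [
        scan_residue(
            trajectory, receptor_chains, ligand_chains, key,
            config=config, params=params, frames=frames,
        )
        for key in residue_keys
    ]
    summary = {
        "hot_receptor": sum(
            1 for r in records if r.side == "receptor" and r.classification == "hot"
        ),
        "hot_ligand": sum(
            1 for r in records if r.side == "ligand" and r.classification == "hot"
        ),
        "warm_receptor": sum(
            1 for r in records if r.side == "receptor" and r.classification == "warm"
        ),
        "warm_ligand": sum(
            1 for r in records if r.side == "ligand" and r.classification == "warm"
        ),
        "excluded": sum(1 for r in records if r.classification == "excluded"),
    }
    return records, summary


def scan_table(records: list[AlaScanRecord]) -> pd.DataFrame:
    """Tabulate scan records with the standard per-term column layout."""
    rows = []
    for r in records:
        rows.append(
            {
                "residue": f"{r.residue_key[2]}{r.residue_key[1]}",
                "chain": r.residue_key[0],
                "side": r.side,
                "ddE_vdw": round(r.dd_e_vdw, 2),
                "ddE_electrostatic": round(r.dd_e_ele, 2),
                "ddE_gas": round(r.dd_e_gas, 2),
                "ddG_sol_nonpol": round(r.dd_g_np, 2),
                "ddG_sol_PB": round(r.dd_g_pb, 2),
                "ddG_solvation": round(r.dd_g_solv, 2),
                "ddG_subtotal": round(r.dd_g_subtotal, 2),
                "class": r.classification,
            }
        )
    return pd.DataFrame(rows)
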