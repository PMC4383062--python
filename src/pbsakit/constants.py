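"""Physical constants and shared conventions.

Units used throughout the package: lengths in Angstrom, energies in
kcal/mol, charges in elementary-charge units, masses in amu, angles in
radians internally (degrees at file/CLI boundaries), temperatures in K.
"""

from __future__ import annotations

import scipy.constants as _sc

#: Coulomb constant in kcal*Angstrom/(mol*e^2).
COULOMB_CONSTANT = 332.0636

#: Default interior (solute) and exterior (solvent) relative permittivities
#: for the Poisson-Boltzmann term.
EPSILON_SOLUTE = 1.0
EPSILON_SOLVENT = 80.0

#: Surface-tension coefficient gamma of the nonpolar solvation term,
#: kcal/(mol*Angstrom^2).
GAMMA_NONPOLAR = 0.0072

#: Water-probe radius for solvent-accessible surface area, Angstrom.
PROBE_RADIUS = 1.4

#: Hydrogen-bond geometric criteria: donor-heavy-atom to acceptor distance
#: ceiling (Angstrom) and donor-hydrogen-acceptor angle floor (degrees).
HBOND_DISTANCE_CUTOFF = 3.5
HBOND_ANGLE_CUTOFF = 120.0

#: Heavy-atom distance defining a hydrophobic contact, Angstrom.
CONTACT_CUTOFF = 4.5

#: 1-4 nonbonded scaling divisors (ff03-style convention).
SCEE = 1.2  # electrostatic divisor
SCNB = 2.0  # Lennard-Jones divisor

#: Alanine-scanning classification thresholds, kcal/mol, on the scale where
#: a more-negative double-difference marks a more important residue.
HOT_SPOT_THRESHOLD = -4.0
WARM_SPOT_THRESHOLD = -2.0

#: Per-residue decomposition importance cutoff, kcal/mol.
DECOMP_CUTOFF = -1.0

#: Default simulation temperature (K) and pressure (atm) for entropy terms.
TEMPERATURE = 300.0
PRESSURE_ATM = 1.0

#: Backbone atom names; everything else in a residue counts as side chain.
BACKBONE_ATOM_NAMES = frozenset(
    {"N", "H", "HN", "H1", "H2", "H3", "CA", "HA", "HA2", "HA3", "C", "O", "OXT"}
)

#: Standard C(beta)-H bond length used when capping a truncated side chain.
CB_H_BOND_LENGTH = 1.09

# --- unit conversions for normal-mode analysis ---

#: kcal/mol -> J
KCAL_PER_MOL_TO_J = 4184.0 / _sc.Avogadro
#: amu -> kg
AMU_TO_KG = _sc.atomic_mass
#: Angstrom -> m
ANGSTROM_TO_M = 1e-10
#: Gas constant in cal/(mol*K) (entropies are conventionally reported in cal).
R_CAL = _sc.R / 4.184
#: Speed of light in cm/s, for wavenumber conversion.
C_CM = _sc.c * 100.0

GLY_PRO = frozenset({"GLY", "PRO"})
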