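# Methods

This note records the models, conventions and numerical choices behind
`pbsakit`, in the spirit of a package methods appendix. Units throughout:
Å, kcal/mol, elementary charges, amu, K; angles are degrees at file and CLI
boundaries and radians internally.

## Scope and protocol

The package implements the *post-processing* layer of an MM-PBSA study. It
does not run molecular dynamics: trajectories arrive as multi-MODEL PDB (or
from the synthetic generator), and every energy is re-evaluated on those
frames. The default protocol is **single-trajectory**: receptor and ligand
coordinates are sliced out of the complex frames, so bonded (internal)
energies cancel identically in the binding difference — the pipeline asserts
`ΔE_int = 0` on every frame — and the gas-phase binding delta reduces to the
cross receptor–ligand van der Waals and Coulomb sums. Nothing prevents the
caller from supplying separately generated species trajectories and
differencing the absolute `g_cal` columns (a three-trajectory analysis), but
the single-trajectory route is the default and the only one the helper
functions automate.

Snapshot statistics are reported as mean ± standard error, with the
standard error defined as sample standard deviation / √N_frames.

## Force-field conventions (gas phase)

- Harmonic bonds and angles use `E = k(Δx)²` — the AMBER parameter-file
  convention, with the factor of two inside `k`. The test suite pins this by
  checking `dE/dr = 2kΔr` against finite differences.
- Torsions: `E = (V/2)(1 + cos(nφ − γ))`.
- Lennard-Jones in Rmin/ε form: `Rmin_ij = Rmin_i/2 + Rmin_j/2`,
  `ε_ij = √(ε_i ε_j)`.
- Coulomb constant `k_C = 332.0636 kcal·Å/(mol·e²)`.
- Exclusions from the bond graph: 1–2 and 1–3 excluded; 1–4 divided by 1.2
  (electrostatic) and 2.0 (Lennard-Jones). Both divisors are arguments of
  `NonbondedTables.from_system`. No distance cutoff anywhere: these are
  post-processing energies on finite solute coordinates, not a periodic
  simulation.
- Parameters come from a package-owned TSV (documented in
  `read_parameters`): per-(residue, atom-name) templates for charge, Rmin/2,
  ε and mass, plus explicit per-system bond/angle/torsion records. The same
  Rmin/2 values double as the atomic radii for the PB dielectric boundary
  and for SASA; the radius provenance is thereby fixed and recorded in the
  parameter file itself.

## Poisson–Boltzmann solver

The polar solvation term solves the zero-ionic-strength linearized PB
equation — i.e. a variable-dielectric Poisson problem — by finite
differences on a uniform grid:

- ε = 1 inside the union of atomic spheres (Rmin/2 radii), ε = 80 outside,
  assigned per grid edge at the edge midpoint. Both values are configurable.
- Charges are spread to the eight surrounding nodes trilinearly.
- Dirichlet boundary potentials are Coulombic sums over all solute charges
  screened by the exterior dielectric (Debye–Hückel at zero salt). Summing
  per atom rather than using a single monopole keeps the boundary sensible
  for net-neutral solutes.
- The linear system is solved by red–black successive over-relaxation with
  the model-problem optimal relaxation factor `ω = 2/(1 + sin(π/n))`;
  iteration stops when the largest potential update in a sweep falls below
  `tolerance` (default 5·10⁻⁵ kcal/(mol·e)), and a `ConvergenceError`
  reports the final residual otherwise (default cap 20 000 sweeps).
- The reported energy is the reaction-field energy
  `½Σ qᵢ(φ_solv − φ_vac)(rᵢ)`, with the vacuum reference solved on the same
  grid with the same charge spreading so the grid self-energy cancels
  exactly.

Default spacing is 0.4 Å with a 7 Å margin. Against the analytic Born ion
the solver lands within ~1.5 % at 0.4 Å (the test suite bounds it at 5 %,
and at 2 % for 0.25 Å), and halving the spacing moves the result
monotonically toward the closed form on the Born fixture. For differences
(binding deltas, alanine ΔΔ), all species are solved on one grid pinned to
the complex (`PBGridConfig.pinned_to`) so placement artifacts cancel; the
translation-invariance test bounds the residual artifact at 1 %. Toy-scale
pipeline runs in the tests and the acceptance script use 0.8 Å spacing with
a 5 Å margin to keep a full scan in seconds — a deliberate desk-scale
problem size, since the designed signals (several kcal/mol) are far above
the coarser grid's noise.

## SASA and the nonpolar term

SASA uses the LCPO (linear combination of pairwise overlaps) functional
form: per atom, `A_i = P1·S_i + P2·ΣA_ij + P3·ΣΣA_jk + P4·Σ(A_ij·ΣA_jk)`
over solvent-expanded spheres (probe 1.4 Å), clamped at zero. The shipped
coefficient set is the *exact two-body* one, `(P1, P2, P3, P4) =
(1, −1, 0, 0)`: an isolated atom returns its full accessible sphere area and
a two-sphere system is analytically exact (the tests verify it against a
surface-sampling oracle). Published per-atom-type fitted coefficients are
keyed to full force-field atom typing, which the reduced toy representation
does not carry; the parameter dictionary is configurable per element for
callers who have such typing. The known cost of the exact two-body set is
over-subtraction in dense multi-overlap packings — deeply coordinated atoms
clamp to zero, so *absolute* SASA of a tightly packed core is
underestimated while surface and interface (buried-area) differences remain
the meaningful quantities. The nonpolar term is `γ·SASA` with
γ = 0.0072 kcal/(mol·Å²) and no additive offset.

## Normal-mode entropy

The Hessian is assembled by central finite differences (step 10⁻⁴ Å) of the
total MM energy, symmetrised and mass-weighted; the six (five for linear
molecules) smallest-magnitude eigenvalues are discarded as rigid-body
modes. Entropy components at T = 300 K, 1 atm: Sackur–Tetrode translation,
classical rigid-rotor rotation (symmetry number configurable, default 1),
and the quantum harmonic oscillator sum for vibration. Imaginary modes are
excluded with a logged count; more than 25 % imaginary raises a quality
error, since that indicates the geometry is nowhere near a minimum.
Pre-minimisation is the caller's responsibility — the package's MD-free
scope means it ships no minimiser — and the entropy term is therefore *off
by default* in the snapshot pipeline (`include_entropy=False`); it is
intended for small, near-minimum species or for attaching an externally
computed −TΔS to the report. The O((3N)²) finite-difference Hessian is
practical to a few dozen atoms, which covers the package's fixtures.

## Alanine scanning

Mutants are generated on the existing frames (no re-sampling, no
repacking): all side-chain atoms beyond Cβ are removed, Cβ takes the
alanine-template parameters, and one cap hydrogen is placed along the
removed Cβ→Cγ unit vector at 1.09 Å — recomputed per frame, since the
direction moves with the trajectory. The mutated residue's charge set is
the alanine template's (backbone charges untouched); this is one documented
choice among several defensible charge-redistribution schemes. Glycine
(no side chain to represent) and proline (backbone conformation not
alanine-like) are excluded and come back as `excluded` records.

`ΔΔG(term) = ΔG_wild(term) − ΔG_mutant(term)`, averaged over frames. On
this scale a residue whose side chain stabilises binding scores negative.
Classification: hot ≤ −4.0 kcal/mol (the −4.0 boundary resolves to hot),
warm in (−4.0, −2.0], else null. Candidate lists are typically pre-filtered
at the per-residue decomposition cutoff (≤ −1.0 kcal/mol); the CLI's
`--residues auto` applies exactly that filter.

## Per-residue decomposition

Each cross-interface atom-pair energy (vdW and Coulomb) is split evenly
between its two atoms, the polar delta `ΔG_PB` is apportioned by per-atom
|charge|, and the nonpolar delta by each atom's buried accessible area
(species minus complex). Summing the per-residue totals over *both* sides
therefore reconstructs the full binding delta `Δg_cal` exactly (the tests
bound the identity at 10⁻³ kcal/mol) — note this half-share convention
differs from decomposition schemes that assign each residue its full pair
interaction and hence double-count across sides. Backbone/side-chain shares
partition by atom name (N, H, CA, HA, C, O and terminal variants are
backbone). The importance flag is `ΔG_total ≤ −1.0 kcal/mol`.

## Trajectory descriptors

- Superposition is the SVD-based optimal least-squares rigid fit with the
  determinant correction that forbids reflections; weights are supported.
- RMSD series default to the backbone (CA, N, O) selection against the
  first frame (standing in for a minimized initial structure when none is
  supplied); RMSF is per-residue Cα displacement about the *starting
  structure* (not the trajectory mean — configurable via `reference`).
- Hydrogen bonds: donors are N/O/S heavy atoms with a bonded hydrogen
  (taken from the bond records); acceptors are N/O/S heavy atoms. A frame
  qualifies when donor–acceptor distance ≤ 3.5 Å *and* donor–H–acceptor
  angle ≥ 120°. Occupancy is the qualifying-frame percentage of the window;
  distances are reported as mean ± SD over qualifying frames. Classes:
  strong > 75 %, medium 50–75 % inclusive at both boundaries, weak < 50 %.
- Hydrophobic contacts list cross-interface residue pairs with any
  heavy-atom pair within 4.5 Å (optionally carbon/sulfur only).

## The synthetic complex generator

The generator emulates, at toy scale, a kinase-like receptor with a short
peptide bound along one face: two parallel chains (3.8 Å residue spacing,
8.3 Å backbone separation), reduced residues (backbone N, H, CA, C, O plus
0–3 side-chain pseudo-atoms) with a shipped parameter table, and designed
features placed by direct coordinate construction:

- **Hydrogen bonds** — a serine-like side-chain donor over a glycine
  acceptor whose carbonyl O is flipped toward the interface; built
  collinear at 2.9 Å so the reference frame satisfies the 3.5 Å/120°
  criteria with margin. Target occupancies are hit by *deterministic frame
  interleaving* (breaking the bond by a 2.5 Å out-of-plane side-chain
  displacement in a scheduled fraction of frames), not Bernoulli draws, so
  divisible frame counts hit the target exactly and jitter perturbs it by
  well under the ±2 % test band.
- **A buried hydrophobic residue** — a methionine-like side chain whose SD
  sits 3.8 Å from three pocket C-betas arranged around it; the SD/pocket ε
  values are chosen so the contact is worth several kcal/mol of vdW, making
  the residue a designed hot spot with ΔΔE_vdw dominant.
- **A charge pair** — ±0.25 e on facing C-betas at 3.9 Å, for designed
  electrostatics.
- **Fluctuation structure** — per-region isotropic Gaussian jitter
  (defaults: core σ = 0.12 Å, loop σ = 0.35 Å), giving the loop-vs-core
  RMSF contrast; for uniform σ the per-atom RMSF follows the σ√3 closed
  form up to the rigid-body-fit deflation (3N−6)/3N.

Everything is deterministic given the recipe seed. What the generator does
*not* emulate: realistic backbone dihedral geometry, water, counter-ions,
conformational transitions, or any absolute-energy realism — its force
field is a device for making designed features recoverable, so passing
tests demonstrate the *machinery* (energy bookkeeping, classification,
occupancy counting) rather than predictive accuracy on real proteins.

The repository also carries transcriptions of the published binding-energy,
hydrogen-bond and alanine-scan tables of the study this package
operationalises, as `load_printed_fixture("table1"|"table2"|"table3")`.
Cells whose printed values are internally inconsistent (e.g. a duplicated
receptor G_PB cell, a gas-phase row that disagrees with its own components
by 0.31, two apparent digit transpositions and one lost minus sign) are
transcribed verbatim and flagged; replay tests assert the aggregation
arithmetic only on unflagged cells. The original MD trajectories are not
deposited anywhere, so absolute re-computation of those tables from
structures is out of reach by construction; the replays validate the
aggregation and classification layers, which is all they claim.

## Problem sizes

Test and acceptance runs use the desk-scale settings deliberately: the
8+5-residue designed complex (87 atoms), 300-frame trajectories for
occupancy/RMSF statistics, 2–5-frame subsamples for PB-bearing pipeline
stages at 0.8 Å grid spacing, and the Born/two-sphere/diatomic fixtures for
kernel oracles. These sizes keep the full suite and the acceptance script
in the minutes range while leaving every designed signal an order of
magnitude above numerical noise.

## Known limitations

- Linearized, zero-salt PB only; no nonlinear term, ionic strength,
  membrane slabs or generalized-Born alternative.
- The exact two-body LCPO coefficients underestimate absolute SASA in dense
  cores (see above); per-type fitted coefficients can be supplied but are
  not shipped.
- The finite-difference Hessian limits normal-mode entropy to small
  species, and entropies are only meaningful near minima the caller must
  provide.
- Alanine-scan charge handling uses the alanine template without
  redistributing any residual net-charge difference over the backbone.
- The toy force field omits torsions and most angles by default (bond
  terms carry the exclusions topology); bonded-energy machinery is
  exercised by dedicated fixtures instead.
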