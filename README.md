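# pbsakit

Engine-free MM-PBSA binding energetics for protein–peptide complexes:
binding free energies with per-residue decomposition, computational alanine
scanning with hot/warm-spot classification, and the trajectory descriptors
(RMSD, RMSF, hydrogen-bond occupancy, hydrophobic contacts) that usually
accompany them.

`pbsakit` is aimed at structural bioinformaticians who have snapshots of a
receptor–peptide complex (multi-MODEL PDB plus a plain-text parameter table)
and want the *post-processing* half of an MM-PBSA study — the energy
re-evaluation, aggregation, decomposition and classification — without
depending on a molecular-dynamics engine. A synthetic-complex generator with
designed hydrogen bonds, a buried hydrophobic pocket residue and
region-dependent positional jitter makes every pipeline stage testable at
desk scale.

## The model

Binding free energy per snapshot, averaged over frames:

```
ΔG_bind = ΔE_gas + ΔG_sol − TΔS
ΔE_gas  = ΔE_int + ΔE_vdw + ΔE_ele          (ΔE_int ≡ 0, single-trajectory)
ΔG_sol  = ΔG_PB + ΔG_nonpol,   ΔG_nonpol = γ·ΔSASA,   γ = 0.0072 kcal/(mol·Å²)
```

- **Gas phase:** AMBER-style molecular mechanics — harmonic bonds/angles
  `k(Δx)²`, periodic torsions `(V/2)(1+cos(nφ−γ))`, 12-6 Lennard-Jones and
  Coulomb (k_C = 332.0636 kcal·Å/mol·e²) with 1–2/1–3 exclusions and 1–4
  scaling (ee/1.2, vdW/2.0), no cutoff.
- **Polar solvation:** finite-difference linearized Poisson–Boltzmann at zero
  ionic strength, ε_in = 1, ε_out = 80, reaction-field energy from matched
  solvated/vacuum grid solves (grid self-energy cancels).
- **Nonpolar solvation:** γ·SASA with SASA from a linear combination of
  pairwise overlaps (LCPO).
- **Entropy:** −TΔS from normal modes — Sackur–Tetrode translation,
  rigid-rotor rotation, quantum-harmonic-oscillator vibration at 300 K.
- **Alanine scanning:** per residue, `ΔΔG = ΔG_bind(wild) − ΔG_bind(mutant)`
  on the wild-type frames, side chain truncated past Cβ with an H cap along
  the Cβ→Cγ direction. Hot spot: ΔΔG ≤ −4 kcal/mol; warm spot:
  −4 < ΔΔG ≤ −2; glycine and proline are excluded.
- **Per-residue decomposition:** cross-interface pair energies split evenly
  between partner residues, |q|-weighted shares of ΔG_PB and buried-area
  shares of ΔG_nonpol; residues at ΔG ≤ −1 kcal/mol are flagged important.
- **Hydrogen bonds:** donor–acceptor ≤ 3.5 Å and donor–H–acceptor ≥ 120°;
  occupancy classes strong (> 75 %), medium (50–75 %), weak (< 50 %).

## Worked example

```python
import pbsakit as pk
from pbsakit.synthetic import default_recipe

recipe = default_recipe(n_frames=300, seed=2024)
system, ref, params = pk.build_complex(recipe)
traj = pk.generate_trajectory(system, ref, recipe)

for b in pk.hbond_occupancy(traj, across_only=True):
    print(f"{b.donor[2]}{b.donor[1]}-{b.donor[3]} -> "
          f"{b.acceptor[2]}{b.acceptor[1]}-{b.acceptor[3]}: "
          f"{b.mean_distance:.3f} ({b.distance_sd:.2f}) A, "
          f"{b.occupancy:.2f}%, {b.strength}")

cfg = pk.MMPBSAConfig(pb=pk.PBGridConfig(spacing=0.8, margin=5.0))
rec = pk.scan_residue(traj, {"A"}, {"B"}, ("B", 3, "MET"),
                      config=cfg, params=params,
                      frames=list(range(0, 300, 60)))
print(f"MET B3 -> ALA: ddE_vdw={rec.dd_e_vdw:.2f}, "
      f"ddG_subtotal={rec.dd_g_subtotal:.2f}, class={rec.classification}")
```

prints

```
SER1-OG -> GLY1-O: 2.914 (0.17) A, 97.00%, strong
SER5-OG -> GLY5-O: 2.907 (0.17) A, 70.00%, medium
MET B3 -> ALA: ddE_vdw=-9.01, ddG_subtotal=-8.96, class=hot
```

The two designed hydrogen bonds come back at their target occupancies (97 %
strong, 70 % medium) with donor–acceptor distances just under the 3.5 Å
cutoff, and truncating the designed pocket methionine costs ~9 kcal/mol of
binding free energy — almost entirely van der Waals — so it is classified a
hot spot, while an alanine→alanine control gives exactly zero.

The same stages are scriptable from the shell: `pbsakit synth`, `pbsakit
run`, `pbsakit decomp`, `pbsakit alascan`, `pbsakit traj
rmsd|rmsf|hbonds|contacts` (see `pbsakit --help`).

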