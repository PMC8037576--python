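# s100b-abeta

Analysis toolkit for the S100B : amyloid-beta-42 chaperone–client
interaction, built for structural bioinformaticians who want to run the
complete desk-scale analysis layer of that system — interface profiling,
contact mapping, binding energetics and aggregation kinetics — without
needing microsecond MD trajectories or plate-reader data: every input can be
generated synthetically with known ground truth.

S100B is an astrocytic Ca²⁺-binding protein that acts as a holdase-type
chaperone, delaying aggregation of the amyloid-beta peptide (Aβ42) by
binding its monomers at a cleft between the two protomers of the S100B
dimer. The Aβ 25–35 segment (carrying Lys28 and the hydrophobic
Ile31/Ile32/Met35 stretch) is the core client epitope. This package
implements the quantitative protocols used to characterize such a complex:

* **SASA** — Shrake–Rupley solvent-accessible surface area on a
  deterministic spherical Fibonacci lattice (probe 0.14 nm, 960 points by
  default, hydrogens excluded).
* **Interfacial area** — ½[(SASA_A,alone − SASA_A,complex) +
  (SASA_B,alone − SASA_B,complex)], the both-surface average of the area
  each partner buries on binding.
* **SAS^hydro index** — per-residue interfacial SASA weighted by the
  Wimley–White interface hydrophobicity score; positive values flag
  hydrophilic contributions (e.g. Lys28), negative values hydrophobic ones
  (Ile31/Ile32/Met35). Time series use a trailing floating window and
  equilibrium averages discard the first 55% of each replicate, with errors
  reported as the SEM over replicate means.
* **Contact persistence** — minimum distance from a probe atom (the Lys28
  sidechain) to every receptor residue; a 0.6 nm screen discards weak
  interactions, persistence is the fraction of equilibrated frames within
  0.35 nm (thresholds inclusive), and distances pooled over replicates give
  probability densities.
* **Helical content** — Kabsch–Sander hydrogen-bond energies
  (E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol) with the
  minimal-α-helix rule (two consecutive i→i+4 bonds below −0.5 kcal/mol).
* **MM-PBSA** — single-trajectory binding decomposition
  ΔG = ΔE_coul + ΔE_vdw + ΔSolv_polar + ΔSolv_apolar, with vacuum Coulomb
  and Lennard-Jones terms, a finite-difference linearized Poisson–Boltzmann
  solver (solute dielectric 4, solvent 78.4, 0.1 M ionic strength, Stern
  layer 0.2 nm, Debye–Hückel boundaries) and a γ·SASA apolar term.
* **Aggregation kinetics** — ThT-curve normalization, t_1/2 (interpolated
  50% crossing), t_lag (highest measured time below 10% fibrillar mass),
  Δt_1/2 against a control, and fits of the secondary-nucleation-dominated
  model via its effective rates κ = √(2k₊k₂m₀^(n₂+1)) and
  λ = √(2k₊k_n m₀^(n_c)).

## Worked example

Generate the synthetic study system — a 43-residue S100B-like helical
receptor (residues 49–91, Met79/Thr82/Glu86 at their canonical positions)
against the full Aβ42 peptide built helical, three 50-frame replicate
pseudo-trajectories plus control/inhibited ThT traces — then run the
numbered analyses:

```bash
python analysis/01_build_inputs.py --seed 1
python analysis/02_interface_profile.py
python analysis/03_contact_map.py
python analysis/04_binding_energy.py
python analysis/05_aggregation_kinetics.py
```

which prints (abridged):

```
equilibrated interfacial area: 5.55 +/- 0.01 nm^2 (SEM)
SAS^hydro split: hydrophilic +0.61, hydrophobic -0.26 nm^2 kcal/mol
client 25-35 helicity: 1.00 +/- 0.00
residues screened in at 0.6 nm: [74, 75, 78, 79]
MM-PBSA decomposition (kcal/mol, mean +/- SEM over replicate means):
  E_coul         +469.00 +/- 0.99
  E_vdw           -13.41 +/- 0.57
  Solv_polar     -111.80 +/- 0.42
  Solv_apolar      -6.21 +/- 0.01
control: t_half 14542 s, t_lag 10800 s, kappa 7.04e-04 /s
inhibited: t_half 20650 s, t_lag 15200 s, kappa 4.63e-04 /s
inhibition slows aggregation by delta-t_half = 6108 s
```

Reading the numbers: the client core buries a stable ~5.5 nm² interface;
the SAS^hydro split shows the amphiphilic character of the 25–35 epitope
(Lys28 positive against Ile/Met negative); receptor residues 74–79 pass the
0.6 nm Lys28 contact screen; interface burial is favourable in the vdW,
polar-solvation and cavity terms while the vacuum Coulomb term is repulsive
for this reduced rod-rod geometry (two net-acidic partners — see
`docs/methods.md`); and halving the secondary-nucleation rate shifts t_1/2
by ~6100 s, recovered faithfully by the model fit.

The same stages are available as one config-driven command
(`s100b-abeta run pipeline.yaml`) plus per-stage subcommands
(`synth`, `sasa`, `interface`, `contacts`, `helicity`, `mmpbsa`,
`kinetics`, `validate`).

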