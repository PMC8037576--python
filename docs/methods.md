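# Methods

This note records the models, conventions and numerical choices behind the
package, and what the synthetic-data tests do and do not demonstrate.

## Coordinate model and parameters

Coordinates are stored in nanometres (the MD convention; every distance
threshold in the protocol is quoted in nm) and converted to/from angstroms
only at PDB I/O. Residue numbering is 1-based with ranges inclusive at both
ends. The two protomers of a receptor dimer are distinguished by chain ID
rather than by a residue-number offset. Frames of one trajectory must share
an identical atom ordering; no periodic-boundary handling is performed —
frames are assumed whole and clustered, which is a documented limitation of
the analysis layer.

Physical parameters (radius, partial charge, Lennard-Jones σ/ε) attach to
atoms from a TSV table keyed by (residue, atom name), with an element-keyed
radius fallback (charge and LJ default to zero there); lookup precedence is
exact key, then element, then a hard error listing every unresolved atom.
The packaged table is a synthetic united-atom-like set matching the reduced
models below: backbone N/CA/C/O with an amide/carbonyl dipole pattern
(±0.30/±0.45 e) and one pseudo-sidechain sphere per residue whose radius
grows with sidechain bulk and which carries the formal charge of
Asp/Glu/Lys/Arg (the only residues treated as ionized, the physiological-pH
convention). It is not a validated force field; it exists to exercise the
energetics with realistic magnitudes.

## Synthetic study system

The generators replace microsecond MD and plate-reader data at desk scale:

* **Ideal helices** are built by internal-coordinate chain extension
  (bond 0.1458/0.1525/0.1329 nm, angles 111.2°/116.2°/121.7°, ω = 180°)
  with uniform (φ, ψ); the default (−57°, −47°) yields 0.380 nm CA–CA
  steps and ≈0.158 nm rise per residue, and (−120°, 120°) an extended
  strand. One pseudo-sidechain sphere sits at the Cβ position; rotamers are
  out of scope.
* **The default complex** pairs a 43-residue S100B-like helix (numbered
  49–91 so the binding-cleft triad Met79/Thr82/Glu86 keeps its canonical
  numbers) with the 42-residue Aβ42 sequence built fully helical (the
  standard starting conformation for this system; the 25–35 core carries
  Lys28 and Ile31/Ile32/Met35). Both helices are aligned on z; the receptor
  presents its Glu86 face and the client its Lys28 face across the
  interface, a reduced mimic of the electrostatic-anchor geometry. The
  ligand is placed by bisection so the minimum interatomic distance equals
  the requested gap (default 0.45 nm, van der Waals contact of the
  sidechain spheres) within 0.001 nm.
* **Pseudo-trajectories** are i.i.d. isotropic Gaussian jitter per atom per
  frame (default sd 0.01 nm) on top of an optional rigid per-frame ligand
  offset along the separation axis; the analysis drivers use a cosine
  "breathing" schedule (amplitude 0.12 nm, period 10 frames) so contact
  statistics are neither 0 nor 1. There are no correlated modes, no
  solvent, and no force-field dynamics: the trajectories exercise the
  estimators, they do not emulate kinetics or thermodynamics of the real
  complex. Passing tests therefore demonstrates correctness of the
  analysis, not reproduction of the real system's numbers.
* **ThT traces** sample a normalized mass curve (secondary-nucleation model
  or logistic) every 400 s (the plate-reader cadence) with additive
  Gaussian noise: signal = baseline + scale·M(t) + N(0, σ). Defaults (κ =
  7×10⁻⁴ s⁻¹ control vs 4.5×10⁻⁴ s⁻¹ inhibited, 5 µM monomer, 1 bell-to-
  plateau over ~11 h) were chosen to resemble quiescent Aβ42 plate-reader
  experiments at micromolar concentration. All generators are pure
  functions of (inputs, seed) using one explicitly seeded NumPy generator.

## SASA

Shrake–Rupley with a deterministic spherical Fibonacci lattice (default 960
points, probe 0.14 nm). Determinism was preferred over random test points so
results are exactly reproducible; quadrature error at 960 points is ~1–4%
per atom on dense clusters and falls below 0.6% at 30720 points, which is
what the oracle-equivalence check uses against a 10⁶-sample Monte-Carlo
reference. A test point exactly on a neighbouring expanded sphere counts as
accessible (burial requires strict inequality) — a tie rule fixed for
determinism. Hydrogens are excluded by default (heavy-atom SASA, the common
convention; a flag includes them). Neighbour search uses a k-d tree; only
spheres that can intersect the scored surface are tested.

Because the same lattice scores a subset in isolation and within the
complex, burial can only grow when occluders are added; per-residue
interfacial SAS values are therefore exactly non-negative and sum exactly
to twice the both-surface-averaged interfacial area. The two mapped areas
(receptor-mapped vs client-mapped) agree only to quadrature, since the
buried caps are sampled from different lattice directions; their average is
the reported quantity.

## Interface profile conventions

* Trailing (causal) floating window over (t − w, t], default 100 ns at
  production scale (10 ns in the desk-scale drivers, scaled with the
  trajectory length); a centered window would fill the t = 0 edge with
  future data.
* Burn-in as an index fraction: the first ⌊f·n⌋ samples are dropped
  (f = 0.55 keeps exactly the last 450 of 1000 samples).
* Replicate statistics: per-replicate means over the equilibrated segment
  first, then mean and SEM (sd/√n) across replicate means — pooling frames
  would understate errors through autocorrelation. A single replicate
  returns SEM = NaN.
* The Wimley–White interface scale ships as an editable TSV with
  charged-state values for Asp/Glu/Lys/Arg (matching the ionization
  convention above) and neutral His; sign convention positive =
  hydrophilic. The SAS^hydro product uses the *interfacial* per-residue SAS
  by default — consistent with an interface-centric index — with a flag to
  use absolute in-complex SASA instead.

## Contact protocol

The probe is a single named atom (sidechain nitrogen NZ of the configured
lysine for all-atom inputs; the SC pseudo-sidechain in the reduced models).
All thresholds are inclusive (≤): "within 0.35 nm" retains the boundary
frame, and the 0.6 nm screen retains a residue that ever touches 0.60 nm in
the equilibrated segment. Residues selected for pooled densities default to
those with persistence ≥ 0.1 (the selection rule for "relevant" residues is
otherwise not numerically prescribed, so it is exposed as configuration);
histograms span [0, screen + 0.2 nm] with fixed 0.01 nm bins, extended when
data exceed the range so the density always integrates to 1.

## Helix assignment

No assignment method is canonical for this quantity, so the package uses
the Kabsch–Sander electrostatic criterion (E < −0.5 kcal/mol) with the
minimal-α-helix rule: a residue is helical iff it lies inside two
consecutive i→i+4 hydrogen-bonded turns. 3₁₀/π helices are not counted.
Amide hydrogens are built geometrically (1.0 Å from N opposite the bisector
of C(prev)–N and CA–N) when absent, as in united-atom models. Pairs across
a chain break (consecutive CA–CA > 0.45 nm or non-consecutive numbering)
are skipped. Assignment is method-sensitive at helix termini; interior
fractions are the robust quantity.

## MM-PBSA

Single-trajectory scheme: for each equilibrated frame every term is
evaluated for the complex and for each partner at identical coordinates, so
intramolecular contributions cancel in the difference (the Coulomb
difference equals the inter-partner pairwise sum to rounding). Vacuum terms
use f = 138.935458 kJ·mol⁻¹·nm·e⁻², Lorentz–Berthelot combination, no
cutoff, and a 0.01 nm clash guard. Entropy terms are deliberately absent
from the binding energy.

The polar term solves the linearized PB equation on a cubic grid
(7-point stencil, Jacobi-preconditioned conjugate gradients, relative
residual 10⁻⁸): solute dielectric 4 inside the van der Waals surface,
solvent 78.4 outside (the paper-grade solute value with the standard water
value, both configurable), Debye screening from the ionic strength at
310 K outside a 0.2 nm Stern layer, Debye–Hückel single-sphere
superposition as the Dirichlet boundary, charges spread trilinearly. Face
dielectrics are harmonic averages weighted by the fractional edge
penetration into the solute (8 samples per edge); this smoothed boundary
restores near-monotone grid convergence, where a midpoint rule oscillates.
The reported energy is the difference between this solve and a reference
solve (solute dielectric everywhere, no salt) on the identical grid, which
cancels the grid self-energy. Default grid 0.05 nm spacing / 1.2 nm
padding reproduces the Born ion to <1% and a two-charge Kirkwood sphere to
~1–3%; the desk-scale pipeline uses 0.15–0.2 nm spacing where only
consistency, not absolute accuracy, matters. The apolar term is
γ·SASA + c with γ = 2.27 kJ·mol⁻¹·nm⁻² (≈0.0054 kcal·mol⁻¹·Å⁻², the common
MM-PBSA choice; the study's own γ is not prescribed) and c = 0.

On the reduced synthetic complex the net vacuum Coulomb binding term is
*positive*: both partners are net-acidic (receptor ≈ −12 e, Aβ42 −3 e) and
the rod-rod geometry concentrates the monopole repulsion, partially
compensated by the polar solvation term. This is expected physics of the
stand-in geometry, not a defect; magnitudes are not comparable to a folded
protein complex, and no synthetic result here should be read as reproducing
the real system's binding energies.

## Aggregation kinetics

Normalization maps the signal to fibrillar mass via baseline/plateau window
means (defaults: first/last 10% of samples, ≥3 samples each); t_1/2 and
t_lag are invariant under affine transforms of the raw signal. t_1/2
interpolates the first upward 0.5 crossing; t_lag deliberately does not
interpolate — it returns the highest *measured* time below 10%, restricted
to t ≤ t_1/2 to guard against post-plateau noise dips.

The secondary-nucleation-dominated closed form is evaluated through the
composite-exponential solution with effective rates
κ = √(2k₊k₂m₀^(n₂+1)) and λ = √(2k₊k_n m₀^(n_c)); B± = (k∞ ± k̃∞)/2κ,
C± = ±λ²/2κ², k∞ = √(2κ²/(n₂(n₂+1)) + 2λ²/n_c), k̃∞ = √(k∞² − 4C₊C₋κ²).
The large-t factor is computed via e^(−κt) to avoid overflow, and the
parameter domain is checked (the form requires the secondary-dominated
regime, λ ≲ κ). M(0) = 0, M is non-decreasing and saturates at 1.

From a single normalized curve only (κ, λ) are identifiable; fits therefore
optimize (log κ, log λ) (coarse grid seed around a half-time heuristic, then
Levenberg–Marquardt), and individual rate constants are reported only under
an explicit k₊ = 1 convention. Reaction orders default to n_c = n₂ = 2 (the
standard Aβ42 convention) and stay fixed during fitting unless overridden.
Noise-free recovery is exact to ~10⁻¹²; at 1% added noise the median κ
error is well below 5% and recovered half-times stay within one 400 s
sampling interval.

## Pipeline

One YAML config drives helicity → interface/SAS^hydro → contacts → MM-PBSA
→ (optional) kinetics, with the burn-in fraction applied once and
consistently; every stage writes TSV/JSON and a manifest records version,
config hash, seed and stage status. All analysis stages are deterministic
given their inputs, so a re-run with the same config and seed is
byte-identical. Desk-scale problem sizes used throughout the drivers and
verification runs — 3 replicates × 50 frames of the 425-atom complex,
0.15–0.2 nm PB grids, stride 5 for the energy stage — were chosen as the
smallest sizes at which every statistic (burn-in, SEM over replicates,
persistence fractions, pooled densities) is still exercised meaningfully.

## Known limitations

* The parameter set and reduced geometry are synthetic; energies and areas
  are internally consistent but not comparable to all-atom force fields.
* No periodic boundaries, no trajectory formats beyond multi-model PDB and
  single-frame GRO (binary-trajectory adapters are an explicit hook for
  downstream work).
* Linearized PB only (no nonlinear term), vdW dielectric boundary (no
  molecular surface), single-sphere Debye–Hückel boundary condition.
* Helix assignment ignores 3₁₀/π helices by default and depends on built
  amide hydrogens for united-atom inputs.
* Secondary-nucleation fits from one curve cannot separate k_n, k₊, k₂;
  multi-concentration global fitting is out of scope.
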