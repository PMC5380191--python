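# Methods

This note records the models implemented by `torsionfold`, the conventions
and defaults chosen where several were defensible, what the synthetic-data
generators do and do not emulate, and the toolkit's known limitations.

## The coupled 2D torsion term

The backbone torsion correction is a single scalar field E(φ, ψ) shared by
all residues.  It is defined on tabulated input — a uniform periodic
lattice whose spacing must divide 360° exactly; the conventional grid is
24×24 nodes at 15°, with nodes at {−180°, −165°, …, 165°} (left-closed
periodic lattice) — and decomposed as E = E_QM − E_other − G_solv when the
three component matrices are supplied.  Producing those components
(quantum chemistry, molecular-mechanics internal terms, generalized-Born
solvation) is out of scope: grids are inputs, generated synthetically in
all tests.

**Min-shift.** `decompose_grid` shifts the global minimum of the
decomposed surface to zero and records the offset.  Only energy
differences matter downstream, and the shift keeps the constant Fourier
coefficient small.  `fit_fourier` itself fits the grid exactly as given
(no second shift), so fitting a constant surface recovers that constant
in `c_cc[0, 0]`.

**Fitting.** Ordinary least squares on the tensor-product trigonometric
basis, rather than an FFT: the basis matrix for a 24×24 grid is 576×529
and solves in milliseconds, and OLS extends unchanged to non-square or
partially masked grids.  Structural zeros (sine factors of order zero
vanish identically) are excluded from the design matrix and stored as
exact zeros.  The truncation order is capped by the aliasing bound
floor((n_nodes − 1)/2) per axis — 11 for a 24-point axis, the default.
Note that the structurally nonzero basis at order 11 has (2·11+1)² = 529
functions against 576 nodes, so arbitrary node values are fitted in the
least-squares sense; any surface *in the basis span* is reproduced to
machine precision, which is the regime all recovery guarantees address.

**Units and conventions.** Angles are degrees at every interface; the
partial derivatives returned by `surface_partials` are kcal/mol per
*radian* (the natural unit for the chain rule into Cartesian forces).
Dihedrals follow the IUPAC convention: cis = 0°, trans = 180°, range
(−180°, 180°].

## Forces

The dihedral gradient uses the standard cross-product formulation with an
explicit guard that raises on near-collinear geometries (silent NaNs would
poison any sampler built on top).  Per residue, the 2D term needs both φ
and ψ; terminal residues carrying only one torsion contribute nothing and
are skipped.  Because each dihedral gradient has exactly zero net
translation and zero net torque, the accumulated force set conserves
momentum and angular momentum to numerical precision — this is asserted,
not assumed, in the tests (1e-10 kcal/mol/Å).  Proline can be excluded
from the shared surface by filtering its quadruplets before calling
`torsion_forces`; the surface itself is residue-blind (per-residue
parameter sets are a known future refinement).

## Peptide builder

`build_ideal_peptide` constructs chains by natural-extension-reference-
frame (NeRF) placement with fixed idealized bond lengths and angles (the
table in `constants.py`); ω is fixed trans.  The builder's only contract
is *self-consistency*: measured backbone dihedrals reproduce the requested
values to well below 1e-6°, and builds are bit-deterministic.  Placed
hydrogens are the amide H (absent on proline) and one HA; side chains are
a CB pseudo-atom, plus an indole-centroid pseudo-atom `XIN` on tryptophan
so stacking distances are well-defined without full side-chain geometry.
For an uncapped chain, φ of the first and ψ of the last residue have no
flanking peptide group and are not realized; `capped=True` adds ACE/NME
caps and realizes every requested torsion.  PDB I/O is delegated to
biotite; multi-model files become trajectories.

## Polarization model

A hydrogen bond N–H···O=C alters the charges of the four participating
atoms.  The model is Δq(d) = a·exp(−b·d) with separate (a, b) for the
donor nitrogen and acceptor oxygen, applied as paired transfers (H→N and
C→O), which conserves total charge identically.  Conventions chosen here:

- **d is the N···O heavy-atom distance** (the donor/acceptor distance is
  not otherwise pinned down); recorded once and used consistently by
  detection, the reaction coordinate, and the charge model.
- **Clamping, not extrapolation**, outside the fitted 2.5–6.5 Å range.
- **Shortest-partner rule**: an atom engaged in several detected bonds is
  polarized only through its shortest bond, because the exponential was
  parameterized on a single hydrogen-bonded dipeptide pair; longer bonds
  sharing an atom are dropped entirely so transfers stay paired.
- Geometric detection defaults: N···O ≤ 3.5 Å, N–H···O angle ≥ 120° at
  the hydrogen, sequence separation ≥ 2.  All configurable.

The shipped (a, b) amplitudes are explicitly **placeholders** with a
physically plausible shape; the fitted values belong to the original
parameterization data and should be supplied by the user, for which
`fit_exponential` (log-linear seeding + nonlinear least squares) is
provided and verified to recover generating parameters to 1e-6 relative
on noiseless data over the fitted range.

## Samplers and what they emulate

The Monte Carlo machinery replaces molecular dynamics, not approximates
it: a Metropolis chain in (φ, ψ) with uniform symmetric proposals and
periodic wrap samples the exact Boltzmann density of the torsion surface,
so every distributional claim can be checked against 1D quadrature.  The
replica-exchange variant runs one walker per ladder temperature with
neighbor swaps every `swap_interval` steps, alternating even/odd pairing,
acceptance min(1, exp[(β_i − β_j)(E_i − E_j)]).  The two temperature
ladders shipped as presets (`2i9m`: 267–577 K, `trpzip2`: 255–597.08 K,
12 replicas each) are the conventional spans for short-peptide folding
studies.  k_B = 0.0019872041 kcal/(mol·K) throughout.

What this does *not* emulate: Cartesian dynamics, solvent friction,
kinetics, or any coupling between the torsion surface and the other force
field terms.  A passing sampler test therefore certifies the statistical
mechanics of the implementation, not the realism of any particular
surface.

The **two-state generator** draws i.i.d. folded/unfolded labels with the
exact Boltzmann probability for a system with a non-degenerate folded
state at E = 0 and a g-fold degenerate unfolded state at E = ΔE.  It is
the analytic truth against which WHAM is validated.  Two characteristic
temperatures are recorded in its metadata and must not be conflated:

- the **half-occupancy (melting) temperature** T_m = ΔE / (k_B ln g),
  where the folded fraction crosses 1/2 (295.9 K for ΔE = 2 kcal/mol,
  g = 30);
- the **specific-heat peak**, which for a two-level system is the
  Schottky anomaly at the solution of 2/x = tanh((x − ln g)/2) with
  x = ΔE/(k_B T) — 229.5 K for the same parameters, well *below* T_m.

For real peptides with many microstates the heat-capacity peak and the
melting midpoint nearly coincide; for a strict two-level toy they do not,
and the WHAM validation targets the closed-form Schottky peak.

## WHAM and derived quantities

Binned temperature-WHAM (the histogram formulation, 200 energy bins over
the pooled range padded 1%, tolerance 1e-7 on max|Δf|, at most 1e5
iterations, f₁ ≡ 0), iterated in log space with `logsumexp` for
stability.  Once the per-replica shifts converge, *per-sample* weights at
any target temperature follow from the same denominator evaluated at the
sample energies; free-energy surfaces are weighted histograms over any
recorded observables (F = −k_B T ln P, empty bins masked, occupied
minimum shifted to zero), and Cv(T) = (⟨E²⟩−⟨E⟩²)/(k_B T²) from the
weighted moments.  The Cv argmax is reported as the melting-curve peak,
ties broken toward lower temperature, default scan resolution 1 K.

Samples are treated as statistically independent — correct for the i.i.d.
synthetic generators used in validation; correlated trajectory input
would need an inefficiency correction that is deliberately out of scope.

## Analysis conventions

- RMSD: closed-form Kabsch superposition with the determinant correction
  (proper rotations only); cross-checked in tests against an independent
  implementation.
- Clustering: seeded Lloyd iterations over frames superposed onto frame 0
  and flattened, centroid frame = member nearest the cluster mean, empty
  clusters re-seeded with the farthest point; deterministic under a fixed
  seed.  (A library k-means serves as an independent oracle in tests, not
  as the implementation.)
- Reaction coordinates: the collective hydrogen-bond distance d is the
  arithmetic mean of the native-pair N···O distances (max and RMS offered
  as alternatives); the stacking distance l is the mean indole-centroid
  separation over the configured Trp pairs.  The default pair list
  (2–11, 4–11) follows the conventional quotation for tryptophan-zipper
  hairpins even though the geometric partners would be 2–11/4–9; it is a
  config default, deliberately not silently "fixed", and overridable.
- Ramachandran regions are ordered rectangles with first-match-wins and
  an `other` fallback, so populations always partition unity.  The
  defaults (alpha φ∈[−100,−30] ψ∈[−67,−7]; ppii φ∈[−110,−50]
  ψ∈[120,180]; beta φ∈[−180,−90], ψ∈[90,180]∪[−180,−150]) are
  conventional stand-ins; a tightened `alpha_strict` box is provided as an
  alternative region set rather than in the default partition, because a
  strict box listed first would shadow the loose one.  Tests pin behavior
  to the configured values, not to any literature set.
- Karplus: J(θ) = A cos²θ + B cos θ + C with θ = φ − 60°; the default
  coefficients (A = 7.09, B = −1.42, C = 1.55 Hz) are a widely used
  HN–Hα literature set and fully overridable.

## Problem sizes

The validation suite uses the sizes at which its statistical tolerances
were derived: 1e6 Metropolis steps for the 3% Boltzmann-variance check,
5e4 samples per replica across the 12-temperature ladder for the
0.05 kcal/mol WHAM ΔF and 5 K Cv-peak checks, 100 random conformations
for force/finite-difference agreement, and 24×24 grids throughout.  Unit
tests run scaled-down versions of the same checks with correspondingly
looser, pre-derived tolerances.

## Known limitations

- One torsion surface for all residues; no residue-specific or
  glycine/proline-specific parameter sets.
- The polarization amplitudes ship as placeholders (see above).
- No other force-field terms: the samplers live purely in torsion space,
  so nothing here measures the interplay of the 2D correction with
  nonbonded or solvation terms.
- The builder's side-chain model (CB pseudo-atom, Trp centroid) supports
  distances and torsions, not packing or sterics.
- WHAM assumes uncorrelated samples.
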