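# Methods

This note records the model, the numerical choices, and the limits of what
the test fixtures can demonstrate.

## Energy model

The intermolecular energy is a whole-molecule pairwise sum: exp-6
(Buckingham) repulsion–dispersion between atom types, plus point-charge
electrostatics.  The exp-6 part is truncated by the **centre-of-mass
distance** between molecules (default 20 Å), not atom–atom distance, and
carries no long-range tail correction.  Electrostatics are summed by Ewald
with tinfoil boundary conditions over all atoms; the (rigid, constant)
intramolecular Coulomb terms are subtracted so the reported energy is purely
intermolecular.  The Ewald splitting parameter is chosen automatically and
the result is independent of it within the requested accuracy (default
1e-7 kJ/mol-scale; the NaCl and CsCl Madelung constants are reproduced to
1e-5 against direct Evjen summation).

Combining rules (geometric mean for A and C, arithmetic for B) back-fill
missing cross terms and are logged, never silent.  The relative permittivity
stored with a force field is metadata describing how its charges were
derived; it never scales an energy.

*Truncation smoothness.* A sharp COM cutoff makes the energy a step function
of geometry whenever a molecule pair crosses it.  Every derivative machine in
the package (the optimiser, elastic finite differences) therefore works on a
**frozen pair list** built from its reference geometry, so the surface it
differentiates is smooth; converged structures are re-scored with the exact
cutoff.  The fcc fixture additionally places its cutoff mid-gap between
neighbour shells so that no shell crosses it over the volume range explored
by thermal expansion.

## Optimisation

Minimisation runs over the 6 entries of a triangular lattice matrix (fixing
the global orientation) plus per-molecule COM translations and rotation
vectors about the principal inertia axes; the first molecule's translation
is pinned.  Gradients are central finite differences (step 1e-4 Å/rad),
updates BFGS, convergence at max-norm gradient below `tol` (default
1e-4 kJ/mol per coordinate).  Rotation axes with zero inertia moment (single
atoms; the axis of a linear molecule) carry no dynamics and are excluded, so
a linear molecule has 5 rigid-body coordinates, an atom 3.  A structure
whose volume changes by more than 50% or whose molecules translate more than
3 Å is reported as destroyed by the applied pressure rather than "optimised".

## Lattice dynamics

Force constants are assembled **analytically** from first and second
derivatives of the pair potential (exp-6 plus 1/r Coulomb), transformed to
rigid-body coordinates with the exact rotation curvature term.  The
electrostatic part of the force constants is summed in real space over the
same whole-molecule cutoff as the exp-6 part: for neutral molecules the
leading intermolecular electrostatic curvature decays like R⁻⁵
(dipole–dipole), so the molecule-pair sum converges absolutely.  (Lattice
*energies* still use Ewald; only the force constants use the real-space
molecular sum.)  Translational invariance of the pair sum then enforces the
acoustic sum rule to machine precision — the three zone-centre acoustic
frequencies on all fixtures are below 1e-5 cm⁻¹.

Wavevectors are sampled on a uniform Γ-centred grid (default 4×4×4 for
production, 3×3×3 in most tests).  The three acoustic zeros at Γ are
replaced by a Debye term representing 3/N_k modes per primitive cell.  The
Debye velocity is fitted at dedicated small-|k| probe points (reduced
|k| = 0.02 along the three reciprocal axes and the body diagonal, averaged
as ⟨v⁻³⟩^(−1/3), the Debye density-of-states weighting) rather than on the
grid's innermost shell: the innermost shell of a coarse grid is far outside
the linear regime and would bias the velocity by ~10%.  The Debye cutoff
frequency follows from requiring exactly 3/N_k acoustic modes per cell.

Thermodynamics (ZPE, F_vib, S, C_v) default to the discrete weighted mode
sum plus a 96-point Gauss–Legendre integral over the Debye density of
states; entropy and heat capacity use the analytic per-mode formulas, never
numerical differencing (the suite checks S = −dF/dT to 1e-6 kJ/mol/K).  A
Gaussian-KDE density of states (default bandwidth 3 cm⁻¹) is available both
as an output representation and as an alternative integration path
(`use_kde=True`); KDE-based free energies converge to the discrete sum as
the bandwidth shrinks.  Imaginary frequencies anywhere on the grid abort the
calculation unless diagnostics are explicitly requested
(`allow_imaginary`), mirroring the exclusion of dynamically unstable
structures from any survey.

## Quasi-harmonic workflow

The thermal pressure P_th(T) = −∂F_vib/∂V is a central finite difference
over isotropic volume scalings ±0.5% with rigid molecular geometry (COMs
move affinely).  By default the zero-point part of F_vib is **excluded**
from the thermal pressure: empirical exp-6 force fields are fitted to
low-temperature crystal structures and therefore already contain zero-point
expansion, so P_th(0) = 0 and the 0 K quasi-harmonic state is the static
minimum with A(0) = E_latt + ZPE.  `include_zpe=True` switches to the full
derivative.  The expanded structure at T comes from one static optimisation
at external pressure −P_th(T) evaluated at the fixed 0 K reference
(single-pass, not self-consistent); on the fcc fixture this reproduces
explicit minimisation of E(V) + F_vib(V, T) over a 15-point volume grid to
0.06% in volume and 0.002 kJ/mol in free energy at 300 K.  The volumetric
expansion coefficient is the finite difference (V_T − V_0)/(V_0·T),
reported over 0→350 K by convention.

Free-energy curves A(T) are piecewise-cubic Hermite interpolants whose node
slopes are the analytic −S(T), so the interpolant's derivative at each node
equals minus the computed entropy exactly; polymorph transition temperatures
are bracketed sign changes of ΔA(T) refined by Brent's method.

## Elastic constants

The 6×6 matrix (Voigt notation, engineering shear strains) comes from
central second differences of the energy density at ±0.002 strain, with
rigid-body internal coordinates re-relaxed at every strained cell
(relaxed-ion; `relax_internal=False` gives the clamped variant, which is
never softer on the diagonal).  Aggregate moduli use the Voigt (upper) and
Reuss (lower) bounds and their arithmetic mean (Hill).  Note that a cubic
crystal is *not* elastically isotropic: the central-force fcc fixture
satisfies the cubic symmetry pattern and the Cauchy relation c12 = c44
instead of the isotropy condition c11 − c12 = 2c44.

## Melting estimators

Two estimators: the Gold–Ogle fraction of the boiling point,
T_m = 0.5839·T_b, and a regression of T_m on √(−E_inter) — ordinary least
squares after the variance-stabilising square-root (Anscombe) transform,
with residual SD = √(SSR/(n−2)).  Users fit the regression to their own
(E_inter, T_m) data; the package deliberately ships no canned coefficients.
The combined prediction is the mean of the two estimators, falling back with
a warning when only one is available.  Fragment-contribution boiling/melting
estimates themselves are out of scope and must be supplied.

## Polymorph comparison

Pairs are compared through per-molecule differences ΔE_latt, ΔA(0)
(including ZPE) and ΔA(T_m), one melting temperature per polymorph family.
A sign change between ΔA(0) and ΔA(T_m) with both magnitudes above a
degeneracy tolerance (default 0.01 kJ/mol) means the ranking inverts with
temperature — a predicted enantiotropic pair; otherwise monotropic, with
the free-energy curves classified as diverging or converging by comparing
|ΔA(T_m)| with |ΔA(0)|.  Differences inside the tolerance are reported as
degenerate, never forced into a class.  The conformer filter computes the
minimum heavy-atom RMSD over rigid superposition (Kabsch) with the atom
correspondence supplied by the caller; 0.25 Å is the packing-polymorph
threshold.

## Fixtures and what they show

All test systems are generated programmatically with their oracles attached:

- **chain_1d** — a monatomic chain whose COM cutoff of 1.5a restricts
  interactions to nearest neighbours, making the longitudinal dispersion
  exactly 2√(κ/m)|sin(ka/2)| with κ = φ''(a).  The chain sits slightly
  beyond the pair minimum (bond under tension) so transverse branches are
  real.
- **exp6_fcc** — a krypton-like monatomic fcc crystal with a ~10 kJ/mol
  pair well, phonons at 50–130 cm⁻¹, used for the quasi-harmonic and
  elastic oracles.
- **rigid_diatomic_crystal** — a CO-like rigid dipolar diatomic in two
  distinct antiparallel layered packings ~0.8 kJ/mol apart, both verified
  dynamically (dense k-scan) and elastically stable; the end-to-end
  polymorph-pair fixture.
- **synthetic_pair_ensemble** — polymorph-pair energy differences drawn
  from zero-centred normals (static 2.0, zero-point 0.5, harmonic thermal
  1.0, thermal-expansion contribution 0.42 kJ/mol), the statistical shape
  of a large polymorph survey.

These fixtures exercise every code path with analytic or brute-force
reference values, but they are far simpler than real organic crystals: no
hydrogen bonding, no multipolar electrostatics beyond point charges, no
molecular flexibility, and pair wells chosen for numerical robustness.
Passing tests demonstrate correctness of the machinery, not force-field
accuracy for any real compound.

## Problem sizes and tolerances

Default test problem sizes — 3×3×3 phonon grids, 15-point volume grids,
two-molecule cells — were chosen so the whole suite exercises every
pipeline end to end in a few minutes on one core; grid-convergence tests
verify that doubling the phonon grid moves F_vib(300 K) by well under
0.1 kJ/mol on the fixtures.  Key tolerances: optimiser gradient 1e-4 kJ/mol
per coordinate; acoustic zeros below 0.1 cm⁻¹; Ewald accuracy 1e-7 (1e-8/1e-9
in fixtures that feed finite differences); elastic strain 0.002;
thermal-pressure volume step 0.5%.

## Known limitations

- Point charges only: no distributed multipoles or polarisation, so
  hydrogen-bonded and strongly polar crystals are outside the model's
  accuracy envelope (the force-field file format reserves room for future
  multipole columns).
- Rigid molecules: no intramolecular relaxation or conformational energy.
- Isotropic thermal pressure: anisotropic cells expand along all axes
  according to their compliance under a scalar pressure, which cannot
  reproduce strongly anisotropic (or negative) thermal expansion.
- Phonon force constants truncate electrostatics at the molecular cutoff;
  systems with net-charged rigid units (ionic crystals treated as "one atom
  per unit") get correct Ewald energies but their dynamical matrices would
  need an Ewald force-constant sum that is not implemented.
- The single-pass thermal-pressure expansion assumes F_vib(V) is close to
  linear over the expansion range; very soft crystals close to their
  spinodal (toy systems near an effective melting point) abort with a
  drastic-change error rather than report an unreliable state.
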