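# Methods

This note records the models implemented in npbind, the assumptions behind
them, the defaults and why they were chosen, and what the synthetic-data
generators do and do not emulate. Units throughout: lengths in Å, energies
in kcal/mol, charges in elementary charge units e, electrostatic potentials
in kT/e at the stated temperature, residue numbers 1-based as in PDB files,
internal atom indices 0-based.

## Conformational transition coordinate

The coordinate interpolating between an open reference `v1` and a locked
reference `v2` is the norm ratio `lambda = |v − v1| / |v2 − v1|` over the
flattened coordinate vector of a selection (Cα by default — the same
convention used for the fluctuation matrix; which atoms enter the vector is
in general a convention, and it is configurable).

Three design points deserve spelling out:

* **Reference alignment.** `v2` as given need not sit in `v1`'s frame, and
  a naive least-squares fit of the locked structure onto the open one would
  land it at `lambda < 1`. A `ReferencePair` therefore superposes `v2` onto
  `v1` (Kabsch, on the selection) once at construction and defines the axis
  from the aligned copy; `compute_lambda` runs every frame through the same
  superposition code path. Consequences: `lambda(v2) = 1` bitwise,
  `lambda(v1) = 0` to machine precision, and — because the aligned
  difference vector has no rigid component, making the cross-covariance of
  any interpolate with `v1` symmetric positive semidefinite — the Kabsch
  fit of `v1 + t (v2_aligned − v1)` onto `v1` is the identity, so
  `lambda(t) = t` exactly along the interpolation path.
* **Superposition target.** Frames are fitted to the open state. Anchoring
  to `v1` matches the coordinate's "deviation from open" semantics; it is a
  documented convention, not an inferred one, and the fit makes the
  coordinate invariant under any rigid motion of the input frame.
* **Norm ratio vs projection.** The norm ratio is the defining formula and
  the default. It is non-negative, so isotropic positional noise of
  standard deviation σ inflates its mean by roughly `M σ² / (2 t A²)`
  (M coordinates, axis length A, true position t): a 0.5 Å-noise ensemble
  at t = 0.32 on the default fixture averages ≈ 0.61. This is a property of
  the statistic, not an implementation artifact. Where the position along
  the axis is to be *estimated* — e.g. checking that generated trajectories
  recover their target — the signed projection
  `(v − v1)·(v2 − v1)/|v2 − v1|²` is the right (unbiased) estimator, and
  both the API (`projection=True`), the CLI (`--projection`) and the
  parameter-recovery acceptance test use it in that role. The norm-ratio
  series is separately verified against a brute-force re-evaluation on the
  same frames.

## Distance-fluctuation matrix

`tau_ij` is the population variance (ddof = 0, matching the time-average
bracket) of the i–j distance over frames, computed on frame-internal
distances with no superposition — the matrix is invariant under per-frame
rigid motion and independent of any reference structure by construction.
Diagonal exactly zero; at least two frames are required, since a
single-frame "fluctuation" is undefined.

## Trajectory clustering

Neighbor-count clustering on the pairwise superposed-RMSD matrix:
repeatedly the unassigned frame with the most unassigned neighbors within
the cutoff becomes a centroid and claims its neighbors. Ties on the
neighbor count go to the lowest frame index (determinism); clusters are
renumbered by descending population with the centroid index as tiebreak.
The cutoff (default 1.5 Å) is the only parameter — the cluster count is an
outcome, never an input. Every frame ends up within the cutoff of its
centroid; populations sum to 1.

## Elastic-network normal modes

Anisotropic network model on Cα nodes: pairs within the cutoff (default
15 Å) are joined by springs of uniform constant k = 1 (arbitrary units —
the analysis reports mode shapes and relative stiffness, not frequencies,
because absolute spring constants are not identifiable from a single
structure). Off-diagonal 3×3 Hessian blocks are `−k (Δr Δrᵀ)/|Δr|²`,
diagonal blocks the negative row sums, which enforces translational
invariance exactly. Rigid-body modes are identified by a relative
eigenvalue threshold (1e-8 of the largest), with a sanity check that
exactly 6 fall below it (5 for the two-node diatomic); three or more
collinear nodes are rejected, since transverse directions then carry no
ANM stiffness and flood the spectrum with spurious zero modes. Mode
overlaps with the open-to-locked difference vector are absolute cosines;
over the complete non-trivial basis their squares sum to 1 because the
aligned difference vector has no rigid component.

A note on the two-domain fixture: whether the softest mode is an
inter-domain hinge motion (small peripheral domain swinging more) or a
global bend depends on how many springs cross the domain boundary. At the
default 15 Å cutoff the compact fixture is rod-like and bends as a whole;
the hinge regime appears at shorter cutoffs (≈ 8 Å), which is where the
domain-amplitude comparison is made.

## MM/PBSA

Single-trajectory end-point protocol: the unbound protein and ligand keep
their complex geometry, so the bonded delta is identically zero while
`E_bonded` itself remains computable (harmonic bonds `k_b (r − r0)²`,
harmonic angles `k_θ (θ − θ0)²` with θ in radians, periodic dihedrals
`k_φ (1 + cos(nφ − δ))`, impropers sharing the dihedral form). The original
workflow re-ran short MD after each mutation; this package deliberately
substitutes single-geometry (or supplied-ensemble) re-evaluation — running
MD is out of its scope, and the substitution is the standard desk-scale
approximation.

* **Nonbonded terms.** Coulomb `k_C q_i q_j / (ε_solute r_ij)` with
  `k_C = 332.0636 kcal·Å/(mol·e²)` and Lennard-Jones 12-6 with
  Lorentz–Berthelot combining; exact all-pair sums, no cutoff (the analysis
  is post-hoc scoring, and exactness makes oracle testing meaningful).
  Solute dielectric default 2, solvent 80, 150 mM 1:1 salt, 300 K — common
  continuum-electrostatics conventions, all configurable.
* **Entropy.** The `−T S` term is carried in the data model but off by
  default: totals are then exactly the sum of the four printed components,
  which is also how reference binding-energy tables in this area aggregate.
* **Polar solvation.** Finite-difference linearized PB on a cubic grid
  (default spacing 0.5 Å, padding 8 Å beyond the atom spheres plus a 2 Å
  Stern ion-exclusion layer). Dielectric is assigned per node (inside any
  atom's radius → solute, else solvent) with harmonic-mean face averaging;
  charges spread trilinearly to the 8 surrounding nodes; Debye–Hückel
  screened-Coulomb Dirichlet boundary values; conjugate-gradient solve
  (Jacobi preconditioner, relative tolerance 1e-8, failure to converge is
  an error reporting the residual). `G_polar = ½ Σ q_i (φ_solv − φ_vac)`
  with both potentials from the same grid and charge spreading, so the grid
  self-energy cancels in the difference. Validation: a 2 Å, +1 e Born ion
  at ε 1→80 reproduces the closed form within 5% at 0.5 Å spacing with
  monotone improvement under refinement (measured −6.5% → −4.2% → −1.7% at
  1.0/0.5/0.25 Å). A guard rejects grids above 2×10⁷ nodes rather than
  exhausting memory.
* **Nonpolar solvation.** `G_nonpolar = γ·SASA + b` with γ = 0.00542
  kcal/(mol·Å²), b = 0.92 kcal/mol, probe 1.4 Å, Shrake–Rupley areas at 960
  points per atom using the structure's own per-atom radii.
* **Decomposition.** Per-atom terms: half of every cross-group Coulomb and
  LJ pair energy to each partner; `½ q_i Δφ_i` in the complex minus the
  same in the atom's own unbound part for polar; `γ ΔSASA_i` for nonpolar
  with the constant `−b` of the delta spread uniformly over the atoms (the
  offset belongs to no atom; spreading it is the one arbitrary choice, and
  it preserves exact closure). Per-atom sums roll up to per-residue sums
  and to `dG_bind` to better than 1e-6 kcal/mol by construction.
* **Alanine scanning.** Side-chain atoms beyond Cβ are deleted, the Cβ
  charge is reset so the truncated residue is net-neutral, backbone
  geometry is untouched, and the binding energy is re-evaluated. Mutating
  an alanine is a no-op; glycine (no Cβ) and proline (backbone ring) are
  rejected. A multi-site mutant is the same operation with several residues
  at once. Trajectory averaging reports the arithmetic mean and standard
  deviation of every term over frames, with per-frame values retained.

## Nanoparticle surface characterization

Particles are point-charge site models. The accessible surface is the
union of site spheres (site radius 1.5 Å + probe 1.4 Å) sampled with a
golden-spiral lattice at fixed point density; points inside another site's
sphere are discarded, and the area is the exposed-fraction estimate.
Surface potentials are unscreened Coulomb sums converted to kT/e (at 300 K,
1 kcal/mol/e = 1/0.5962 kT/e) — the map renders the particle's own fixed
charges; a Debye-screened variant would reuse the energetics module's salt
treatment but is not what a fixed-charge surface map shows. Patch
classification labels points by sign outside a neutral band and groups
same-label points into connected components under an adjacency radius
(default twice the mean nearest-neighbor spacing), reporting per-patch
areas, mean potentials and axial centroids. Size-series tables compare
total charge against the shape's nominal geometric surface area (sphere, or
spherocylinder for rod/needle).

## Synthetic-data generators

All generators are pure functions of their spec, seed included.

* **Two-state references.** Two Cα helix-trace domains on a common axis
  (N-domain 20 residues, C-domain 12 by default, 3.8 Å Cα spacing, 4 Å
  linker gap), with 0.25 Å seeded jitter to break the helix symmetry. The
  locked state rotates the C-domain about its long axis (default 35°) and
  translates it toward the N-domain (default 3 Å) — a rigid inter-domain
  motion of the kind that distinguishes open and locked adaptor
  conformations. N-domain coordinates are identical between the states by
  construction; a zero-rotation zero-translation spec is rejected.
* **Trajectories.** Frames at `v1 + t (v2_aligned − v1)` plus isotropic
  Gaussian noise (default 0.5 Å — a typical Cα positional fluctuation
  scale), then per-frame random rigid rotation/translation, on by default
  so superposition is always exercised. With zero noise every frame sits
  exactly at the target for any scatter.
* **Particles.** Sites on a cubic lattice (default spacing 3 Å, the scale
  of cation–anion separations in a calcium-phosphate mineral) clipped to a
  sphere (default diameter 1.926 nm), rod (3:1 length:width, 3 nm) or
  needle (8:1, 4.8 nm; the aspect ratios are conventions). Charge patterns
  are declarative region→charge maps; the defaults emulate the qualitative
  morphology-dependent surface electrostatics: sphere — alternating
  weak-positive (+0.2 e) and strong-negative (−0.5 e) patches, net
  negative; needle — positive tips (+0.4 e, outer 18% of the length) on a
  negative body (−0.25 e); rod — weakly positive shell (+0.08 e). Charged
  "shell" sites are boundary sites (a lattice neighbor falls outside the
  shape): their count tracks the geometric surface area across sizes, which
  is what makes the charge-per-area of a sphere size series nearly constant
  (measured spread ≈ 3.5% over 1.926–3.2 nm). The alternating sphere
  patches are equal-count azimuthal wedges assigned by azimuth rank — a
  lattice checkerboard or fixed-angle sectors would leave a systematically
  unbalanced split on a curved shell. Because the small sphere is strongly
  net-negative, its monopole dominates the surface potential: the *charges*
  alternate, the potential map stays negative everywhere — matching the
  "weak positive" description of the pattern, not a claim about potential
  sign.
* **Complex fixture.** A 10-residue charged helical peptide (net +1;
  backbone beads N/CA/C/O with charges summing to −0.2 per residue, Cβ
  +0.2, charged side-chain tips ±1) beside a small negatively charged
  sphere, fully parameterized (charges, σ/ε, PB radii), with positive side
  chains facing the particle so an attractive contact region exists. The
  toy force field is internally consistent but not CHARMM; it exists so the
  energetics identities (closure, symmetry, oracle equivalence, mutation
  arithmetic) can be tested exactly, not to reproduce any published
  absolute binding energy.

What passing tests on these fixtures do *not* show: agreement with real
force fields, real protein geometry, solvent structure, conformational
entropy, or the absolute binding energies of any published system — those
require the original ensembles and parameters, which this package does not
regenerate.

## Pipeline problem sizes

The demo pipeline runs three 60-frame trajectories (the unbound,
needle-bound and sphere-bound coordinate regimes at targets 0.24, 0.32,
0.65), clusters each, computes five modes, one MM/PBSA decomposition with a
1.0 Å PB grid plus a two-mutant alanine scan, and characterizes three
particles — sizes chosen so a full run finishes in seconds while exercising
every stage; all of them scale up through the config.

## Known limitations

* The PB solver is linearized, Cartesian-grid, two-solve reaction-field
  only: no nonlinear PB, no molecular (SES) surface, no focusing; accuracy
  at 0.5 Å spacing is the measured ≈ 4% Born-level error, and charged
  systems inherit the usual grid-discretization sensitivity.
* Entropy is a pass-through term; no normal-mode or quasi-harmonic
  estimator is provided.
* The alanine scan re-evaluates a fixed geometry; side-chain relaxation and
  re-equilibration effects are absent by design.
* XYZ files carry no residue/chain structure, so energetics groups read
  from XYZ require a parameter sidecar for identity.
* Surface patch areas are point-count shares of the accessible area, exact
  only in the dense-sampling limit.
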