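# npbind

Post-simulation analysis of nanoparticle–protein recognition, built around
the kind of question asked of the clathrin adaptor AP2: when a charged
nanoparticle (for example a hydroxyapatite sphere, rod or needle) binds the
cargo-recognition subunit, how far does the protein move along its
open-to-locked conformational transition, which residues pay for the
binding, and how does the particle's surface electrostatics select the
binding site?

The package is aimed at molecular modellers who already have (or simulate)
conformational ensembles and docked complexes and want the downstream
analysis as tested, reusable, scriptable components rather than one-off
scripts. Because the original MD ensembles of such studies are rarely
deposited, a first-class synthetic-data module generates seeded stand-ins —
two-state reference structures, coordinate-targeted trajectories, charged
particle models and a fully parameterized protein–particle complex — so
every stage runs end to end from nothing but a seed.

## What it computes

**Conformational transition coordinate.** Given an open reference `v1` and
a locked reference `v2` (Cα coordinates by default), each sampled structure
`v` is first superposed onto `v1` and then scored as

    lambda = |v - v1| / |v2 - v1|

so `lambda = 0` is the open state and `lambda = 1` the locked state. A
signed projection variant, `(v - v1)·(v2 - v1) / |v2 - v1|^2`, is available
where an unbiased estimator of the position along the axis is wanted (the
norm ratio is non-negative and therefore noise-inflated; see
`docs/methods.md`).

**Distance-fluctuation matrix.** `tau_ij = <(d_ij - <d_ij>)^2>`, the time
variance of each internal Cα–Cα distance — a reference-free map of protein
plasticity.

**Trajectory clustering.** Neighbor-count (GROMOS-style) clustering under a
pairwise superposed-RMSD cutoff (default 1.5 Å); the number of clusters is
emergent, not an input.

**Elastic-network normal modes.** Anisotropic network model on Cα nodes
(cutoff 15 Å, uniform spring constant), with rigid-body-mode detection,
per-node mode amplitudes, and the overlap of each mode with the
open-to-locked difference vector.

**MM/PBSA binding energies.** End-point binding free energy

    dG_bind = G_complex - (G_protein + G_ligand),      G_x = <E_MM> - T S + <G_solv>
    E_MM    = E_bonded + E_vdW + E_elec                (Coulomb + Lennard-Jones)
    G_solv  = G_polar + G_nonpolar                     (PB + gamma*SASA + b)

with a finite-difference linearized Poisson–Boltzmann solver for `G_polar`,
Shrake–Rupley solvent-accessible surface areas for `G_nonpolar`, the
single-trajectory protocol (partner geometries taken from the complex, so
the bonded delta vanishes), per-residue decomposition
`dR_x = sum_i (A_i^complex - A_i^free)` that closes exactly to `dG_bind`,
and computational alanine scanning (side chains truncated at Cβ, residue
re-neutralized, energies re-evaluated).

**Nanoparticle surface electrostatics.** Accessible-surface sampling of
point-charge particle models, Coulomb potential maps in units of kT/e,
signed patch classification (e.g. the positive tips on a negative needle
body), and charge-per-surface-area series across particle sizes.

## Worked example

```python
import numpy as np
from npbind import (TwoStateSpec, TrajectorySpec, make_two_state_references,
                    make_trajectory, lambda_series, compute_lambda,
                    cluster_trajectory, make_complex, merge_structures,
                    particle_as_structure, mmpbsa, EnergyModelConfig)

refs = make_two_state_references(TwoStateSpec(seed=1))
print(f"lambda(open)   = {compute_lambda(refs.v1, refs):.3f}")
print(f"lambda(locked) = {compute_lambda(refs.v2, refs):.3f}")

traj = make_trajectory(refs, TrajectorySpec(lambda_target=0.65,
                                            positional_noise_sd=0.5,
                                            n_frames=200, seed=2))
series = lambda_series(traj, refs, projection=True)
print(f"projection mean over 200 frames: {series.mean:.3f} +/- {series.std:.3f}")

clusters = cluster_trajectory(traj, cutoff=1.5)
print(f"clusters at 1.5 A cutoff: {len(clusters.populations)} "
      f"(populations {np.round(clusters.populations, 2)})")

protein, particle, table = make_complex(seed=0)
complex_structure = merge_structures(protein, particle_as_structure(particle))
result = mmpbsa(complex_structure, "chain:A", "chain:X",
                cfg=EnergyModelConfig(pb_grid_spacing=1.0))
d = result.delta
print(f"dE_vdW={d.e_vdw:+.2f}  dE_elec={d.e_elec:+.2f}  "
      f"dG_polar={d.g_polar:+.2f}  dG_nonpolar={d.g_nonpolar:+.2f}  "
      f"dG_binding={d.g_total:+.2f} kcal/mol")
print("strongest residue contribution:",
      result.per_residue.index[0], f"{result.per_residue.iloc[0]:+.2f}")
```

prints

```
lambda(open)   = 0.000
lambda(locked) = 1.000
projection mean over 200 frames: 0.652 +/- 0.056
clusters at 1.5 A cutoff: 1 (populations [1.])
dE_vdW=-0.48  dE_elec=-89.99  dG_polar=+106.45  dG_nonpolar=-1.13  dG_binding=+14.86 kcal/mol
strongest residue contribution: A:6:LYS -0.98
```

Reading the output: the generated reference pair pins the coordinate's
endpoints exactly; a noisy trajectory aimed at `lambda = 0.65` is recovered
by the projection estimator; the tight single-basin ensemble forms one
cluster; and for the synthetic complex the favorable cross-electrostatics
(−90 kcal/mol, led by a lysine at −0.98) is outweighed by the polar
desolvation penalty — the per-term ledger is exactly the information used to
rank binders and pick mutation sites.

The same stages run from the shell: `npbind simulate`, `npbind lambda`,
`npbind dfmat`, `npbind cluster`, `npbind nma`, `npbind mmpbsa`,
`npbind alascan`, `npbind npsurf`, and `npbind pipeline` for the whole
sequence; every output file starts with a provenance header (version,
config hash, seed) and a fixed config+seed reproduces every byte.

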