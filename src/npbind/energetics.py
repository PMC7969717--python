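"""MM/PBSA binding-energy engine with per-residue decomposition.

The binding free energy of a protein-ligand (here protein-nanoparticle)
complex is estimated end-point style::

    dG_bind = G_complex - (G_protein + G_ligand)
    G_x     = <E_MM> - T*S + <G_solvation>
    E_MM    = E_bonded + E_vdW + E_elec
    G_solv  = G_polar + G_nonpolar

with the vacuum molecular-mechanics terms from Coulomb + Lennard-Jones +
harmonic bonded potentials, the polar solvation from a finite-difference
linearized Poisson-Boltzmann (PB) solver, and the nonpolar solvation from a
solvent-accessible surface-area (SASA) model, G_nonpolar = gamma*SASA + b.

The single-trajectory protocol is used throughout: the unbound protein and
ligand geometries are extracted unchanged from the complex, so the bonded
contribution to dG_bind vanishes identically.  The entropy term -T*S is
carried in the data model but disabled by default; totals are then exactly
the sum of the four nonbonded/solvation components.

Per-residue decomposition splits every cross-group pair energy half to each
partner atom, assigns polar terms as (1/2) q_i dphi_i and nonpolar terms as
gamma * dSASA_i (the constant offset b is spread uniformly over the atoms),
so per-atom terms sum exactly to dG_bind.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import biotite.structure as struc
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import LinearOperator, cg

from .io_model import (SelectionSpec, Structure, Trajectory,
                       _atom_array_from_structure)
from .units import COULOMB_CONSTANT

BACKBONE_NAMES = {"N", "CA", "C", "O", "CB"}


class EnergeticsError(ValueError):
    pass


# --------------------------------------------------------------------------
# Configuration and result containers
# --------------------------------------------------------------------------

@dataclass
class EnergyModelConfig:
    """All tunable parameters of the energy model.

    Units: dielectrics are relative, ionic strength in mM, temperature in K,
    lengths in A, gamma in kcal/(mol*A^2), offsets and energies in kcal/mol.
    No nonbonded cutoff is applied: MM sums are exact over all pairs.
    """

    coulomb_constant: float = COULOMB_CONSTANT
    solute_dielectric: float = 2.0
    solvent_dielectric: float = 80.0
    ionic_strength_mM: float = 150.0
    temperature: float = 300.0
    include_entropy: bool = False
    entropy: float = 0.0                 # S [kcal/(mol*K)], used only if enabled
    pb_grid_spacing: float = 0.5
    pb_padding: float = 8.0              # A of solvent beyond spheres + Stern
    pb_stern: float = 2.0                # ion-exclusion layer beyond radii
    pb_rtol: float = 1e-8
    pb_maxiter: int = 20000
    sasa_probe: float = 1.4
    sasa_gamma: float = 0.00542
    sasa_offset: float = 0.92
    sasa_points: int = 960               # Shrake-Rupley points per atom

    def __post_init__(self):
        if self.solute_dielectric <= 0 or self.solvent_dielectric <= 0:
            raise ValueError("dielectric constants must be positive")
        if self.pb_grid_spacing <= 0:
            raise ValueError("pb_grid_spacing must be positive")


@dataclass
class EnergyBreakdown:
    """The G_x ledger: MM terms plus solvation terms, in kcal/mol."""

    e_bonded: float = 0.0
    e_vdw: float = 0.0
    e_elec: float = 0.0
    g_polar: float = 0.0
    g_nonpolar: float = 0.0
    ts: float = 0.0
    include_entropy: bool = False

    @property
    def g_total(self) -> float:
        total = (self.e_bonded + self.e_vdw + self.e_elec
                 + self.g_polar + self.g_nonpolar)
        if self.include_entropy:
            total -= self.ts
        return total

    def __sub__(self, other: "EnergyBreakdown") -> "EnergyBreakdown":
        return EnergyBreakdown(
            e_bonded=self.e_bonded - other.e_bonded,
            e_vdw=self.e_vdw - other.e_vdw,
            e_elec=self.e_elec - other.e_elec,
            g_polar=self.g_polar - other.g_polar,
            g_nonpolar=self.g_nonpolar - other.g_nonpolar,
            ts=self.ts - other.ts,
            include_entropy=self.include_entropy,
        )

    def __add__(self, other: "EnergyBreakdown") -> "EnergyBreakdown":
        return EnergyBreakdown(
            e_bonded=self.e_bonded + other.e_bonded,
            e_vdw=self.e_vdw + other.e_vdw,
            e_elec=self.e_elec + other.e_elec,
            g_polar=self.g_polar + other.g_polar,
            g_nonpolar=self.g_nonpolar + other.g_nonpolar,
            ts=self.ts + other.ts,
            include_entropy=self.include_entropy,
        )


@dataclass
class BondedTerms:
    """Harmonic bond/angle plus periodic dihedral terms (impropers share the
    dihedral functional form).  Angles theta0 and phases delta in radians."""

    bonds: list[tuple[int, int, float, float]] = field(default_factory=list)
    angles: list[tuple[int, int, int, float, float]] = field(default_factory=list)
    dihedrals: list[tuple[int, int, int, int, float, int, float]] = \
        field(default_factory=list)

    def validate(self, n_atoms: int) -> None:
        for rec in self.bonds:
            if not (0 <= rec[0] < n_atoms and 0 <= rec[1] < n_atoms):
                raise EnergeticsError(f"bond {rec} references a missing atom")
            if rec[2] < 0:
                raise EnergeticsError(f"bond {rec}: force constant must be >= 0")
        for rec in self.angles:
            if any(not 0 <= i < n_atoms for i in rec[:3]):
                raise EnergeticsError(f"angle {rec} references a missing atom")
            if rec[3] < 0:
                raise EnergeticsError(f"angle {rec}: force constant must be >= 0")
        for rec in self.dihedrals:
            if any(not 0 <= i < n_atoms for i in rec[:4]):
                raise EnergeticsError(f"dihedral {rec} references a missing atom")
            if rec[4] < 0:
                raise EnergeticsError(f"dihedral {rec}: force constant must be >= 0")


@dataclass
class BindingResult:
    complex: EnergyBreakdown
    protein: EnergyBreakdown
    ligand: EnergyBreakdown
    delta: EnergyBreakdown
    per_residue: pd.Series          # residue label -> dR_x^BE [kcal/mol]
    per_atom: np.ndarray            # per-atom contribution to dG_bind


# --------------------------------------------------------------------------
# Group resolution
# --------------------------------------------------------------------------

def resolve_group(s: Structure, group) -> np.ndarray:
    """Resolve an atom group: a SelectionSpec, a ``chain:A[,B]`` string, or
    an explicit index sequence."""
    if isinstance(group, SelectionSpec):
        return group.resolve(s)
    if isinstance(group, str):
        if not group.startswith("chain:"):
            raise EnergeticsError(f"cannot parse group spec {group!r}")
        chains = {c.strip() for c in group[len("chain:"):].split(",")}
        idx = np.array([i for i, a in enumerate(s.atoms) if a.chain in chains],
                       dtype=int)
        if idx.size == 0:
            raise EnergeticsError(f"group {group!r} selects no atoms")
        return idx
    idx = np.asarray(list(group), dtype=int)
    if idx.size == 0:
        raise EnergeticsError("empty atom group")
    return np.unique(idx)


def substructure(s: Structure, idx: np.ndarray) -> Structure:
    return Structure([s.atoms[int(i)] for i in idx], s.metadata)


def _charges(s: Structure, idx: np.ndarray) -> np.ndarray:
    q = np.empty(len(idx))
    for k, i in enumerate(idx):
        a = s.atoms[int(i)]
        if a.charge is None:
            raise EnergeticsError(
                f"atom {a.chain}:{a.residue_id}:{a.name} has no charge"
            )
        q[k] = a.charge
    return q


def _lj_params(s: Structure, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sig = np.empty(len(idx))
    eps = np.empty(len(idx))
    for k, i in enumerate(idx):
        a = s.atoms[int(i)]
        if a.lj_sigma is None or a.lj_epsilon is None:
            raise EnergeticsError(
                f"atom {a.chain}:{a.residue_id}:{a.name} has no LJ parameters"
            )
        sig[k] = a.lj_sigma
        eps[k] = a.lj_epsilon
    return sig, eps


def _radii(s: Structure, idx: np.ndarray | None = None) -> np.ndarray:
    if idx is None:
        idx = np.arange(len(s))
    r = np.empty(len(idx))
    for k, i in enumerate(idx):
        a = s.atoms[int(i)]
        if a.radius is None:
            raise EnergeticsError(
                f"atom {a.chain}:{a.residue_id}:{a.name} has no radius"
            )
        r[k] = a.radius
    return r


def _pair_layout(s: Structure, group_a, group_b):
    """Classify the pair sum: identical groups -> unique internal pairs,
    disjoint groups -> cross pairs; anything else is rejected."""
    ia = resolve_group(s, group_a)
    ib = resolve_group(s, group_b)
    if np.array_equal(ia, ib):
        return ia, ib, "internal"
    if np.intersect1d(ia, ib).size:
        raise EnergeticsError("groups overlap but are not identical")
    return ia, ib, "cross"


# --------------------------------------------------------------------------
# Vacuum MM terms
# --------------------------------------------------------------------------

def _check_distances(d: np.ndarray) -> None:
    if np.any(d < 1e-9):
        raise EnergeticsError("coincident atoms (zero interatomic distance)")


def coulomb_energy(s: Structure, cfg: EnergyModelConfig,
                   group_a="chain:A", group_b="chain:A") -> float:
    """Pairwise Coulomb energy k_C * q_i q_j / (eps_solute * r_ij), summed
    over unique internal pairs (identical groups) or cross pairs (disjoint
    groups)."""
    ia, ib, layout = _pair_layout(s, group_a, group_b)
    x = s.coords
    qa, qb = _charges(s, ia), _charges(s, ib)
    d = np.linalg.norm(x[ia][:, None, :] - x[ib][None, :, :], axis=2)
    if layout == "internal":
        iu, ju = np.triu_indices(len(ia), k=1)
        _check_distances(d[iu, ju])
        e = qa[iu] * qb[ju] / d[iu, ju]
    else:
        _check_distances(d.ravel())
        e = (np.outer(qa, qb) / d).ravel()
    return float(cfg.coulomb_constant / cfg.solute_dielectric * e.sum())


def coulomb_per_atom_cross(s: Structure, cfg: EnergyModelConfig,
                           group_a, group_b) -> np.ndarray:
    """Cross-group Coulomb energy split half to each partner atom; zeros for
    atoms outside both groups.  Sums to the cross coulomb_energy."""
    ia, ib, layout = _pair_layout(s, group_a, group_b)
    if layout != "cross":
        raise EnergeticsError("per-atom cross term needs disjoint groups")
    x = s.coords
    qa, qb = _charges(s, ia), _charges(s, ib)
    d = np.linalg.norm(x[ia][:, None, :] - x[ib][None, :, :], axis=2)
    _check_distances(d.ravel())
    pair = cfg.coulomb_constant / cfg.solute_dielectric * np.outer(qa, qb) / d
    out = np.zeros(len(s))
    out[ia] += 0.5 * pair.sum(axis=1)
    out[ib] += 0.5 * pair.sum(axis=0)
    return out


def lj_energy(s: Structure, cfg: EnergyModelConfig,
              group_a="chain:A", group_b="chain:A") -> float:
    """Lennard-Jones 12-6 energy with Lorentz-Berthelot combining (sigma:
    arithmetic mean, epsilon: geometric mean)."""
    ia, ib, layout = _pair_layout(s, group_a, group_b)
    x = s.coords
    sa, ea = _lj_params(s, ia)
    sb, eb = _lj_params(s, ib)
    d = np.linalg.norm(x[ia][:, None, :] - x[ib][None, :, :], axis=2)
    sig = 0.5 * (sa[:, None] + sb[None, :])
    eps = np.sqrt(np.outer(ea, eb))
    if layout == "internal":
        iu, ju = np.triu_indices(len(ia), k=1)
        d, sig, eps = d[iu, ju], sig[iu, ju], eps[iu, ju]
    else:
        d, sig, eps = d.ravel(), sig.ravel(), eps.ravel()
    _check_distances(d)
    sr6 = (sig / d) ** 6
    return float(np.sum(4.0 * eps * (sr6 * sr6 - sr6)))


def lj_per_atom_cross(s: Structure, cfg: EnergyModelConfig,
                      group_a, group_b) -> np.ndarray:
    ia, ib, layout = _pair_layout(s, group_a, group_b)
    if layout != "cross":
        raise EnergeticsError("per-atom cross term needs disjoint groups")
    x = s.coords
    sa, ea = _lj_params(s, ia)
    sb, eb = _lj_params(s, ib)
    d = np.linalg.norm(x[ia][:, None, :] - x[ib][None, :, :], axis=2)
    _check_distances(d.ravel())
    sig = 0.5 * (sa[:, None] + sb[None, :])
    eps = np.sqrt(np.outer(ea, eb))
    sr6 = (sig / d) ** 6
    pair = 4.0 * eps * (sr6 * sr6 - sr6)
    out = np.zeros(len(s))
    out[ia] += 0.5 * pair.sum(axis=1)
    out[ib] += 0.5 * pair.sum(axis=0)
    return out


def _dihedral_angle(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    nb1 = np.linalg.norm(b1)
    if nb1 < 1e-9 or np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise EnergeticsError("degenerate dihedral geometry")
    return math.atan2(np.dot(np.cross(n1, n2), b1) / nb1, np.dot(n1, n2))


def bonded_energy(s: Structure, terms: BondedTerms | None,
                  group: np.ndarray | None = None) -> float:
    """Harmonic bonds k_b (r - r0)^2, harmonic angles k_th (theta - theta0)^2
    and periodic dihedrals k_phi (1 + cos(n*phi - delta)).  When ``group`` is
    given, only terms entirely within the group contribute."""
    if terms is None:
        return 0.0
    terms.validate(len(s))
    x = s.coords
    members = None if group is None else set(int(i) for i in group)

    def _in(idxs) -> bool:
        return members is None or all(i in members for i in idxs)

    e = 0.0
    for i, j, kb, r0 in terms.bonds:
        if not _in((i, j)):
            continue
        r = float(np.linalg.norm(x[j] - x[i]))
        e += kb * (r - r0) ** 2
    for i, j, k, kt, t0 in terms.angles:
        if not _in((i, j, k)):
            continue
        v1, v2 = x[i] - x[j], x[k] - x[j]
        n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
        if n1 < 1e-9 or n2 < 1e-9:
            raise EnergeticsError(f"degenerate angle geometry at ({i},{j},{k})")
        theta = math.acos(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))
        e += kt * (theta - t0) ** 2
    for i, j, k, l, kp, n, delta in terms.dihedrals:
        if not _in((i, j, k, l)):
            continue
        phi = _dihedral_angle(x[i], x[j], x[k], x[l])
        e += kp * (1.0 + math.cos(n * phi - delta))
    return float(e)


# --------------------------------------------------------------------------
# Finite-difference linearized Poisson-Boltzmann solver
# --------------------------------------------------------------------------

def _debye_kappa2(cfg: EnergyModelConfig) -> float:
    """Inverse squared Debye length [1/A^2] for a 1:1 electrolyte."""
    from .units import kt_kcal_mol
    if cfg.ionic_strength_mM <= 0:
        return 0.0
    bjerrum = cfg.coulomb_constant / (cfg.solvent_dielectric
                                      * kt_kcal_mol(cfg.temperature))
    number_density = cfg.ionic_strength_mM * 1e-3 * 6.02214076e-4   # 1/A^3
    return 8.0 * math.pi * bjerrum * number_density


class _PBGrid:
    """Cubic grid with node coordinates lo + index * h."""

    def __init__(self, coords, radii, cfg: EnergyModelConfig, spacing: float):
        margin = cfg.pb_padding + cfg.pb_stern
        lo = (coords - radii[:, None]).min(axis=0) - margin
        hi = (coords + radii[:, None]).max(axis=0) + margin
        self.h = spacing
        self.n = np.ceil((hi - lo) / spacing).astype(int) + 1
        if int(np.prod(self.n)) > 20_000_000:
            raise EnergeticsError(
                f"PB grid of {tuple(self.n)} nodes is too large; increase the "
                "grid spacing or shrink the system"
            )
        self.lo = lo
        self.coords_shape = tuple(self.n)

    def node_axes(self):
        return [self.lo[d] + np.arange(self.n[d]) * self.h for d in range(3)]


def _sphere_mask(grid: _PBGrid, coords, dist):
    """Boolean grid of nodes within ``dist_i`` of atom i (union)."""
    nx, ny, nz = grid.n
    mask = np.zeros(grid.coords_shape, dtype=bool)
    ax = grid.node_axes()
    for c, r in zip(coords, dist):
        i0 = np.maximum(np.floor((c - r - grid.lo) / grid.h).astype(int), 0)
        i1 = np.minimum(np.ceil((c + r - grid.lo) / grid.h).astype(int) + 1,
                        grid.n)
        if np.any(i0 >= i1):
            continue
        X = ax[0][i0[0]:i1[0]][:, None, None]
        Y = ax[1][i0[1]:i1[1]][None, :, None]
        Z = ax[2][i0[2]:i1[2]][None, None, :]
        d2 = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2
        mask[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] |= d2 <= r * r
    return mask


def _spread_charges(grid: _PBGrid, coords, q):
    """Trilinear assignment of point charges to the 8 surrounding nodes."""
    Q = np.zeros(grid.coords_shape)
    t = (coords - grid.lo) / grid.h
    base = np.floor(t).astype(int)
    frac = t - base
    if np.any(base < 1) or np.any(base + 1 > grid.n - 2):
        raise EnergeticsError("atom outside the PB grid interior")
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (np.where(dx, frac[:, 0], 1 - frac[:, 0])
                     * np.where(dy, frac[:, 1], 1 - frac[:, 1])
                     * np.where(dz, frac[:, 2], 1 - frac[:, 2]))
                np.add.at(Q, (base[:, 0] + dx, base[:, 1] + dy,
                              base[:, 2] + dz), w * q)
    return Q


def _interp_potential(grid: _PBGrid, phi, coords):
    t = (coords - grid.lo) / grid.h
    base = np.floor(t).astype(int)
    frac = t - base
    out = np.zeros(len(coords))
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (np.where(dx, frac[:, 0], 1 - frac[:, 0])
                     * np.where(dy, frac[:, 1], 1 - frac[:, 1])
                     * np.where(dz, frac[:, 2], 1 - frac[:, 2]))
                out += w * phi[base[:, 0] + dx, base[:, 1] + dy, base[:, 2] + dz]
    return out


def _boundary_potential(grid: _PBGrid, coords, q, eps, kappa: float):
    """Screened-Coulomb (Debye-Hueckel) Dirichlet values on the outer faces."""
    phi = np.zeros(grid.coords_shape)
    boundary = np.zeros(grid.coords_shape, dtype=bool)
    boundary[0, :, :] = boundary[-1, :, :] = True
    boundary[:, 0, :] = boundary[:, -1, :] = True
    boundary[:, :, 0] = boundary[:, :, -1] = True
    idx = np.argwhere(boundary)
    pts = grid.lo + idx * grid.h
    d = np.linalg.norm(pts[:, None, :] - coords[None, :, :], axis=2)
    vals = (COULOMB_CONSTANT / eps) * \
        np.sum(q[None, :] * np.exp(-kappa * d) / d, axis=1)
    phi[tuple(idx.T)] = vals
    return phi


def _solve_fd(grid: _PBGrid, eps_node, kappa2_node, Q, phi_bnd, cfg,
              coulomb_constant: float):
    """Assemble and solve the 7-point finite-difference system on interior
    nodes; returns the full potential grid."""
    nx, ny, nz = grid.n
    h = grid.h
    interior = np.zeros(grid.coords_shape, dtype=bool)
    interior[1:-1, 1:-1, 1:-1] = True
    unk = -np.ones(grid.coords_shape, dtype=np.int64)
    m = int(interior.sum())
    unk[interior] = np.arange(m)

    diag = np.zeros(grid.coords_shape)
    rhs = 4.0 * math.pi * coulomb_constant * Q / h
    rhs = rhs.copy()
    rows, cols, vals = [], [], []
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(0, -1)
        sl_b[axis] = slice(1, None)
        sl_a, sl_b = tuple(sl_a), tuple(sl_b)
        ea, eb = eps_node[sl_a], eps_node[sl_b]
        face = 2.0 * ea * eb / (ea + eb)                 # harmonic mean
        diag[sl_a] += face
        diag[sl_b] += face
        ua, ub = unk[sl_a], unk[sl_b]
        both = (ua >= 0) & (ub >= 0)
        rows.append(ua[both]); cols.append(ub[both]); vals.append(-face[both])
        rows.append(ub[both]); cols.append(ua[both]); vals.append(-face[both])
        a_only = (ua >= 0) & (ub < 0)
        rhs[sl_a][a_only] += face[a_only] * phi_bnd[sl_b][a_only]
        b_only = (ub >= 0) & (ua < 0)
        rhs[sl_b][b_only] += face[b_only] * phi_bnd[sl_a][b_only]

    diag = diag + h * h * eps_node * kappa2_node
    rows.append(unk[interior]); cols.append(unk[interior])
    vals.append(diag[interior])
    A = coo_matrix(
        (np.concatenate(vals),
         (np.concatenate(rows), np.concatenate(cols))),
        shape=(m, m),
    ).tocsr()
    b = rhs[interior]
    d_inv = 1.0 / A.diagonal()
    M = LinearOperator((m, m), matvec=lambda x: d_inv * x)
    x, info = cg(A, b, rtol=cfg.pb_rtol, atol=0.0, maxiter=cfg.pb_maxiter, M=M)
    if info != 0:
        res = np.linalg.norm(A @ x - b) / max(np.linalg.norm(b), 1e-300)
        raise EnergeticsError(
            f"PB solver did not converge in {cfg.pb_maxiter} iterations "
            f"(relative residual {res:.2e})"
        )
    phi = phi_bnd.copy()
    phi[interior] = x
    return phi


def pb_polar_per_atom(s: Structure, cfg: EnergyModelConfig,
                      spacing: float | None = None) -> np.ndarray:
    """Per-atom polar solvation energy (1/2) q_i (phi_solv - phi_vac)(r_i).

    Two linear solves on the same grid with identical charge spreading: a
    solvated run (solute dielectric inside the atom spheres, solvent outside,
    Debye screening outside the Stern layer, Debye-Hueckel boundary values)
    and a uniform-dielectric vacuum run.  The grid self-energy cancels in the
    difference.
    """
    spacing = spacing or cfg.pb_grid_spacing
    coords = s.coords
    q = _charges(s, np.arange(len(s)))
    radii = _radii(s)
    if np.allclose(q, 0.0):
        return np.zeros(len(s))
    grid = _PBGrid(coords, radii, cfg, spacing)
    inside = _sphere_mask(grid, coords, radii)
    eps_solv = np.where(inside, cfg.solute_dielectric, cfg.solvent_dielectric)
    ion_excl = _sphere_mask(grid, coords, radii + cfg.pb_stern)
    kappa2 = _debye_kappa2(cfg) * (~ion_excl)
    Q = _spread_charges(grid, coords, q)

    kappa = math.sqrt(_debye_kappa2(cfg))
    phi_b_solv = _boundary_potential(grid, coords, q,
                                     cfg.solvent_dielectric, kappa)
    phi_solv = _solve_fd(grid, eps_solv, kappa2, Q, phi_b_solv, cfg,
                         cfg.coulomb_constant)

    eps_vac = np.full(grid.coords_shape, cfg.solute_dielectric)
    phi_b_vac = _boundary_potential(grid, coords, q, cfg.solute_dielectric, 0.0)
    phi_vac = _solve_fd(grid, eps_vac, np.zeros(grid.coords_shape), Q,
                        phi_b_vac, cfg, cfg.coulomb_constant)

    dphi = _interp_potential(grid, phi_solv - phi_vac, coords)
    return 0.5 * q * dphi


def pb_polar_energy(s: Structure, cfg: EnergyModelConfig,
                    spacing: float | None = None) -> float:
    """Total polar (reaction-field) solvation energy in kcal/mol."""
    return float(pb_polar_per_atom(s, cfg, spacing).sum())


# --------------------------------------------------------------------------
# SASA nonpolar term
# --------------------------------------------------------------------------

def sasa(s: Structure, cfg: EnergyModelConfig) -> tuple[np.ndarray, float]:
    """Shrake-Rupley per-atom solvent-accessible areas [A^2] and their total,
    using the structure's own radii and the configured probe and point count."""
    radii = _radii(s)
    arr = _atom_array_from_structure(s)
    areas = struc.sasa(arr, probe_radius=cfg.sasa_probe,
                       point_number=cfg.sasa_points, ignore_ions=False,
                       vdw_radii=radii.astype(np.float32))
    areas = np.nan_to_num(np.asarray(areas, dtype=float))
    return areas, float(areas.sum())


def nonpolar_energy(total_sasa: float, cfg: EnergyModelConfig) -> float:
    """G_nonpolar = gamma * SASA + b."""
    return cfg.sasa_gamma * total_sasa + cfg.sasa_offset


# --------------------------------------------------------------------------
# MM/PBSA with per-residue decomposition
# --------------------------------------------------------------------------

def _breakdown(s: Structure, group: np.ndarray, terms: BondedTerms | None,
               cfg: EnergyModelConfig,
               spacing: float | None) -> tuple[EnergyBreakdown, np.ndarray,
                                               np.ndarray]:
    """Energy ledger of one subsystem plus its per-atom polar and SASA terms
    (arrays over the subsystem's atoms)."""
    sub = substructure(s, group)
    internal = np.arange(len(sub))
    e_bonded = bonded_energy(s, terms, group)
    e_vdw = lj_energy(sub, cfg, internal, internal)
    e_elec = coulomb_energy(sub, cfg, internal, internal)
    polar_atoms = pb_polar_per_atom(sub, cfg, spacing)
    areas, total_area = sasa(sub, cfg)
    bd = EnergyBreakdown(
        e_bonded=e_bonded, e_vdw=e_vdw, e_elec=e_elec,
        g_polar=float(polar_atoms.sum()),
        g_nonpolar=nonpolar_energy(total_area, cfg),
        ts=cfg.temperature * cfg.entropy,
        include_entropy=cfg.include_entropy,
    )
    return bd, polar_atoms, areas


def mmpbsa(complex_structure: Structure, protein_sel, ligand_sel,
           terms: BondedTerms | None = None,
           cfg: EnergyModelConfig | None = None,
           spacing: float | None = None) -> BindingResult:
    """Single-trajectory MM/PBSA on one complex geometry.

    ``protein_sel`` and ``ligand_sel`` must partition the complex atoms.  The
    unbound partners keep their complex geometry, so the bonded delta is
    identically zero.  ``spacing`` overrides the PB grid spacing (useful for
    quick, coarse runs).
    """
    cfg = cfg or EnergyModelConfig()
    prot = resolve_group(complex_structure, protein_sel)
    lig = resolve_group(complex_structure, ligand_sel)
    if np.intersect1d(prot, lig).size:
        raise EnergeticsError("protein and ligand selections overlap")
    n = len(complex_structure)
    if len(prot) + len(lig) != n:
        raise EnergeticsError("protein and ligand selections must cover the "
                              "whole complex")

    allg = np.arange(n)
    bd_c, polar_c, sasa_c = _breakdown(complex_structure, allg, terms, cfg,
                                       spacing)
    bd_p, polar_p, sasa_p = _breakdown(complex_structure, prot, terms, cfg,
                                       spacing)
    bd_l, polar_l, sasa_l = _breakdown(complex_structure, lig, terms, cfg,
                                       spacing)
    delta = bd_c - (bd_p + bd_l)

    # per-atom decomposition: MM cross terms split half/half per pair
    per_atom = coulomb_per_atom_cross(complex_structure, cfg, prot, lig)
    per_atom += lj_per_atom_cross(complex_structure, cfg, prot, lig)
    # polar: (1/2) q dphi in complex minus in the respective unbound part
    dpolar = polar_c.copy()
    dpolar[prot] -= polar_p
    dpolar[lig] -= polar_l
    per_atom += dpolar
    # nonpolar: gamma * dSASA, the offset b spread uniformly
    dsasa = sasa_c.copy()
    dsasa[prot] -= sasa_p
    dsasa[lig] -= sasa_l
    per_atom += cfg.sasa_gamma * dsasa - cfg.sasa_offset / n

    labels = [f"{a.chain}:{a.residue_id}:{a.residue_name}"
              for a in complex_structure.atoms]
    per_residue = pd.Series(per_atom).groupby(labels).sum()
    per_residue = per_residue.sort_values()
    return BindingResult(complex=bd_c, protein=bd_p, ligand=bd_l, delta=delta,
                         per_residue=per_residue, per_atom=per_atom)


_TERM_NAMES = ["e_bonded", "e_vdw", "e_elec", "g_polar", "g_nonpolar",
               "g_total"]


def mmpbsa_trajectory(traj: Trajectory, protein_sel, ligand_sel,
                      terms: BondedTerms | None = None,
                      cfg: EnergyModelConfig | None = None,
                      spacing: float | None = None
                      ) -> tuple[list[BindingResult], pd.DataFrame]:
    """MM/PBSA averaged over frames: per-frame results plus a summary table
    with the arithmetic mean and standard deviation of every delta term."""
    results = [mmpbsa(f, protein_sel, ligand_sel, terms, cfg, spacing)
               for f in traj.frames]
    rows = []
    for k, r in enumerate(results):
        row = {"frame": k}
        for t in _TERM_NAMES:
            row[t] = getattr(r.delta, t) if t != "g_total" else r.delta.g_total
        rows.append(row)
    df = pd.DataFrame(rows)
    summary = df[_TERM_NAMES].agg(["mean", "std"])
    return results, pd.concat(
        [df, summary.reset_index().rename(columns={"index": "frame"})],
        ignore_index=True,
    )


# --------------------------------------------------------------------------
# Computational alanine scanning
# --------------------------------------------------------------------------

def mutate_to_alanine(s: Structure,
                      residues: list[tuple[str, int]]) -> Structure:
    """Truncate the named residues to alanine.

    Side-chain atoms beyond C-beta are removed and the C-beta charge is reset
    so the residue is net-neutral on its remaining atoms; backbone geometry
    is unchanged.  Glycine (no C-beta) and proline (backbone ring) are
    rejected.
    """
    wanted = {(str(c), int(r)) for c, r in residues}
    res_names: dict[tuple[str, int], str] = {}
    for a in s.atoms:
        res_names.setdefault((a.chain, a.residue_id), a.residue_name)
    missing = wanted - set(res_names)
    if missing:
        raise EnergeticsError(f"residues not found: {sorted(missing)}")
    for key in sorted(wanted):
        if res_names[key] == "GLY":
            raise EnergeticsError(
                f"{key}: glycine has no C-beta to truncate to alanine")
        if res_names[key] == "PRO":
            raise EnergeticsError(
                f"{key}: proline's backbone ring cannot be truncated cleanly")
    # alanines in the list are a no-op; only other residues are truncated
    to_mutate = {k for k in wanted if res_names[k] != "ALA"}
    kept = []
    for a in s.atoms:
        key = (a.chain, a.residue_id)
        if key not in to_mutate:
            kept.append(a)
        elif a.name in BACKBONE_NAMES:
            kept.append(replace(a, residue_name="ALA"))
    backbone_sum = {k: 0.0 for k in to_mutate}
    for a in kept:
        key = (a.chain, a.residue_id)
        if key in to_mutate and a.name != "CB":
            backbone_sum[key] += a.charge or 0.0
    out = []
    for a in kept:
        key = (a.chain, a.residue_id)
        if key in to_mutate and a.name == "CB":
            out.append(replace(a, charge=-backbone_sum[key]))
        else:
            out.append(a)
    return Structure(out, s.metadata)


def alanine_scan(complex_structure: Structure,
                 residues: list[tuple[str, int]],
                 protein_sel, ligand_sel,
                 terms: BondedTerms | None = None,
                 cfg: EnergyModelConfig | None = None,
                 spacing: float | None = None) -> BindingResult:
    """Binding energy of the (possibly multiple-site) alanine mutant.

    All listed residues are mutated simultaneously and dG_bind is
    re-evaluated on the unchanged backbone geometry.  Group selections must
    be chain-based or SelectionSpec (atom indices shift after truncation).
    """
    if isinstance(protein_sel, (list, tuple, np.ndarray)) or \
            isinstance(ligand_sel, (list, tuple, np.ndarray)):
        raise EnergeticsError("alanine_scan needs chain- or spec-based group "
                              "selections, not raw indices")
    mutant = mutate_to_alanine(complex_structure, residues)
    return mmpbsa(mutant, protein_sel, ligand_sel, terms, cfg, spacing)


def alanine_scan_table(complex_structure: Structure,
                       mutants: dict[str, list[tuple[str, int]]],
                       protein_sel, ligand_sel,
                       terms: BondedTerms | None = None,
                       cfg: EnergyModelConfig | None = None,
                       spacing: float | None = None
                       ) -> tuple[dict[str, BindingResult], pd.DataFrame]:
    """Wild type plus named mutants, with a delta-term comparison table."""
    wt = mmpbsa(complex_structure, protein_sel, ligand_sel, terms, cfg, spacing)
    results = {"wild_type": wt}
    rows = [{"mutant": "wild_type",
             **{t: getattr(wt.delta, t) for t in _TERM_NAMES[:-1]},
             "g_total": wt.delta.g_total, "ddG": 0.0}]
    for name, residues in mutants.items():
        r = alanine_scan(complex_structure, residues, protein_sel, ligand_sel,
                         terms, cfg, spacing)
        results[name] = r
        rows.append({"mutant": name,
                     **{t: getattr(r.delta, t) for t in _TERM_NAMES[:-1]},
                     "g_total": r.delta.g_total,
                     "ddG": r.delta.g_total - wt.delta.g_total})
    return results, pd.DataFrame(rows)
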