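"""Seeded generators standing in for the study's MD and docking data.

Four families of fixtures:

* two-state protein references — a two-domain C-alpha model whose "locked"
  state differs from the "open" one by a rigid rotation of the C-terminal
  domain about its long axis plus an approach toward the N-terminal domain,
  the motion that distinguishes the crystallographic end states of the
  adaptor cargo-binding subunit;
* trajectories concentrated around a target value of the open/locked
  coordinate with Gaussian positional noise and per-frame rigid scatter;
* idealized sphere / rod / needle charged nanoparticles with declarative
  surface-charge patterns (sphere: alternating weak-positive/strong-negative
  patches; needle: positive tips on a negative body; rod: weakly positive);
* a small fully parameterized protein-particle complex for the
  binding-energy engine.

All generators are pure functions of their spec (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conformation import CALPHA, ReferencePair
from .io_model import Atom, ParameterTable, SelectionSpec, Structure, Trajectory
from .surface import Nanoparticle

# idealized alpha-helix used for all generated C-alpha traces
_HELIX_RADIUS = 2.3      # A
_HELIX_RISE = 1.5        # A per residue
_HELIX_TWIST = 100.0     # degrees per residue


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via a normalized random quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _helix_coords(n: int, z0: float) -> np.ndarray:
    i = np.arange(n)
    ang = np.deg2rad(_HELIX_TWIST) * i
    return np.column_stack([
        _HELIX_RADIUS * np.cos(ang),
        _HELIX_RADIUS * np.sin(ang),
        z0 + _HELIX_RISE * i,
    ])


# --------------------------------------------------------------------------
# Two-state references and lambda-targeted trajectories
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoStateSpec:
    """Geometry of the open/locked reference pair.

    ``rotation_angle`` [degrees, (0, 180]] turns the C-domain about its long
    axis; ``translation`` [A] moves it toward the N-domain.  A spec with both
    zero is rejected: the transition axis would be undefined.
    """

    n_residues_N_domain: int = 20
    n_residues_C_domain: int = 12
    rotation_angle: float = 35.0
    translation: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.n_residues_N_domain < 3 or self.n_residues_C_domain < 3:
            raise ValueError("both domains need at least 3 residues")
        if not (0.0 <= self.rotation_angle <= 180.0):
            raise ValueError("rotation_angle must lie in [0, 180] degrees")
        if self.rotation_angle == 0.0 and self.translation == 0.0:
            raise ValueError("degenerate spec: zero rotation and zero "
                             "translation leave the lambda axis undefined")


def make_two_state_references(spec: TwoStateSpec,
                              selection: SelectionSpec = CALPHA) -> ReferencePair:
    """Generate the open (v1) and locked (v2) reference structures.

    Both domains are C-alpha helix traces on a common axis (N-domain below,
    C-domain above, 4 A gap).  v2 applies the spec's rigid motion to the
    C-domain only, so N-domain coordinates are identical between the states
    by construction.
    """
    n1, n2 = spec.n_residues_N_domain, spec.n_residues_C_domain
    rng = _rng(spec.seed)
    xyz_n = _helix_coords(n1, 0.0)
    z_top = xyz_n[-1, 2] + 4.0
    xyz_c = _helix_coords(n2, z_top)
    open_coords = np.vstack([xyz_n, xyz_c])
    # small seeded jitter breaks the helix symmetry (useful for normal modes)
    open_coords = open_coords + rng.normal(scale=0.25, size=open_coords.shape)

    theta = np.deg2rad(spec.rotation_angle)
    c, s = np.cos(theta), np.sin(theta)
    rot_z = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    locked_coords = open_coords.copy()
    cdom = locked_coords[n1:]
    axis_point = np.array([0.0, 0.0, cdom[:, 2].mean()])
    cdom = (cdom - axis_point) @ rot_z.T + axis_point
    cdom[:, 2] -= spec.translation           # approach toward the N-domain
    locked_coords[n1:] = cdom

    atoms = [
        Atom(name="CA", element="C", residue_id=i + 1, residue_name="ALA",
             chain="A", position=open_coords[i])
        for i in range(n1 + n2)
    ]
    meta = {"n_domain": (1, n1), "c_domain": (n1 + 1, n1 + n2)}
    v1 = Structure(atoms, metadata=meta)
    v2 = v1.with_coords(locked_coords)
    v2.metadata = dict(meta)
    return ReferencePair(v1=v1, v2=v2, selection=selection)


@dataclass(frozen=True)
class TrajectorySpec:
    """Frames at v1 + lambda_target*(v2 - v1) plus isotropic Gaussian noise,
    optionally rigidly rotated/translated per frame (on by default, so the
    superposition step is always exercised)."""

    lambda_target: float = 0.5
    positional_noise_sd: float = 0.5
    n_frames: int = 100
    seed: int = 0
    rigid_scatter: bool = True

    def __post_init__(self):
        if not (0.0 <= self.lambda_target <= 1.0):
            raise ValueError("lambda_target must lie in [0, 1]")
        if self.positional_noise_sd < 0:
            raise ValueError("positional_noise_sd must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


def make_trajectory(refs: ReferencePair, spec: TrajectorySpec) -> Trajectory:
    """Sample a trajectory around a target point on the open/locked axis.

    Interpolation runs along the aligned axis (v2 superposed onto v1), so
    with zero noise every frame sits exactly at ``lambda_target``, with or
    without rigid scatter.
    """
    rng = _rng(spec.seed)
    x1 = refs.v1.coords
    x2 = refs.v2_aligned.coords
    base = x1 + spec.lambda_target * (x2 - x1)
    frames = []
    for _ in range(spec.n_frames):
        coords = base
        if spec.positional_noise_sd > 0:
            coords = coords + rng.normal(scale=spec.positional_noise_sd,
                                         size=coords.shape)
        if spec.rigid_scatter:
            rot = _random_rotation(rng)
            shift = rng.uniform(-20.0, 20.0, size=3)
            center = coords.mean(axis=0)
            coords = (coords - center) @ rot.T + center + shift
        frames.append(refs.v1.with_coords(coords))
    return Trajectory(frames)


# --------------------------------------------------------------------------
# Idealized charged nanoparticles
# --------------------------------------------------------------------------

# length:width conventions for the elongated shapes
ROD_ASPECT = 3.0
NEEDLE_ASPECT = 8.0

# azimuthal sectors for the alternating sphere charge patches
_N_SECTORS = 8

DEFAULT_SIZES_NM = {"sphere": 1.926, "rod": 3.0, "needle": 4.8}

# declarative surface-charge patterns emulating the qualitative potential
# maps of the three morphologies: region name -> site charge [e]
DEFAULT_PATTERNS = {
    "sphere": {"shell_even": 0.2, "shell_odd": -0.5},
    "needle": {"tips": 0.4, "body": -0.25},
    "rod": {"shell": 0.08},
}


@dataclass(frozen=True)
class ParticleSpec:
    """A lattice-carved point-charge particle.

    ``characteristic_size`` [nm] is the sphere diameter or the rod/needle
    length (width follows from the aspect ratio).  ``site_charge_pattern``
    maps region names (all, core, shell, shell_even, shell_odd, tips, body)
    to site charges in e; regions are applied in order, later entries
    overriding earlier ones, and uncovered sites stay neutral.
    """

    shape: str = "sphere"
    characteristic_size: float | None = None
    lattice_spacing: float = 3.0
    site_charge_pattern: tuple[tuple[str, float], ...] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.shape not in {"sphere", "rod", "needle"}:
            raise ValueError(f"unknown particle shape {self.shape!r}")
        if self.lattice_spacing <= 0:
            raise ValueError("lattice_spacing must be positive")
        if self.characteristic_size is not None and self.characteristic_size <= 0:
            raise ValueError("characteristic_size must be positive")

    @property
    def size_nm(self) -> float:
        return self.characteristic_size or DEFAULT_SIZES_NM[self.shape]

    @property
    def pattern(self) -> tuple[tuple[str, float], ...]:
        if self.site_charge_pattern is not None:
            return tuple(self.site_charge_pattern)
        return tuple(DEFAULT_PATTERNS[self.shape].items())


def nominal_area(spec: ParticleSpec) -> float:
    """Geometric surface area [A^2] of the spec's idealized shape (sphere, or
    spherocylinder for rod/needle)."""
    size = spec.size_nm * 10.0
    if spec.shape == "sphere":
        r = size / 2.0
        return 4.0 * np.pi * r * r
    width = size / (ROD_ASPECT if spec.shape == "rod" else NEEDLE_ASPECT)
    r = width / 2.0
    half_core = size / 2.0 - r
    return 4.0 * np.pi * r * r + 2.0 * np.pi * r * (2.0 * half_core)


def _capsule_axis_distance(pts: np.ndarray, half_core: float) -> np.ndarray:
    """Distance from points to the z-axis segment [-half_core, +half_core]."""
    z = np.clip(pts[:, 2], -half_core, half_core)
    return np.sqrt(pts[:, 0] ** 2 + pts[:, 1] ** 2 + (pts[:, 2] - z) ** 2)


def make_particle(spec: ParticleSpec) -> Nanoparticle:
    """Carve sites from a cubic lattice clipped to the shape and apply the
    charge pattern by region."""
    h = spec.lattice_spacing
    size = spec.size_nm * 10.0                      # nm -> A
    rng = _rng(spec.seed)
    if spec.shape == "sphere":
        radius = size / 2.0
        half_extent = radius
    else:
        length = size
        width = size / (ROD_ASPECT if spec.shape == "rod" else NEEDLE_ASPECT)
        radius = width / 2.0
        half_core = length / 2.0 - radius           # spherocylinder core
        if half_core <= 0:
            raise ValueError("particle length must exceed its width")
        half_extent = length / 2.0

    n_side = int(np.floor(half_extent / h))
    grid = np.arange(-n_side, n_side + 1)
    ii, jj, kk = np.meshgrid(grid, grid, grid, indexing="ij")
    idx = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    pts = idx * h

    def _inside(points: np.ndarray) -> np.ndarray:
        if spec.shape == "sphere":
            return np.linalg.norm(points, axis=1) <= radius
        return _capsule_axis_distance(points, half_core) <= radius

    inside = _inside(pts)
    if inside.sum() < 2:
        raise ValueError(
            "lattice_spacing too large: the lattice cannot resolve the shape")
    pts, idx = pts[inside], idx[inside]

    # shell = boundary sites (a 6-neighbor falls outside the shape); their
    # count tracks the geometric surface area across sizes
    shell = np.zeros(len(pts), dtype=bool)
    for d in np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                       [0, -1, 0], [0, 0, 1], [0, 0, -1]]) * h:
        shell |= ~_inside(pts + d)
    # alternating azimuthal wedges with equal site counts: wedge membership
    # by azimuth *rank*, so the even/odd split is balanced to within a couple
    # of sites regardless of how lattice planes intersect the surface (a
    # lattice checkerboard or fixed-angle sectors would be badly biased)
    parity = np.zeros(len(pts), dtype=bool)
    shell_order = np.flatnonzero(shell)[
        np.argsort(np.arctan2(pts[shell, 1], pts[shell, 0]), kind="stable")]
    for w, wedge in enumerate(np.array_split(shell_order, _N_SECTORS)):
        parity[wedge] = (w % 2 == 0)
    if spec.shape == "needle":
        length = size
        tips = np.abs(pts[:, 2]) >= length / 2.0 - 0.18 * length
    else:
        tips = np.zeros(len(pts), dtype=bool)
    regions = {
        "all": np.ones(len(pts), dtype=bool),
        "core": ~shell,
        "shell": shell,
        "shell_even": shell & parity,
        "shell_odd": shell & ~parity,
        "tips": tips,
        "body": ~tips,
    }
    charges = np.zeros(len(pts))
    labels = np.array(["uncharged"] * len(pts), dtype=object)
    for region, q in spec.pattern:
        if region not in regions:
            raise ValueError(f"unknown pattern region {region!r}")
        mask = regions[region]
        charges[mask] = q
        labels[mask] = region
    # small seeded jitter so lattice planes are not perfectly degenerate
    pts = pts + rng.normal(scale=0.05, size=pts.shape)
    return Nanoparticle(positions=pts, charges=charges,
                        labels=list(labels), shape=spec.shape)


# --------------------------------------------------------------------------
# Protein-particle complex fixture for the binding-energy engine
# --------------------------------------------------------------------------

# toy amino-acid parameter set: backbone charges sum to -0.20 per residue,
# the C-beta carries +0.20, charged side-chain tips carry the formal charge
_BACKBONE = {
    # name: (charge e, sigma A, epsilon kcal/mol, radius A, element)
    "N": (-0.35, 3.30, 0.17, 1.65, "N"),
    "CA": (0.10, 3.50, 0.08, 1.90, "C"),
    "C": (0.45, 3.50, 0.08, 1.90, "C"),
    "O": (-0.40, 3.10, 0.17, 1.60, "O"),
}
_CB = (0.20, 3.40, 0.10, 1.90, "C")
_TIPS = {
    "ASP": ("OD1", -1.0, 3.00, 0.15, 1.55, "O"),
    "GLU": ("OE1", -1.0, 3.00, 0.15, 1.55, "O"),
    "LYS": ("NZ", 1.0, 3.25, 0.17, 1.65, "N"),
    "ARG": ("NH1", 1.0, 3.25, 0.17, 1.65, "N"),
    "GLN": ("NE2", 0.0, 3.25, 0.17, 1.65, "N"),
}
_PARTICLE_SITE = (3.2, 0.12, 1.70)   # sigma, epsilon, radius for HAP sites

DEFAULT_COMPLEX_SEQUENCE = (
    "LYS", "ASP", "GLU", "GLN", "ALA", "LYS", "ARG", "LYS", "ALA", "GLU",
)


def _build_peptide(sequence: tuple[str, ...], rng: np.random.Generator) -> Structure:
    ca = _helix_coords(len(sequence), 0.0)
    ca = ca + rng.normal(scale=0.15, size=ca.shape)
    atoms: list[Atom] = []
    for i, res in enumerate(sequence):
        prev_ca = ca[i - 1] if i > 0 else ca[i] - np.array([0.0, 0.0, _HELIX_RISE])
        next_ca = ca[i + 1] if i < len(sequence) - 1 else \
            ca[i] + np.array([0.0, 0.0, _HELIX_RISE])
        t = next_ca - prev_ca
        t = t / np.linalg.norm(t)
        radial = ca[i] - np.array([0.0, 0.0, ca[i][2]])
        r_hat = radial / np.linalg.norm(radial)
        n_hat = np.cross(t, r_hat)
        n_hat /= np.linalg.norm(n_hat)
        placements = {
            "N": ca[i] - 1.2 * t + 0.35 * r_hat,
            "CA": ca[i],
            "C": ca[i] + 1.2 * t + 0.35 * r_hat,
            "O": ca[i] + 1.2 * t + 0.9 * r_hat + 0.9 * n_hat,
        }
        for name, (q, sig, eps, rad, elem) in _BACKBONE.items():
            atoms.append(Atom(name=name, element=elem, residue_id=i + 1,
                              residue_name=res, chain="A",
                              position=placements[name], charge=q,
                              lj_sigma=sig, lj_epsilon=eps, radius=rad))
        if res != "GLY":
            q, sig, eps, rad, elem = _CB
            atoms.append(Atom(name="CB", element=elem, residue_id=i + 1,
                              residue_name=res, chain="A",
                              position=ca[i] + 1.5 * r_hat, charge=q,
                              lj_sigma=sig, lj_epsilon=eps, radius=rad))
        if res in _TIPS:
            name, q, sig, eps, rad, elem = _TIPS[res]
            atoms.append(Atom(name=name, element=elem, residue_id=i + 1,
                              residue_name=res, chain="A",
                              position=ca[i] + 3.2 * r_hat, charge=q,
                              lj_sigma=sig, lj_epsilon=eps, radius=rad))
    return Structure(atoms)


def particle_as_structure(particle: Nanoparticle, chain: str = "X") -> Structure:
    """Represent particle sites as HETATM-style atoms (one residue per site)
    so the particle can join a complex Structure for energetics."""
    sig, eps, rad = _PARTICLE_SITE
    atoms = []
    for i in range(particle.n_sites):
        q = float(particle.charges[i])
        elem = "Ca" if q > 0 else ("P" if q < 0 else "O")
        atoms.append(Atom(name=f"S{i + 1}", element=elem, residue_id=i + 1,
                          residue_name="HAP", chain=chain,
                          position=particle.positions[i], charge=q,
                          lj_sigma=sig, lj_epsilon=eps, radius=rad))
    return Structure(atoms)


def merge_structures(a: Structure, b: Structure) -> Structure:
    return Structure(a.atoms + b.atoms, {**a.metadata, **b.metadata})


def make_complex(seed: int = 0) -> tuple[Structure, Nanoparticle, ParameterTable]:
    """A small charged peptide plus a nearby charged sphere, fully
    parameterized, with an attractive contact region (positive side chains
    facing the mostly negative particle surface)."""
    rng = _rng(seed)
    protein = _build_peptide(DEFAULT_COMPLEX_SEQUENCE, rng)
    spec = ParticleSpec(shape="sphere", characteristic_size=1.2,
                        lattice_spacing=3.0,
                        site_charge_pattern=(("shell_even", 0.1),
                                             ("shell_odd", -0.4)),
                        seed=seed)
    particle = make_particle(spec)
    # park the particle off the helix flank, ~5 A from the outermost tips
    ca_z = np.array([a.position[2] for a in protein.atoms])
    center = np.array([14.0, 0.0, float(ca_z.mean())])
    positions = particle.positions - particle.positions.mean(axis=0) + center
    particle = Nanoparticle(positions=positions, charges=particle.charges,
                            labels=particle.labels, shape=particle.shape,
                            site_radius=particle.site_radius)
    complex_structure = merge_structures(protein, particle_as_structure(particle))
    table = ParameterTable.from_structure(complex_structure)
    return protein, particle, table
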