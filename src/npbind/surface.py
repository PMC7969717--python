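"""Charged-nanoparticle surface characterization.

A nanoparticle is a set of point-charge interaction sites.  The module
samples the solvent-accessible union-of-spheres surface, maps the Coulomb
electrostatic potential onto it in units of kT/e, classifies signed surface
patches, and tabulates size/charge/area descriptors such as the surface
charge density (total charge over accessible area).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .units import COULOMB_CONSTANT, kt_kcal_mol

DEFAULT_SITE_RADIUS = 1.5   # A; effective radius of a charged site
DEFAULT_PROBE = 1.4         # A; water-probe radius for the accessible surface


@dataclass
class Nanoparticle:
    """Point-charge site model of a particle (positions [A], charges [e])."""

    positions: np.ndarray
    charges: np.ndarray
    labels: list[str] = field(default_factory=list)
    shape: str = "other"
    site_radius: float = DEFAULT_SITE_RADIUS

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.charges = np.asarray(self.charges, dtype=float)
        if self.positions.shape[0] == 0:
            raise ValueError("a Nanoparticle needs at least one site")
        if self.positions.shape[0] != self.charges.shape[0]:
            raise ValueError("positions and charges differ in length")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("site positions must be finite")
        if not self.labels:
            self.labels = ["site"] * len(self.charges)

    @property
    def n_sites(self) -> int:
        return len(self.charges)

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())


@dataclass
class SurfaceMap:
    """Surface sample points with electrostatic potentials.

    ``potentials`` are in kT/e at the map's temperature; ``area`` in nm^2;
    ``charge_density`` in e/nm^2.
    """

    points: np.ndarray
    potentials: np.ndarray
    area: float
    total_charge: float
    temperature: float

    def __post_init__(self):
        if len(self.points) != len(self.potentials):
            raise ValueError("points and potentials differ in length")
        if self.area <= 0:
            raise ValueError("surface area must be positive")

    @property
    def charge_density(self) -> float:
        return self.total_charge / self.area


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit-sphere directions (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + 5.0 ** 0.5) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def surface_points(p: Nanoparticle, probe: float = DEFAULT_PROBE,
                   density: float = 0.5) -> np.ndarray:
    """Sample the outer (solvent-accessible) union-of-spheres surface.

    Each site contributes a sphere of radius ``site_radius + probe`` sampled
    with ``density`` points per A^2; points falling inside any other site's
    sphere are discarded.  Deterministic for a fixed density.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    r = p.site_radius + probe
    n_per_site = max(int(round(density * 4.0 * np.pi * r * r)), 8)
    shell = _fibonacci_sphere(n_per_site) * r
    pts = (p.positions[:, None, :] + shell[None, :, :]).reshape(-1, 3)
    owner = np.repeat(np.arange(p.n_sites), n_per_site)
    tree = cKDTree(p.positions)
    # a point is buried if any *other* site center is closer than r
    neighbor_lists = tree.query_ball_point(pts, r * (1 - 1e-9))
    keep = np.array(
        [all(j == owner[k] for j in nb) for k, nb in enumerate(neighbor_lists)]
    )
    return pts[keep]


def accessible_area(p: Nanoparticle, probe: float = DEFAULT_PROBE,
                    density: float = 0.5) -> float:
    """Accessible area [A^2] from the exposed fraction of each site sphere."""
    r = p.site_radius + probe
    n_per_site = max(int(round(density * 4.0 * np.pi * r * r)), 8)
    pts = surface_points(p, probe, density)
    exposed_fraction = len(pts) / (p.n_sites * n_per_site)
    return p.n_sites * 4.0 * np.pi * r * r * exposed_fraction


def electrostatic_map(p: Nanoparticle, points: np.ndarray,
                      temperature: float = 300.0,
                      probe: float = DEFAULT_PROBE,
                      density: float = 0.5) -> SurfaceMap:
    """Coulomb potential of the site charges at the sample points, in kT/e.

    phi(x) = k_C * sum_i q_i / |x - r_i|  [kcal/mol/e], divided by k_B*T*N_A
    at the given temperature.  Unscreened vacuum potentials: the map renders
    the particle's own fixed charges.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 0:
        raise ValueError("no sample points given")
    d = np.linalg.norm(points[:, None, :] - p.positions[None, :, :], axis=2)
    if np.any(d < 1e-9):
        raise ValueError("a sample point coincides with a charge site")
    phi_kcal = COULOMB_CONSTANT * (p.charges[None, :] / d).sum(axis=1)
    phi = phi_kcal / kt_kcal_mol(temperature)
    area_nm2 = accessible_area(p, probe, density) / 100.0
    return SurfaceMap(points=points, potentials=phi, area=area_nm2,
                      total_charge=p.total_charge, temperature=temperature)


def classify_patches(m: SurfaceMap, threshold: float = 0.0,
                     adjacency_radius: float | None = None) -> pd.DataFrame:
    """Label surface points by potential sign and group them into patches.

    Points with |phi| <= threshold are neutral.  Patches are connected
    components of same-label points under an adjacency radius (default twice
    the mean nearest-neighbor spacing).  Returns one row per point with
    columns x, y, z, potential, label, patch; patch ids are -1 for neutral
    points and otherwise numbered by descending patch size.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    phi = m.potentials
    labels = np.where(phi > threshold, "positive",
                      np.where(phi < -threshold, "negative", "neutral"))
    pts = m.points
    tree = cKDTree(pts)
    if adjacency_radius is None:
        if len(pts) > 1:
            nn = tree.query(pts, k=2)[0][:, 1]
            adjacency_radius = 2.0 * float(np.mean(nn))
        else:
            adjacency_radius = 1.0
    pairs = tree.query_pairs(adjacency_radius, output_type="ndarray")
    patch = np.full(len(pts), -1, dtype=int)
    signed = labels != "neutral"
    if signed.any():
        same = signed[pairs[:, 0]] & signed[pairs[:, 1]] & \
            (labels[pairs[:, 0]] == labels[pairs[:, 1]]) if len(pairs) else \
            np.zeros(0, dtype=bool)
        rows = pairs[same] if len(pairs) else np.zeros((0, 2), dtype=int)
        adj = coo_matrix(
            (np.ones(len(rows)), (rows[:, 0], rows[:, 1])),
            shape=(len(pts), len(pts)),
        )
        n_comp, comp = connected_components(adj, directed=False)
        # keep components of signed points only, renumber by descending size
        comp_ids, counts = np.unique(comp[signed], return_counts=True)
        order = comp_ids[np.argsort(-counts)]
        renum = {int(c): k for k, c in enumerate(order)}
        patch[signed] = [renum[int(c)] for c in comp[signed]]
    return pd.DataFrame({
        "x": pts[:, 0], "y": pts[:, 1], "z": pts[:, 2],
        "potential": phi, "label": labels, "patch": patch,
    })


def patch_summary(point_table: pd.DataFrame, area: float) -> pd.DataFrame:
    """Aggregate the per-point table into per-patch areas and mean potentials.

    ``area`` is the total accessible area [nm^2]; each patch is assigned the
    share of area proportional to its point count.
    """
    total_points = len(point_table)
    rows = []
    for (patch, label), grp in point_table[point_table["patch"] >= 0].groupby(
            ["patch", "label"]):
        rows.append({
            "patch": int(patch), "label": label, "n_points": len(grp),
            "area_nm2": area * len(grp) / total_points,
            "mean_potential": float(grp["potential"].mean()),
            "z_center": float(grp["z"].mean()),
        })
    return pd.DataFrame(rows).sort_values("patch").reset_index(drop=True)


def size_series_density(specs: list) -> pd.DataFrame:
    """Size / total-charge / area / charge-density table for a shape family.

    ``specs`` is a list of particle specs sharing one shape; each is built
    and tabulated against its shape's nominal geometric surface area.  The
    returned frame carries a ``relative_spread`` attribute: (max - min) /
    |mean| of the charge density, the quantity that is nearly constant for a
    surface-charged size series.
    """
    from .synthetic import make_particle, nominal_area
    if len(specs) < 2:
        raise ValueError("a size series needs at least 2 particle specs")
    shapes = {spec.shape for spec in specs}
    if len(shapes) > 1:
        raise ValueError(f"mixed shapes in size series: {sorted(shapes)}")
    rows = []
    for spec in specs:
        p = make_particle(spec)
        area = nominal_area(spec) / 100.0   # nm^2
        rows.append({
            "size_nm": spec.size_nm,
            "n_sites": p.n_sites,
            "total_charge_e": p.total_charge,
            "area_nm2": area,
            "charge_density_e_nm2": p.total_charge / area,
        })
    df = pd.DataFrame(rows)
    dens = df["charge_density_e_nm2"]
    df.attrs["relative_spread"] = float(
        (dens.max() - dens.min()) / abs(dens.mean())
    )
    return df
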