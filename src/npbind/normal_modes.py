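"""Anisotropic elastic-network normal-mode analysis on C-alpha nodes.

The protein is reduced to its C-alpha atoms connected by uniform harmonic
springs within a distance cutoff.  The Hessian of the pairwise harmonic
energy E = (k/2) * sum_pairs (|r_ij| - |r_ij0|)^2 evaluated at the input
geometry has 3x3 super-blocks -k * (dr dr^T)/|dr|^2 off the diagonal and
negative row sums on the diagonal; its low-frequency eigenvectors are the
collective motions.  Spring constants are in arbitrary units (the analysis
reports mode shapes and relative stiffness, not absolute frequencies).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .conformation import CALPHA, ReferencePair
from .io_model import SelectionSpec, Structure

DEFAULT_CUTOFF = 15.0     # A
DEFAULT_K = 1.0

# relative eigenvalue threshold below which a mode counts as rigid-body
RIGID_THRESHOLD = 1e-8


@dataclass
class ENMModel:
    nodes: np.ndarray          # (N, 3) C-alpha positions [A]
    cutoff: float
    spring_constant: float
    hessian: np.ndarray        # (3N, 3N), symmetric PSD
    contacts: np.ndarray       # boolean (N, N) spring map
    node_residues: list[int]   # residue id per node


@dataclass
class ModeSet:
    eigenvalues: np.ndarray    # ascending, the n_modes lowest non-trivial
    eigenvectors: np.ndarray   # (3N, n_modes), orthonormal columns
    n_trivial: int

    def node_amplitudes(self, mode: int) -> np.ndarray:
        """Per-node displacement magnitude of one mode."""
        v = self.eigenvectors[:, mode].reshape(-1, 3)
        return np.linalg.norm(v, axis=1)


def _collinear(nodes: np.ndarray) -> bool:
    centered = nodes - nodes.mean(axis=0)
    return np.linalg.matrix_rank(centered, tol=1e-8) < 2


def build_enm(s: Structure, cutoff: float = DEFAULT_CUTOFF,
              k: float = DEFAULT_K,
              sel: SelectionSpec = CALPHA) -> ENMModel:
    """Build the anisotropic-network Hessian on the selected nodes."""
    idx = sel.resolve(s)
    nodes = s.coords[idx]
    n = len(nodes)
    if n < 2:
        raise ValueError("an elastic network needs at least 2 nodes")
    if n >= 3 and _collinear(nodes):
        # transverse directions carry no ANM stiffness, flooding the spectrum
        # with spurious zero modes
        raise ValueError("nodes are collinear; the elastic network is degenerate")
    dist = squareform(pdist(nodes))
    contacts = (dist <= cutoff) & ~np.eye(n, dtype=bool)
    if not contacts.any():
        raise ValueError("no node pair falls within the cutoff")
    hessian = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for j in range(i + 1, n):
            if not contacts[i, j]:
                continue
            dr = nodes[j] - nodes[i]
            block = -k * np.outer(dr, dr) / (dr @ dr)
            hessian[3 * i:3 * i + 3, 3 * j:3 * j + 3] = block
            hessian[3 * j:3 * j + 3, 3 * i:3 * i + 3] = block
            hessian[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
            hessian[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= block
    residues = [s.atoms[i].residue_id for i in idx]
    return ENMModel(nodes=nodes, cutoff=float(cutoff), spring_constant=float(k),
                    hessian=hessian, contacts=contacts, node_residues=residues)


def enm_energy(model: ENMModel, coords: np.ndarray) -> float:
    """Pairwise harmonic energy of a deformed geometry (0 at the reference
    and for any rigid transformation of it)."""
    coords = np.asarray(coords, dtype=float)
    i, j = np.triu_indices(len(model.nodes), k=1)
    on = model.contacts[i, j]
    i, j = i[on], j[on]
    d0 = np.linalg.norm(model.nodes[j] - model.nodes[i], axis=1)
    d = np.linalg.norm(coords[j] - coords[i], axis=1)
    return float(0.5 * model.spring_constant * np.sum((d - d0) ** 2))


def compute_modes(model: ENMModel, n_modes: int = 5) -> ModeSet:
    """The ``n_modes`` lowest non-trivial modes.

    Rigid-body modes are identified by a relative eigenvalue threshold, with
    a sanity check that their count matches the geometry (6 in general; 5
    for the diatomic, whose spin about the bond axis is absent).
    """
    evals, evecs = np.linalg.eigh(model.hessian)
    evals = np.clip(evals, 0.0, None)        # numerically tiny negatives
    thresh = RIGID_THRESHOLD * max(evals[-1], 1.0)
    n_trivial = int(np.sum(evals < thresh))
    expected = 5 if len(model.nodes) == 2 else 6
    if n_trivial != expected:
        raise ValueError(
            f"found {n_trivial} near-zero modes, expected {expected}; "
            "the network may be disconnected or degenerate"
        )
    available = len(evals) - n_trivial
    if n_modes > available:
        raise ValueError(f"requested {n_modes} modes but only {available} "
                         "non-trivial modes exist")
    sl = slice(n_trivial, n_trivial + n_modes)
    return ModeSet(eigenvalues=evals[sl], eigenvectors=evecs[:, sl],
                   n_trivial=n_trivial)


def mode_overlap(modes: ModeSet, refs: ReferencePair) -> np.ndarray:
    """|cosine| of each mode with the open-to-locked difference vector.

    The difference vector is v2_aligned - v1 on the reference selection; its
    dimension must match the mode dimension (same node set).
    """
    diff = refs._x2 - refs._x1
    if diff.shape[0] != modes.eigenvectors.shape[0]:
        raise ValueError(
            f"mode dimension {modes.eigenvectors.shape[0]} does not match "
            f"the reference difference vector ({diff.shape[0]})"
        )
    d = diff / np.linalg.norm(diff)
    return np.abs(modes.eigenvectors.T @ d)
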