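"""Conformational analysis: the open/locked transition coordinate lambda,
distance-fluctuation matrices, least-squares superposition, and RMSD-cutoff
trajectory clustering.

The transition coordinate is a norm ratio between a sampled structure ``v``
and two reference structures ``v1`` (open, lambda = 0) and ``v2`` (locked,
lambda = 1)::

    lambda = |v - v1| / |v2 - v1|

computed over the flattened coordinate vector of a selection (C-alpha by
default).  Frames are superposed onto ``v1`` on that selection first, so
lambda is invariant under rigid motion of the input.  Values above 1 are
possible for structures off the v1-v2 axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.spatial.transform import Rotation

from .io_model import SelectionSpec, Structure, Trajectory

CALPHA = SelectionSpec("calpha")


# --------------------------------------------------------------------------
# Superposition
# --------------------------------------------------------------------------

def superpose(mobile: Structure, target: Structure,
              sel: SelectionSpec = CALPHA) -> tuple[Structure, float]:
    """Least-squares (Kabsch) superposition of ``mobile`` onto ``target``.

    The optimal proper rotation + translation is found on the selection and
    applied to all atoms of ``mobile``.  Returns the transformed structure and
    the minimized RMSD [A] over the selected atoms.
    """
    idx_m = sel.resolve(mobile)
    idx_t = sel.resolve(target)
    if idx_m.size != idx_t.size:
        raise ValueError("mobile and target selections differ in size")
    x = mobile.coords
    a = x[idx_m]
    b = target.coords[idx_t]
    if a.shape[0] < 3:
        raise ValueError("superposition needs at least 3 selected atoms")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    # rank check guards against collinear selections (rotation ill-defined)
    if np.linalg.matrix_rank(a0, tol=1e-8) < 2:
        raise ValueError("selected atoms are collinear; superposition undefined")
    rot, _ = Rotation.align_vectors(b0, a0)
    moved = rot.apply(x - ca) + cb
    rmsd = float(np.sqrt(np.mean(np.sum((rot.apply(a0) - b0) ** 2, axis=1))))
    return mobile.with_coords(moved), rmsd


def rmsd_after_superposition(a: Structure, b: Structure,
                             sel: SelectionSpec = CALPHA) -> float:
    return superpose(a, b, sel)[1]


# --------------------------------------------------------------------------
# The lambda coordinate
# --------------------------------------------------------------------------

@dataclass
class ReferencePair:
    """Open (v1, lambda=0) and locked (v2, lambda=1) reference structures.

    ``v1`` and ``v2`` are stored as given; the lambda axis is built from a
    copy of v2 superposed onto v1 over the selection (``v2_aligned``), so the
    axis is expressed in v1's frame.  Because :func:`compute_lambda` runs each
    frame through the same superposition, passing the raw locked structure
    returns exactly 1.  Aligning the references also makes the coordinate
    linear along the interpolation path: the Kabsch fit of v1 + t*(v2_aligned
    - v1) onto v1 is the identity for t in [0, 1].
    """

    v1: Structure
    v2: Structure
    selection: SelectionSpec = CALPHA

    def __post_init__(self):
        if self.v1.atom_identity() != self.v2.atom_identity():
            raise ValueError("reference structures must share the atom list")
        self.v2_aligned, _ = superpose(self.v2, self.v1, self.selection)
        idx = self.selection.resolve(self.v1)
        self._idx = idx
        self._x1 = self.v1.coords[idx].ravel()
        self._x2 = self.v2_aligned.coords[idx].ravel()
        self.axis_norm = float(np.linalg.norm(self._x2 - self._x1))
        if self.axis_norm <= 1e-10:
            raise ValueError("reference structures coincide on the selection; "
                             "lambda axis undefined")


@dataclass
class LambdaSeries:
    """Per-frame lambda values for a trajectory."""

    values: np.ndarray
    selection: SelectionSpec

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def std(self) -> float:
        return float(np.std(self.values))


def compute_lambda(frame: Structure, refs: ReferencePair,
                   projection: bool = False) -> float:
    """Transition coordinate of one frame.

    Default is the norm ratio |v - v1| / |v2 - v1| after superposing the
    frame onto v1.  With ``projection=True`` the signed component of (v - v1)
    along the v2 - v1 axis (normalized by the axis length) is returned
    instead — the inner-product variant some groups prefer.
    """
    fitted, _ = superpose(frame, refs.v1, refs.selection)
    v = fitted.coords[refs._idx].ravel()
    d = v - refs._x1
    if projection:
        axis = refs._x2 - refs._x1
        return float(np.dot(d, axis) / refs.axis_norm ** 2)
    return float(np.linalg.norm(d) / refs.axis_norm)


def lambda_series(traj: Trajectory, refs: ReferencePair,
                  projection: bool = False) -> LambdaSeries:
    """lambda for every frame, order preserved."""
    vals = np.array([compute_lambda(f, refs, projection) for f in traj.frames])
    return LambdaSeries(values=vals, selection=refs.selection)


# --------------------------------------------------------------------------
# Distance-fluctuation matrix
# --------------------------------------------------------------------------

@dataclass
class FluctuationMatrix:
    """Pairwise time-variance of internal distances, tau_ij [A^2].

    Distances are frame-internal, so tau is independent of any reference
    structure and of per-frame rigid motion; symmetric, zero diagonal.
    """

    tau: np.ndarray
    selection: SelectionSpec
    labels: list[str] = field(default_factory=list)


def distance_fluctuation(traj: Trajectory,
                         sel: SelectionSpec = CALPHA) -> FluctuationMatrix:
    """tau_ij = population variance over frames of the i-j distance."""
    if len(traj) < 2:
        raise ValueError("distance fluctuation needs at least 2 frames")
    idx = sel.resolve(traj.frames[0])
    if idx.size < 2:
        raise ValueError("distance fluctuation needs at least 2 selected atoms")
    dists = np.stack([pdist(f.coords[idx]) for f in traj.frames])
    tau = squareform(np.var(dists, axis=0, ddof=0))
    labels = [f"{a.chain}:{a.residue_id}:{a.name}"
              for a in (traj.frames[0].atoms[i] for i in idx)]
    return FluctuationMatrix(tau=tau, selection=sel, labels=labels)


# --------------------------------------------------------------------------
# GROMOS-style RMSD clustering
# --------------------------------------------------------------------------

@dataclass
class ClusterResult:
    labels: np.ndarray            # frame -> cluster id (0 = most populated)
    populations: np.ndarray       # cluster id -> fraction of frames
    centroids: np.ndarray         # cluster id -> frame index
    cutoff: float


def pairwise_rmsd_matrix(traj: Trajectory, sel: SelectionSpec = CALPHA) -> np.ndarray:
    n = len(traj)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = rmsd_after_superposition(
                traj.frames[i], traj.frames[j], sel)
    return m


def cluster_trajectory(traj: Trajectory, cutoff: float = 1.5,
                       sel: SelectionSpec = CALPHA) -> ClusterResult:
    """Neighbor-count clustering on the pairwise superposed-RMSD matrix.

    Repeatedly the unassigned frame with the most unassigned neighbors within
    ``cutoff`` becomes a cluster centroid and claims its neighbors; ties on
    the neighbor count go to the lowest frame index.  Clusters are numbered
    by descending population.  The cluster count is emergent — only the
    cutoff is a parameter.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = len(traj)
    rm = pairwise_rmsd_matrix(traj, sel)
    neighbor = rm <= cutoff
    np.fill_diagonal(neighbor, True)
    unassigned = np.ones(n, dtype=bool)
    labels = np.full(n, -1, dtype=int)
    centroids: list[int] = []
    members: list[np.ndarray] = []
    while unassigned.any():
        counts = (neighbor & unassigned).sum(axis=1)
        counts[~unassigned] = -1
        center = int(np.argmax(counts))       # argmax takes the lowest index on ties
        mine = np.flatnonzero(neighbor[center] & unassigned)
        centroids.append(center)
        members.append(mine)
        unassigned[mine] = False
    order = sorted(range(len(members)),
                   key=lambda k: (-len(members[k]), centroids[k]))
    pops = np.empty(len(order))
    cents = np.empty(len(order), dtype=int)
    for new_id, old_id in enumerate(order):
        labels[members[old_id]] = new_id
        pops[new_id] = len(members[old_id]) / n
        cents[new_id] = centroids[old_id]
    return ClusterResult(labels=labels, populations=pops,
                         centroids=cents, cutoff=float(cutoff))
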