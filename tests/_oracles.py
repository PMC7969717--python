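"""Independent brute-force oracles used by the test suite.

Each function re-derives a quantity by a route independent of the package
implementation it checks: explicit Python-loop pair sums, the Horn
quaternion closed form for superposition, and literal neighbor-count
clustering.
"""

import numpy as np


def brute_coulomb(positions, charges, eps, k_c=332.0636, pairs=None):
    """O(N^2) loop Coulomb sum over explicit pair list (or all unique pairs)."""
    n = len(charges)
    if pairs is None:
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    e = 0.0
    for i, j in pairs:
        r = np.sqrt(((positions[i] - positions[j]) ** 2).sum())
        e += k_c * charges[i] * charges[j] / (eps * r)
    return e


def brute_lj(positions, sigma, epsilon, pairs=None):
    n = len(sigma)
    if pairs is None:
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    e = 0.0
    for i, j in pairs:
        r = np.sqrt(((positions[i] - positions[j]) ** 2).sum())
        s = 0.5 * (sigma[i] + sigma[j])
        ee = np.sqrt(epsilon[i] * epsilon[j])
        e += 4.0 * ee * ((s / r) ** 12 - (s / r) ** 6)
    return e


def horn_rmsd(mobile, target):
    """Minimum RMSD over proper rotations+translations via Horn's quaternion
    eigenvalue method (closed form, no SVD)."""
    a = mobile - mobile.mean(axis=0)
    b = target - target.mean(axis=0)
    m = a.T @ b
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    n = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam_max = np.linalg.eigvalsh(n)[-1]
    sq = ((a ** 2).sum() + (b ** 2).sum() - 2.0 * lam_max) / len(a)
    return np.sqrt(max(sq, 0.0))


def brute_distance_variance(traj_coords, i, j):
    """Population variance of the i-j distance over frames, one pair."""
    d = [np.sqrt(((f[i] - f[j]) ** 2).sum()) for f in traj_coords]
    d = np.asarray(d)
    return float(np.mean((d - d.mean()) ** 2))


def brute_gromos_labels(rmsd_matrix, cutoff):
    """Literal neighbor-count clustering on a precomputed RMSD matrix,
    lowest-index tie-break, clusters renumbered by descending size."""
    n = rmsd_matrix.shape[0]
    unassigned = set(range(n))
    raw = {}
    order = []
    while unassigned:
        best, best_count = None, -1
        for c in sorted(unassigned):
            count = sum(1 for k in unassigned if rmsd_matrix[c, k] <= cutoff)
            if count > best_count:
                best, best_count = c, count
        members = [k for k in sorted(unassigned) if rmsd_matrix[best, k] <= cutoff]
        raw[best] = members
        order.append(best)
        unassigned -= set(members)
    order = sorted(order, key=lambda c: (-len(raw[c]), c))
    labels = np.empty(n, dtype=int)
    for new_id, c in enumerate(order):
        labels[raw[c]] = new_id
    return labels
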