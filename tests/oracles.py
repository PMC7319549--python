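"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is deliberately written from first principles (plain DP,
dense rotation sampling, exhaustive enumeration) and shares no code
with the package paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Align import substitution_matrices
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def smith_waterman_score(
    a: str, b: str, matrix: str, gap_open: float, gap_extend: float
) -> float:
    """Gotoh local-alignment score; a length-k gap costs open + k*extend."""
    M = substitution_matrices.load(matrix)
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - (gap_open + gap_extend), E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - (gap_open + gap_extend), F[i - 1][j] - gap_extend)
            s = float(M[a[i - 1], b[j - 1]])
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def _rmsd_for_rotation(R: np.ndarray, P: np.ndarray, Q: np.ndarray) -> float:
    # optimal translation for a fixed rotation aligns the centroids
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    diff = Pc @ R.T - Qc
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def brute_force_rmsd(
    moving: np.ndarray, fixed: np.ndarray, n_grid: int = 4000, seed: int = 0
) -> float:
    """Minimum RMSD over rigid motions via dense quaternion sampling
    followed by a local polish over the rotation-vector parameterisation."""
    P = np.asarray(moving, float)
    Q = np.asarray(fixed, float)
    grid = Rotation.random(n_grid, random_state=np.random.default_rng(seed))
    grid = Rotation.concatenate([grid, Rotation.identity()])
    best_rv, best = None, np.inf
    for rot in grid:
        v = _rmsd_for_rotation(rot.as_matrix(), P, Q)
        if v < best:
            best, best_rv = v, rot.as_rotvec()

    def objective(rv):
        return _rmsd_for_rotation(Rotation.from_rotvec(rv).as_matrix(), P, Q)

    res = minimize(objective, best_rv, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
    return float(min(best, res.fun))


def optimal_match_count(
    original: np.ndarray, placed: np.ndarray, cutoff: float
) -> int:
    """Maximum one-to-one matches under the cutoff, by exhaustive
    enumeration over assignments (feasible for ≤6 waters)."""
    orig = np.asarray(original, float).reshape(-1, 3)
    plac = np.asarray(placed, float).reshape(-1, 3)
    n, m = len(orig), len(plac)
    if n == 0 or m == 0:
        return 0
    d = np.linalg.norm(orig[:, None, :] - plac[None, :, :], axis=2)
    ok = d < cutoff
    best = 0
    k = min(n, m)
    for osub in itertools.combinations(range(n), k):
        for perm in itertools.permutations(range(m), k):
            count = sum(1 for oi, pi in zip(osub, perm) if ok[oi, pi])
            best = max(best, count)
    return best
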