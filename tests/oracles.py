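"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — O(N·M) loops, exhaustive pair scans,
numerical optimization — and shares no code path with the package
implementations it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def com(points: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    if weights is None:
        return np.asarray(points).mean(axis=0)
    w = np.asarray(weights, dtype=float)
    return (np.asarray(points) * w[:, None]).sum(axis=0) / w.sum()


def brute_rmsd(P: np.ndarray, Q: np.ndarray, n_starts: int = 12, seed: int = 0) -> float:
    """Minimum RMSD over rigid motions by multi-start numerical minimization
    over rotation vectors (translation handled by centroiding)."""
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)

    def cost(rv):
        R = Rotation.from_rotvec(rv).as_matrix()
        return np.sqrt(np.mean(np.sum((P @ R.T - Q) ** 2, axis=1)))

    rng = np.random.default_rng(seed)
    best = np.inf
    starts = [np.zeros(3)] + [rng.uniform(-np.pi, np.pi, 3) for _ in range(n_starts)]
    for x0 in starts:
        res = minimize(cost, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        best = min(best, res.fun)
    return float(best)


def waters_in_cylinder(
    o_positions: np.ndarray,
    origin: np.ndarray,
    z_axis: np.ndarray,
    z_lo: float,
    z_hi: float,
    radius: float,
) -> int:
    count = 0
    z_axis = z_axis / np.linalg.norm(z_axis)
    for p in o_positions:
        d = p - origin
        z = float(np.dot(d, z_axis))
        rho = np.linalg.norm(d - z * z_axis)
        if z_lo <= z < z_hi and rho <= radius:
            count += 1
    return count


def ring_proximity_count(
    water_atoms: list[tuple[tuple, np.ndarray]],
    ring_atoms: np.ndarray,
    cutoff: float,
) -> int:
    """water_atoms: list of ((chain, resseq), position) for every water atom."""
    hit = set()
    for key, pos in water_atoms:
        for q in ring_atoms:
            if np.linalg.norm(pos - q) < cutoff:
                hit.add(key)
                break
    return len(hit)


def exhaustive_pairs_below(A: np.ndarray, B: np.ndarray, cutoff: float):
    out = []
    for i, p in enumerate(A):
        for j, q in enumerate(B):
            if np.linalg.norm(p - q) < cutoff:
                out.append((i, j))
    return out


def bin_counts(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    counts = np.zeros(edges.size - 1)
    for v in values:
        for b in range(edges.size - 1):
            if edges[b] <= v < edges[b + 1]:
                counts[b] += 1
                break
    return counts


def numerical_forces(energy_fn, coords: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Central finite differences of a scalar energy over atomic coordinates;
    force = −dE/dr."""
    F = np.zeros_like(coords)
    for i in range(coords.shape[0]):
        for k in range(3):
            cp = coords.copy()
            cp[i, k] += h
            ep = energy_fn(cp)
            cm = coords.copy()
            cm[i, k] -= h
            em = energy_fn(cm)
            F[i, k] = -(ep - em) / (2 * h)
    return F
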