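"""Independent oracles used by the unit and acceptance suites.

These deliberately avoid the library's own implementations: the RMSD oracle
minimizes over an explicit rotation grid (plus local polish) instead of the
closed-form superposition, and the clustering oracle enumerates every
partition instead of running Lloyd iterations.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def rmsd_rotation_grid(c1: np.ndarray, c2: np.ndarray, coarse_deg: float = 20.0) -> float:
    """Min RMSD over rigid motions via dense Euler-angle search + refinement."""
    c1 = np.asarray(c1, float)
    c2 = np.asarray(c2, float)
    x = c1 - c1.mean(axis=0)
    y = c2 - c2.mean(axis=0)

    def cost(angles):
        rot = Rotation.from_euler("zyx", angles, degrees=True)
        diff = rot.apply(x) - y
        return np.sqrt((diff**2).sum() / len(x))

    grid = np.arange(0.0, 360.0, coarse_deg)
    half = np.arange(-90.0, 90.1, coarse_deg)
    best_angles, best = None, np.inf
    for a, b, c in itertools.product(grid, half, grid):
        val = cost((a, b, c))
        if val < best:
            best, best_angles = val, (a, b, c)
    res = minimize(cost, best_angles, method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-12})
    return float(min(best, res.fun))


def _partitions_into_k(indices: list[int], k: int):
    """All unordered partitions of ``indices`` into exactly k non-empty blocks."""
    if k == 1:
        yield [indices]
        return
    if len(indices) == k:
        yield [[i] for i in indices]
        return
    first, rest = indices[0], indices[1:]
    # first element joins an existing block of a (k)-partition of the rest
    for part in _partitions_into_k(rest, k):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
    # or forms its own block alongside a (k-1)-partition of the rest
    for part in _partitions_into_k(rest, k - 1):
        yield [[first]] + part


def exhaustive_medoids(points: np.ndarray, k: int) -> list[int]:
    """Globally optimal k-clustering by enumeration; returns sorted medoid indices.

    Objective: total within-cluster sum of squared distances to the cluster
    mean. The medoid of each block is the member closest to the block mean
    (ties to the lowest index). Feasible for n <= 12.
    """
    points = np.asarray(points, float)
    if points.ndim == 1:
        points = points.reshape(-1, 1)
    n = len(points)
    best_cost, best_part = np.inf, None
    for part in _partitions_into_k(list(range(n)), k):
        cost = 0.0
        for block in part:
            blk = points[block]
            cost += ((blk - blk.mean(axis=0)) ** 2).sum()
        if cost < best_cost - 1e-12:
            best_cost, best_part = cost, part
    medoids = []
    for block in best_part:
        blk = points[block]
        dists = np.linalg.norm(blk - blk.mean(axis=0), axis=1)
        medoids.append(block[int(np.argmin(dists))])
    return sorted(medoids)


def charge_prune_oracle(charges: list[int]) -> list[int]:
    """Brute-force ionization-charge pruning: keep q with |q - q0| <= 2,
    q0 the charge closest to zero (more negative on ties)."""
    baseline = min(charges, key=lambda q: (abs(q), q))
    return [q for q in charges if abs(q - baseline) <= 2]


def even_chunks_oracle(n_inputs: int, n_workers: int) -> list[int]:
    """Distribute items one at a time, round-robin; sizes by brute force."""
    sizes = [0] * n_workers
    for i in range(n_inputs):
        sizes[i % n_workers] += 1
    return sorted(sizes, reverse=True)
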