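"""Independent reference implementations used only to cross-check the
package; deliberately written with different algorithms than the
implementation under test."""

from __future__ import annotations

import numpy as np


def horn_quaternion_rmsd(reference: np.ndarray, mobile: np.ndarray) -> float:
    """Optimal superposition RMSD via Horn's closed-form quaternion
    method (largest eigenvalue of the 4x4 key matrix)."""
    a = np.asarray(reference, float)
    b = np.asarray(mobile, float)
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    m = bc.T @ ac  # correlation matrix
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(k)[-1]
    n = len(a)
    msd = (np.sum(ac**2) + np.sum(bc**2) - 2.0 * lam) / n
    return float(np.sqrt(max(msd, 0.0)))


def brute_force_gromos(dist: np.ndarray, cutoff: float) -> list[tuple[tuple[int, ...], int]]:
    """Greedy neighbor-counting clustering from a precomputed distance
    matrix, written as plain nested loops."""
    n = dist.shape[0]
    remaining = set(range(n))
    clusters = []
    while remaining:
        best_center = None
        best_count = -1
        for i in sorted(remaining):
            count = 0
            for j in sorted(remaining):
                if dist[i, j] <= cutoff:
                    count += 1
            if count > best_count:
                best_count = count
                best_center = i
        members = tuple(
            j for j in sorted(remaining) if dist[best_center, j] <= cutoff
        )
        clusters.append((members, best_center))
        remaining -= set(members)
    clusters.sort(key=lambda c: (-len(c[0]), c[1]))
    return clusters


def lca_by_path_intersection(parent: dict, taxa: list[str]) -> str:
    """LCA as the deepest node on every root path."""

    def root_path(node):
        path = []
        while node is not None:
            path.append(node)
            node = parent[node]
        return list(reversed(path))  # root first

    paths = [root_path(t) for t in taxa]
    common = None
    for depth in range(min(len(p) for p in paths)):
        level = {p[depth] for p in paths}
        if len(level) == 1:
            common = level.pop()
        else:
            break
    assert common is not None
    return common


def pairwise_fitted_rmsd_matrix(coords: list[np.ndarray]) -> np.ndarray:
    n = len(coords)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = horn_quaternion_rmsd(coords[i], coords[j])
    return dist
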