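"""Independent brute-force oracles used by unit and acceptance tests.

Each oracle re-derives a quantity by direct enumeration, sharing no code
with the implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_box_count(arr: np.ndarray, eps: int) -> int:
    """Scan every ε-sided box of the origin-anchored grid and count occupied
    ones (partial far-edge boxes included)."""
    arr = np.asarray(arr, dtype=bool)
    count = 0
    ranges = [range(0, s, eps) for s in arr.shape]
    for corner in itertools.product(*ranges):
        sl = tuple(slice(c, c + eps) for c in corner)
        if arr[sl].any():
            count += 1
    return count


def _neighbor_offsets(connectivity: int) -> list[tuple[int, int, int]]:
    offs = []
    for d in itertools.product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        order = sum(abs(x) for x in d)
        if (connectivity == 6 and order == 1) or \
           (connectivity == 18 and order <= 2) or connectivity == 26:
            offs.append(d)
    return offs


def flood_fill_components(vol: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Label connected components by breadth-first flood fill."""
    vol = np.asarray(vol, dtype=bool)
    offsets = _neighbor_offsets(connectivity)
    labels = np.zeros(vol.shape, dtype=np.int32)
    current = 0
    for start in zip(*np.nonzero(vol)):
        if labels[start]:
            continue
        current += 1
        stack = [start]
        labels[start] = current
        while stack:
            z, y, x = stack.pop()
            for dz, dy, dx in offsets:
                nz, ny, nx = z + dz, y + dy, x + dx
                if 0 <= nz < vol.shape[0] and 0 <= ny < vol.shape[1] \
                        and 0 <= nx < vol.shape[2] and vol[nz, ny, nx] \
                        and not labels[nz, ny, nx]:
                    labels[nz, ny, nx] = current
                    stack.append((nz, ny, nx))
    return labels


def same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    """Do two labelings induce the same partition of the foreground?"""
    fa, fb = a > 0, b > 0
    if not np.array_equal(fa, fb):
        return False
    pairs = {(int(x), int(y)) for x, y in zip(a[fa], b[fb])}
    return len({p[0] for p in pairs}) == len(pairs) == len({p[1] for p in pairs})


def brute_force_min_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """O(n⁴) minimal enclosing sphere by support-set enumeration.

    Every support set of 2, 3 or 4 points yields one candidate sphere (its
    circumsphere); the answer is the smallest candidate containing all
    points. Candidates are generated batched and verified in ascending
    radius order, so the first valid one is the minimum.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n == 1:
        return pts[0], 0.0
    tol = 1e-9
    centers_all, radii_all = [], []

    # pairs: diameter spheres
    ii, jj = np.triu_indices(n, k=1)
    centers_all.append(0.5 * (pts[ii] + pts[jj]))
    radii_all.append(0.5 * np.linalg.norm(pts[ii] - pts[jj], axis=1))

    for k in (3, 4):
        if n < k:
            continue
        combos = np.array(list(itertools.combinations(range(n), k)))
        a = pts[combos[:, 0]]                      # (m, 3)
        rows = pts[combos[:, 1:]] - a[:, None, :]  # (m, k-1, 3)
        gram = rows @ rows.transpose(0, 2, 1)
        rhs = 0.5 * np.sum(rows * rows, axis=2)
        dets = np.linalg.det(gram)
        good = np.abs(dets) > 1e-12
        if not good.any():
            continue
        sol = np.linalg.solve(gram[good], rhs[good][..., None])[..., 0]
        centers = a[good] + np.einsum("mi,mij->mj", sol, rows[good])
        centers_all.append(centers)
        radii_all.append(np.linalg.norm(centers - a[good], axis=1))

    centers = np.concatenate(centers_all)
    radii = np.concatenate(radii_all)
    order = np.argsort(radii)
    for chunk in np.array_split(order, max(1, len(order) // 4096)):
        d = np.linalg.norm(pts[None, :, :] - centers[chunk][:, None, :], axis=2)
        valid = np.max(d, axis=1) <= radii[chunk] + tol
        if valid.any():
            k = chunk[np.argmax(valid)]
            return centers[k], float(radii[k])
    raise RuntimeError("no valid candidate sphere (degenerate input)")
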