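"""Brute-force reference implementations used to cross-check the catalog.

These are deliberately naive (explicit loops, BFS, exhaustive search) and
share no code with the package.
"""

from collections import deque

import numpy as np


def exhaustive_otsu(values: np.ndarray) -> float:
    """Smallest threshold minimizing the weighted intra-class variance,
    among the distinct values (foreground strictly above)."""
    flat = values.ravel().astype(np.float64)
    candidates = np.unique(flat)[:-1]
    best_t, best_v = None, np.inf
    for t in candidates:
        lo = flat[flat <= t]
        hi = flat[flat > t]
        v = lo.size * lo.var() + hi.size * hi.var()
        if v < best_v - 1e-9:
            best_v, best_t = v, t
    return float(best_t)


def neighbors26(shape, voxel):
    z, y, x = voxel
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dz == dy == dx == 0:
                    continue
                nz, ny, nx = z + dz, y + dy, x + dx
                if 0 <= nz < shape[0] and 0 <= ny < shape[1] and 0 <= nx < shape[2]:
                    yield nz, ny, nx


def flood_fill_components(mask: np.ndarray) -> np.ndarray:
    """26-connected component labels by BFS, ids in raster order of discovery."""
    labels = np.zeros(mask.shape, dtype=np.int32)
    next_id = 0
    for voxel in zip(*np.nonzero(mask)):
        if labels[voxel]:
            continue
        next_id += 1
        queue = deque([voxel])
        labels[voxel] = next_id
        while queue:
            v = queue.popleft()
            for n in neighbors26(mask.shape, v):
                if mask[n] and not labels[n]:
                    labels[n] = next_id
                    queue.append(n)
    return labels


def reachable_hysteresis(values: np.ndarray, low: float, high: float) -> np.ndarray:
    """Voxels > low that reach a voxel > high through the > low graph (26-conn)."""
    weak = values > low
    out = np.zeros(values.shape, dtype=bool)
    queue = deque(zip(*np.nonzero(values > high)))
    for v in queue:
        out[v] = True
    while queue:
        v = queue.popleft()
        for n in neighbors26(values.shape, v):
            if weak[n] and not out[n]:
                out[n] = True
                queue.append(n)
    return out


def brute_median_filter(values: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Median over the footprint neighborhood with nearest-edge replication."""
    rz, ry, rx = (s // 2 for s in footprint.shape)
    out = np.empty_like(values)
    nz, ny, nx = values.shape
    offsets = [
        (dz - rz, dy - ry, dx - rx)
        for dz, dy, dx in zip(*np.nonzero(footprint))
    ]
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                neighborhood = [
                    values[
                        min(max(z + dz, 0), nz - 1),
                        min(max(y + dy, 0), ny - 1),
                        min(max(x + dx, 0), nx - 1),
                    ]
                    for dz, dy, dx in offsets
                ]
                out[z, y, x] = np.median(neighborhood)
    return out


def percentile_threshold(values: np.ndarray, pct: float) -> float:
    """Smallest distinct value leaving at most pct% of voxels strictly above."""
    flat = np.sort(values.ravel())
    budget = int(np.floor(flat.size * pct / 100.0))
    for t in np.unique(flat):
        if (flat > t).sum() <= budget:
            return float(t)
    return float(flat[-1])


def count_faces(labels: np.ndarray, label: int, sx: float, sy: float, sz: float) -> float:
    """Surface area of one label by direct enumeration of its exposed faces."""
    area = 0.0
    nz, ny, nx = labels.shape
    face = {(1, 0, 0): sx * sy, (0, 1, 0): sx * sz, (0, 0, 1): sy * sz}
    for z, y, x in zip(*np.nonzero(labels == label)):
        for (dz, dy, dx), a in face.items():
            for sign in (-1, 1):
                nzc, nyc, nxc = z + sign * dz, y + sign * dy, x + sign * dx
                if not (0 <= nzc < nz and 0 <= nyc < ny and 0 <= nxc < nx):
                    area += a
                elif labels[nzc, nyc, nxc] != label:
                    area += a
    return area
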