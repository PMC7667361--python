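"""Independent reference implementations used only for cross-checking.

Everything here is deliberately written the slow, obvious way (explicit
double loops, direct textbook formulas) and stays independent of the
package's optimized code paths.
"""
from __future__ import annotations

import numpy as np


def fcd_counts_bruteforce(data, mask, affine, r0, cutoff_mm):
    """Exhaustive pairwise short/long-range edge counts.

    ``data`` is (x, y, z, t). Returns (k_short, k_long) 3D integer maps.
    """
    idx = np.argwhere(mask)
    n = idx.shape[0]
    coords = (idx @ np.asarray(affine)[:3, :3].T) + np.asarray(affine)[:3, 3]
    series = np.array([data[tuple(v)] for v in idx], dtype=float)
    k_short = np.zeros(mask.shape, dtype=np.int64)
    k_long = np.zeros(mask.shape, dtype=np.int64)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            xi, xj = series[i], series[j]
            xi = xi - xi.mean()
            xj = xj - xj.mean()
            denom = np.sqrt((xi**2).sum() * (xj**2).sum())
            if denom == 0:
                continue
            r = float((xi * xj).sum() / denom)
            if r > r0:
                d = float(np.linalg.norm(coords[i] - coords[j]))
                if d <= cutoff_mm:
                    k_short[tuple(idx[i])] += 1
                else:
                    k_long[tuple(idx[i])] += 1
    return k_short, k_long


def max_cluster_bruteforce(binary, voxel_size, rmm):
    """Maximum connected-component size by breadth-first flood fill.

    Neighbourhood: voxel centers within ``rmm`` mm on an isotropic grid.
    """
    offsets = []
    reach = int(rmm // voxel_size) + 1
    for dx in range(-reach, reach + 1):
        for dy in range(-reach, reach + 1):
            for dz in range(-reach, reach + 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                if voxel_size * np.sqrt(dx**2 + dy**2 + dz**2) <= rmm:
                    offsets.append((dx, dy, dz))
    seen = np.zeros(binary.shape, dtype=bool)
    best = 0
    for start in map(tuple, np.argwhere(binary)):
        if seen[start]:
            continue
        size = 0
        queue = [start]
        seen[start] = True
        while queue:
            v = queue.pop()
            size += 1
            for off in offsets:
                w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
                if all(0 <= w[a] < binary.shape[a] for a in range(3)):
                    if binary[w] and not seen[w]:
                        seen[w] = True
                        queue.append(w)
        best = max(best, size)
    return best


def alphasim_null_bruteforce(mask, voxel_size, voxel_p, rmm, iterations, rng):
    """Null max-cluster-size distribution for unsmoothed noise.

    Independent of the package implementation: thresholds iid Gaussian
    noise two-tailed at ``voxel_p``, labels positive and negative
    excursions separately by flood fill, records the pooled maximum.
    """
    from scipy.stats import norm

    zcrit = norm.isf(voxel_p / 2.0)
    out = np.empty(iterations, dtype=np.int64)
    for it in range(iterations):
        noise = rng.standard_normal(mask.shape)
        vals = noise[mask]
        noise = np.where(mask, (noise - vals.mean()) / vals.std(), 0.0)
        pos = mask & (noise > zcrit)
        neg = mask & (noise < -zcrit)
        out[it] = max(
            max_cluster_bruteforce(pos, voxel_size, rmm),
            max_cluster_bruteforce(neg, voxel_size, rmm),
        )
    return out


def cohen_d_textbook(x1, x2):
    """Cohen's d straight from the defining formulas."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n1, n2 = len(x1), len(x2)
    m1 = sum(x1) / n1
    m2 = sum(x2) / n2
    s1 = sum((v - m1) ** 2 for v in x1) / (n1 - 1)
    s2 = sum((v - m2) ** 2 for v in x2) / (n2 - 1)
    s_pooled = np.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2))
    return (m1 - m2) / s_pooled


def pearson_loop(x, y):
    """Pearson correlation by explicit summation."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = np.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def bh_stepup(pvalues):
    """BH step-up adjusted p-values computed by the defining recursion."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, m * p[i] / rank)
        q[i] = min(val, 1.0)
        prev = q[i]
    return q
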