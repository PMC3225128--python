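"""Independent brute-force oracles used by the test suite.

Everything here is written naively (explicit loops, BFS, exhaustive scans)
and on purpose shares no code with the package implementation.
"""

import math
from collections import deque

import numpy as np


def offsets_3d(connectivity):
    out = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dz == dy == dx == 0:
                    continue
                order = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                out.append((dz, dy, dx))
    return out


def offsets_2d(connectivity):
    out = []
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy == dx == 0:
                continue
            if connectivity == 4 and abs(dy) + abs(dx) > 1:
                continue
            out.append((dy, dx))
    return out


def naive_median_2d(voxels, radius):
    """Sliding-window median per slice with edge replication, O(w^2) per pixel."""
    voxels = np.asarray(voxels)
    Z, H, W = voxels.shape
    out = np.empty_like(voxels)
    for z in range(Z):
        for y in range(H):
            for x in range(W):
                window = []
                for dy in range(-radius, radius + 1):
                    for dx in range(-radius, radius + 1):
                        yy = min(max(y + dy, 0), H - 1)
                        xx = min(max(x + dx, 0), W - 1)
                        window.append(voxels[z, yy, xx])
                window.sort()
                out[z, y, x] = window[len(window) // 2]
    return out


def bfs_region_grow_3d(voxels, seed_zyx, theta_min, theta_max, connectivity):
    """Flood fill from the seed over in-range voxels."""
    voxels = np.asarray(voxels)
    Z, H, W = voxels.shape
    offs = offsets_3d(connectivity)
    result = np.zeros(voxels.shape, dtype=bool)
    z0, y0, x0 = seed_zyx
    if not (theta_min <= voxels[z0, y0, x0] <= theta_max):
        return result
    queue = deque([(z0, y0, x0)])
    result[z0, y0, x0] = True
    while queue:
        z, y, x = queue.popleft()
        for dz, dy, dx in offs:
            zz, yy, xx = z + dz, y + dy, x + dx
            if 0 <= zz < Z and 0 <= yy < H and 0 <= xx < W and not result[zz, yy, xx]:
                if theta_min <= voxels[zz, yy, xx] <= theta_max:
                    result[zz, yy, xx] = True
                    queue.append((zz, yy, xx))
    return result


def bfs_label_3d(mask, connectivity):
    """Connected components by BFS, labels in raster order of first voxel."""
    mask = np.asarray(mask).astype(bool)
    Z, H, W = mask.shape
    offs = offsets_3d(connectivity)
    labels = np.zeros(mask.shape, dtype=np.int64)
    current = 0
    for z in range(Z):
        for y in range(H):
            for x in range(W):
                if mask[z, y, x] and labels[z, y, x] == 0:
                    current += 1
                    queue = deque([(z, y, x)])
                    labels[z, y, x] = current
                    while queue:
                        cz, cy, cx = queue.popleft()
                        for dz, dy, dx in offs:
                            zz, yy, xx = cz + dz, cy + dy, cx + dx
                            if (
                                0 <= zz < Z
                                and 0 <= yy < H
                                and 0 <= xx < W
                                and mask[zz, yy, xx]
                                and labels[zz, yy, xx] == 0
                            ):
                                labels[zz, yy, xx] = current
                                queue.append((zz, yy, xx))
    return labels


def bfs_label_2d(mask, connectivity):
    mask = np.asarray(mask).astype(bool)
    return bfs_label_3d(mask[np.newaxis], {4: 6, 8: 26}[connectivity])[0]


def fill_holes_2d(component):
    """Holes = background not 4-reachable from the image border."""
    component = np.asarray(component).astype(bool)
    H, W = component.shape
    outside = np.zeros_like(component)
    queue = deque()
    for y in range(H):
        for x in range(W):
            if (y in (0, H - 1) or x in (0, W - 1)) and not component[y, x]:
                outside[y, x] = True
                queue.append((y, x))
    while queue:
        y, x = queue.popleft()
        for dy, dx in offsets_2d(4):
            yy, xx = y + dy, x + dx
            if 0 <= yy < H and 0 <= xx < W and not component[yy, xx] and not outside[yy, xx]:
                outside[yy, xx] = True
                queue.append((yy, xx))
    return component | ~outside


def wand_oracle(slice_image, start_x, start_y, theta_min, theta_max):
    """Rightward hit, 8-connected in-range component, holes filled."""
    slice_image = np.asarray(slice_image)
    H, W = slice_image.shape
    hit_x = None
    for x in range(start_x, W):
        if theta_min <= slice_image[start_y, x] <= theta_max:
            hit_x = x
            break
    if hit_x is None:
        return None
    in_range = (slice_image >= theta_min) & (slice_image <= theta_max)
    labels = bfs_label_2d(in_range, 8)
    component = labels == labels[start_y, hit_x]
    return fill_holes_2d(component)


def naive_confusion(gt_fg, ms_fg):
    """Exhaustive per-voxel tally."""
    tp = fp = tn = fn = 0
    for g, m in zip(np.asarray(gt_fg).ravel(), np.asarray(ms_fg).ravel()):
        if g and m:
            tp += 1
        elif m:
            fp += 1
        elif g:
            fn += 1
        else:
            tn += 1
    return tp, fp, tn, fn


def overlap_edges_bruteforce(gt, ms):
    """All (gt_label, ms_label) pairs sharing >= 1 voxel, by explicit loop."""
    gt = np.asarray(gt).ravel()
    ms = np.asarray(ms).ravel()
    pairs = set()
    for g, m in zip(gt, ms):
        if g > 0 and m > 0:
            pairs.add((int(g), int(m)))
    return pairs


# ---------------------------------------------------------------------------
# threshold criteria, exhaustive scans
# ---------------------------------------------------------------------------

def _class_stats(counts, t):
    n_b = s_b = n_f = s_f = 0.0
    for i, c in enumerate(counts):
        if c == 0:
            continue
        if i <= t:
            n_b += c
            s_b += i * c
        else:
            n_f += c
            s_f += i * c
    return n_b, s_b, n_f, s_f


def otsu_scan(counts):
    """Smallest t maximising w0*w1*(mu0-mu1)^2."""
    counts = list(counts)
    total = sum(counts)
    best_t, best = None, -1.0
    for t in range(len(counts)):
        n_b, s_b, n_f, s_f = _class_stats(counts, t)
        if n_b == 0 or n_f == 0:
            continue
        w0, w1 = n_b / total, n_f / total
        crit = w0 * w1 * (s_b / n_b - s_f / n_f) ** 2
        if crit > best:
            best, best_t = crit, t
    return best_t


def yen_scan(counts):
    counts = list(counts)
    total = sum(counts)
    p = [c / total for c in counts]
    best_t, best = None, -math.inf
    for t in range(len(counts)):
        p1 = sum(p[: t + 1])
        if not (0 < p1 < 1):
            continue
        p1sq = sum(v * v for v in p[: t + 1])
        p2sq = sum(v * v for v in p[t + 1 :])
        term1 = -math.log(p1sq * p2sq) if p1sq * p2sq > 0 else 0.0
        term2 = 2 * math.log(p1 * (1 - p1))
        crit = term1 + term2
        if crit > best:
            best, best_t = crit, t
    return best_t


def huang_scan(counts):
    """Smallest t minimising Huang-Wang fuzziness."""
    counts = list(counts)
    nz = [i for i, c in enumerate(counts) if c > 0]
    first, last = nz[0], nz[-1]
    c_range = last - first
    best_t, best = None, math.inf
    for t in range(first, last):
        n_b, s_b, n_f, s_f = _class_stats(counts, t)
        if n_b == 0 or n_f == 0:
            continue
        mu_b, mu_f = s_b / n_b, s_f / n_f
        ent = 0.0
        for i, c in enumerate(counts):
            if c == 0:
                continue
            mu = mu_b if i <= t else mu_f
            u = 1.0 / (1.0 + abs(i - mu) / c_range)
            if 1e-6 < u < 1 - 1e-6:
                ent += c * (-u * math.log(u) - (1 - u) * math.log(1 - u))
        if ent < best:
            best, best_t = ent, t
    return best_t


def renyi_scan(counts, rho):
    """Smallest t maximising the two-class Renyi entropy sum of order rho."""
    counts = list(counts)
    total = sum(counts)
    p = [c / total for c in counts]
    best_t, best = None, -math.inf
    for t in range(len(counts)):
        p1 = sum(p[: t + 1])
        if not (0 < p1 < 1):
            continue
        back = [v / p1 for v in p[: t + 1] if v > 0]
        fore = [v / (1 - p1) for v in p[t + 1 :] if v > 0]
        if rho == 1.0:
            h_b = -sum(v * math.log(v) for v in back)
            h_f = -sum(v * math.log(v) for v in fore)
        else:
            h_b = math.log(sum(v**rho for v in back)) / (1 - rho)
            h_f = math.log(sum(v**rho for v in fore)) / (1 - rho)
        crit = h_b + h_f
        if crit > best and math.isfinite(crit):
            best, best_t = crit, t
    return best_t
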