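"""Independent brute-force oracles for cross-checking the implementation.

Everything here is written as plain nested loops over definitions, entirely
separate from the vectorized code paths in the package, so agreement is
evidence of correctness rather than repetition.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np

DIRECTIONS_13 = [
    (0, 0, 1), (0, 1, 0), (1, 0, 0), (0, 1, 1), (0, 1, -1), (1, 0, 1),
    (1, 0, -1), (1, 1, 0), (1, -1, 0), (1, 1, 1), (1, 1, -1), (1, -1, 1),
    (1, -1, -1),
]


# -- first-order --------------------------------------------------------------

def first_order_oracle(values, levels):
    values = [float(v) for v in values]
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / n
    sd = math.sqrt(var)
    if sd > 0:
        skew = sum((v - mean) ** 3 for v in values) / n / sd**3
        kurt = sum((v - mean) ** 4 for v in values) / n / sd**4
    else:
        skew = kurt = 0.0
    counts = {}
    for lv in levels:
        counts[lv] = counts.get(lv, 0) + 1
    probs = [c / n for c in counts.values()]
    entropy = -sum(p * math.log2(p) for p in probs if p > 0)
    uniformity = sum(p * p for p in probs)
    svals = sorted(values)
    if n % 2:
        median = svals[n // 2]
    else:
        median = 0.5 * (svals[n // 2 - 1] + svals[n // 2])
    return {
        "energy": sum(v * v for v in values),
        "entropy": entropy,
        "kurtosis": kurt,
        "maximum": max(values),
        "mean": mean,
        "mean_absolute_deviation": sum(abs(v - mean) for v in values) / n,
        "median": median,
        "minimum": min(values),
        "range": max(values) - min(values),
        "root_mean_square": math.sqrt(sum(v * v for v in values) / n),
        "skewness": skew,
        "standard_deviation": sd,
        "uniformity": uniformity,
        "variance": var,
    }


# -- shape --------------------------------------------------------------------

def shape_oracle(mask, spacing):
    mask = np.asarray(mask, dtype=bool)
    sz, sy, sx = spacing
    vox = sz * sy * sx
    n = int(mask.sum())
    volume = n * vox
    face_area = {0: sy * sx, 1: sz * sx, 2: sz * sy}
    surface = 0.0
    nz, ny, nx = mask.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x]:
                    continue
                for axis, (dz, dy, dx) in enumerate(
                    [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
                ):
                    for sgn in (-1, 1):
                        zz, yy, xx = z + sgn * dz, y + sgn * dy, x + sgn * dx
                        outside = not (
                            0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx
                        ) or not mask[zz, yy, xx]
                        if outside:
                            surface += face_area[axis]
    coords = [
        (z * sz, y * sy, x * sx)
        for z in range(nz)
        for y in range(ny)
        for x in range(nx)
        if mask[z, y, x]
    ]
    diameter = 0.0
    for i in range(len(coords)):
        for j in range(i + 1, len(coords)):
            d = math.dist(coords[i], coords[j])
            diameter = max(diameter, d)
    r = (3 * volume / (4 * math.pi)) ** (1 / 3)
    return {
        "volume": volume,
        "surface_area": surface,
        "surface_to_volume_ratio": surface / volume,
        "sphericity": math.pi ** (1 / 3) * (6 * volume) ** (2 / 3) / surface,
        "spherical_disproportion": surface / (4 * math.pi * r**2),
        "compactness1": volume / (math.sqrt(math.pi) * surface ** 1.5),
        "compactness2": 36 * math.pi * volume**2 / surface**3,
        "maximum_3d_diameter": diameter,
    }


# -- GLCM ---------------------------------------------------------------------

def glcm_matrix_oracle(levels, mask, offset, n_levels):
    """Symmetrized, normalized co-occurrence counts by pair enumeration."""
    nz, ny, nx = levels.shape
    p = np.zeros((n_levels, n_levels))
    dz, dy, dx = offset
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                zz, yy, xx = z + dz, y + dy, x + dx
                if not (0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx):
                    continue
                if mask[z, y, x] and mask[zz, yy, xx]:
                    a, b = levels[z, y, x] - 1, levels[zz, yy, xx] - 1
                    p[a, b] += 1
                    p[b, a] += 1
    total = p.sum()
    return p / total if total > 0 else p


def glcm_features_oracle(p):
    """All 23 co-occurrence features by direct summation loops."""
    ng = p.shape[0]
    px = [sum(p[i, j] for j in range(ng)) for i in range(ng)]
    mu = sum((i + 1) * px[i] for i in range(ng))
    sigma = math.sqrt(sum((i + 1 - mu) ** 2 * px[i] for i in range(ng)))
    p_sum = {}
    p_diff = {}
    for i in range(ng):
        for j in range(ng):
            p_sum[i + j + 2] = p_sum.get(i + j + 2, 0.0) + p[i, j]
            p_diff[abs(i - j)] = p_diff.get(abs(i - j), 0.0) + p[i, j]

    def xlog2(v):
        return v * math.log2(v) if v > 0 else 0.0

    hxy = -sum(xlog2(p[i, j]) for i in range(ng) for j in range(ng))
    hx = -sum(xlog2(v) for v in px)
    hxy1 = -sum(
        p[i, j] * math.log2(px[i] * px[j])
        for i in range(ng)
        for j in range(ng)
        if p[i, j] > 0 and px[i] * px[j] > 0
    )
    hxy2 = -sum(xlog2(px[i] * px[j]) for i in range(ng) for j in range(ng))
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = math.sqrt(max(1 - math.exp(-2 * (hxy2 - hxy)), 0.0))
    corr = (
        (sum((i + 1) * (j + 1) * p[i, j] for i in range(ng) for j in range(ng)) - mu * mu)
        / (sigma * sigma)
        if sigma > 0
        else 0.0
    )
    sum_avg = sum(k * v for k, v in p_sum.items())
    diff_avg = sum(k * v for k, v in p_diff.items())
    out = {
        "autocorrelation": sum((i + 1) * (j + 1) * p[i, j] for i in range(ng) for j in range(ng)),
        "cluster_prominence": sum((i + j + 2 - 2 * mu) ** 4 * p[i, j] for i in range(ng) for j in range(ng)),
        "cluster_shade": sum((i + j + 2 - 2 * mu) ** 3 * p[i, j] for i in range(ng) for j in range(ng)),
        "cluster_tendency": sum((i + j + 2 - 2 * mu) ** 2 * p[i, j] for i in range(ng) for j in range(ng)),
        "contrast": sum((i - j) ** 2 * p[i, j] for i in range(ng) for j in range(ng)),
        "correlation": corr,
        "difference_entropy": -sum(xlog2(v) for v in p_diff.values()),
        "difference_variance": sum((k - diff_avg) ** 2 * v for k, v in p_diff.items()),
        "dissimilarity": sum(abs(i - j) * p[i, j] for i in range(ng) for j in range(ng)),
        "energy": sum(p[i, j] ** 2 for i in range(ng) for j in range(ng)),
        "entropy": hxy,
        "homogeneity1": sum(p[i, j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng)),
        "homogeneity2": sum(p[i, j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng)),
        "imc1": imc1,
        "imc2": imc2,
        "idmn": sum(p[i, j] / (1 + ((i - j) / ng) ** 2) for i in range(ng) for j in range(ng)),
        "idn": sum(p[i, j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng)),
        "inverse_variance": sum(
            p[i, j] / (i - j) ** 2 for i in range(ng) for j in range(ng) if i != j
        ),
        "maximum_probability": max(p[i, j] for i in range(ng) for j in range(ng)),
        "sum_average": sum_avg,
        "sum_entropy": -sum(xlog2(v) for v in p_sum.values()),
        "sum_variance": sum((k - sum_avg) ** 2 * v for k, v in p_sum.items()),
        "sum_of_squares_variance": sum(
            (i + 1 - mu) ** 2 * p[i, j] for i in range(ng) for j in range(ng)
        ),
    }
    return out


# -- run lengths --------------------------------------------------------------

def runs_oracle(levels, mask, offset):
    """All maximal runs (level, length) along one direction, by line walking."""
    nz, ny, nx = levels.shape
    dz, dy, dx = offset
    runs = []
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                # start of a run: predecessor absent/invalid/different
                pz, py, px_ = z - dz, y - dy, x - dx
                if not mask[z, y, x]:
                    continue
                prev_same = (
                    0 <= pz < nz
                    and 0 <= py < ny
                    and 0 <= px_ < nx
                    and mask[pz, py, px_]
                    and levels[pz, py, px_] == levels[z, y, x]
                )
                if prev_same:
                    continue
                length = 1
                zz, yy, xx = z + dz, y + dy, x + dx
                while (
                    0 <= zz < nz
                    and 0 <= yy < ny
                    and 0 <= xx < nx
                    and mask[zz, yy, xx]
                    and levels[zz, yy, xx] == levels[z, y, x]
                ):
                    length += 1
                    zz, yy, xx = zz + dz, yy + dy, xx + dx
                runs.append((int(levels[z, y, x]), length))
    return runs


def rlgl_features_oracle(runs, n_voxels):
    nr = len(runs)
    feats = {
        "short_run_emphasis": sum(1 / l**2 for _, l in runs) / nr,
        "long_run_emphasis": sum(l**2 for _, l in runs) / nr,
        "run_percentage": nr / n_voxels,
        "low_gray_level_run_emphasis": sum(1 / g**2 for g, _ in runs) / nr,
        "high_gray_level_run_emphasis": sum(g**2 for g, _ in runs) / nr,
        "short_run_low_gray_level_emphasis": sum(1 / (g**2 * l**2) for g, l in runs) / nr,
        "short_run_high_gray_level_emphasis": sum(g**2 / l**2 for g, l in runs) / nr,
        "long_run_low_gray_level_emphasis": sum(l**2 / g**2 for g, l in runs) / nr,
        "long_run_high_gray_level_emphasis": sum(g**2 * l**2 for g, l in runs) / nr,
    }
    by_g = {}
    by_l = {}
    for g, l in runs:
        by_g[g] = by_g.get(g, 0) + 1
        by_l[l] = by_l.get(l, 0) + 1
    feats["gray_level_nonuniformity"] = sum(c**2 for c in by_g.values()) / nr
    feats["run_length_nonuniformity"] = sum(c**2 for c in by_l.values()) / nr
    return feats


# -- size zones ---------------------------------------------------------------

def zones_oracle(levels, mask):
    """All (level, zone size) pairs via BFS over 26-connectivity."""
    nz, ny, nx = levels.shape
    seen = np.zeros_like(mask, dtype=bool)
    zones = []
    neigh = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x] or seen[z, y, x]:
                    continue
                level = levels[z, y, x]
                size = 0
                q = deque([(z, y, x)])
                seen[z, y, x] = True
                while q:
                    cz, cy, cx = q.popleft()
                    size += 1
                    for dz, dy, dx in neigh:
                        zz, yy, xx = cz + dz, cy + dy, cx + dx
                        if (
                            0 <= zz < nz
                            and 0 <= yy < ny
                            and 0 <= xx < nx
                            and mask[zz, yy, xx]
                            and not seen[zz, yy, xx]
                            and levels[zz, yy, xx] == level
                        ):
                            seen[zz, yy, xx] = True
                            q.append((zz, yy, xx))
                zones.append((int(level), size))
    return zones


def glszm_features_oracle(zones, n_voxels):
    nz_ = len(zones)
    feats = {
        "small_zone_emphasis": sum(1 / s**2 for _, s in zones) / nz_,
        "large_zone_emphasis": sum(s**2 for _, s in zones) / nz_,
        "zone_percentage": nz_ / n_voxels,
        "low_gray_level_zone_emphasis": sum(1 / g**2 for g, _ in zones) / nz_,
        "high_gray_level_zone_emphasis": sum(g**2 for g, _ in zones) / nz_,
        "small_zone_low_gray_level_emphasis": sum(1 / (g**2 * s**2) for g, s in zones) / nz_,
        "small_zone_high_gray_level_emphasis": sum(g**2 / s**2 for g, s in zones) / nz_,
        "large_zone_low_gray_level_emphasis": sum(s**2 / g**2 for g, s in zones) / nz_,
        "large_zone_high_gray_level_emphasis": sum(g**2 * s**2 for g, s in zones) / nz_,
    }
    by_g, by_s = {}, {}
    for g, s in zones:
        by_g[g] = by_g.get(g, 0) + 1
        by_s[s] = by_s.get(s, 0) + 1
    feats["gray_level_nonuniformity"] = sum(c**2 for c in by_g.values()) / nz_
    feats["zone_size_nonuniformity"] = sum(c**2 for c in by_s.values()) / nz_
    mu_g = sum(g for g, _ in zones) / nz_
    mu_s = sum(s for _, s in zones) / nz_
    feats["gray_level_variance"] = sum((g - mu_g) ** 2 for g, _ in zones) / nz_
    feats["zone_size_variance"] = sum((s - mu_s) ** 2 for _, s in zones) / nz_
    probs = [c / nz_ for c in by_s.values()]
    feats["zone_size_entropy"] = -sum(p * math.log2(p) for p in probs if p > 0)
    return feats


# -- enrichment ---------------------------------------------------------------

def es_running_sum_oracle(scores, is_hit, weight_exp=1.0):
    """Full running-sum ES: walk the entire ranked list position by position."""
    n = len(scores)
    hit_w = [abs(s) ** weight_exp if h else 0.0 for s, h in zip(scores, is_hit)]
    w_total = sum(hit_w)
    n_hit = sum(is_hit)
    n_miss = n - n_hit
    if w_total == 0:
        hit_w = [1.0 if h else 0.0 for h in is_hit]
        w_total = float(n_hit)
    running = 0.0
    best = 0.0
    for i in range(n):
        if is_hit[i]:
            running += hit_w[i] / w_total
        else:
            running -= 1.0 / n_miss
        if abs(running) > abs(best) + 1e-15 or (
            abs(abs(running) - abs(best)) <= 1e-15 and running > best
        ):
            best = running
    return best


# -- survival / classification ------------------------------------------------

def concordance_oracle(risk, time, event):
    conc = 0.0
    n_pairs = 0
    n = len(risk)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            # i is the earlier failure
            if not event[i]:
                continue
            if time[j] > time[i] or (time[j] == time[i] and not event[j]):
                n_pairs += 1
                if risk[i] > risk[j]:
                    conc += 1.0
                elif risk[i] == risk[j]:
                    conc += 0.5
    return conc / n_pairs


def auc_oracle(probs, labels):
    pos = [p for p, y in zip(probs, labels) if y == 1]
    neg = [p for p, y in zip(probs, labels) if y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))


def spearman_oracle(x, y):
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den
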