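"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain loops / flood fills over voxels so it
shares no code path with the package's vectorized implementations.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np

NEIGH26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]
OFFSETS_13 = [d for d in NEIGH26 if d > (0, 0, 0)]


def _inside(shape, p):
    return all(0 <= p[ax] < shape[ax] for ax in range(3))


def glcm_counts(levels: np.ndarray, mask: np.ndarray, n_bins: int) -> np.ndarray:
    """Pairwise co-occurrence counts by per-voxel loop over the 13 offsets."""
    counts = np.zeros((n_bins, n_bins))
    shape = levels.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z]:
                    continue
                for off in OFFSETS_13:
                    q = (x + off[0], y + off[1], z + off[2])
                    if _inside(shape, q) and mask[q]:
                        i, j = levels[x, y, z] - 1, levels[q] - 1
                        counts[i, j] += 1
                        counts[j, i] += 1
    return counts


def glcm_feature_tuple(P: np.ndarray):
    ent = uni = dis = hom = 0.0
    n = P.shape[0]
    for i in range(n):
        for j in range(n):
            p = P[i, j]
            if p > 0:
                ent -= p * math.log2(p)
            uni += p * p
            dis += abs(i - j) * p
            hom += p / (1 + abs(i - j))
    return ent, uni, dis, hom


def histogram_entropy(levels_in_mask: np.ndarray, n_bins: int) -> float:
    counts = {}
    for v in levels_in_mask:
        counts[v] = counts.get(v, 0) + 1
    n = len(levels_in_mask)
    ent = 0.0
    for c in counts.values():
        p = c / n
        ent -= p * math.log2(p)
    return ent


def ngtdm_table(levels: np.ndarray, mask: np.ndarray, n_bins: int):
    """Per-voxel neighborhood loop: returns (s, counts, N)."""
    s = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    shape = levels.shape
    n = 0
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z]:
                    continue
                nbrs = []
                for off in NEIGH26:
                    q = (x + off[0], y + off[1], z + off[2])
                    if _inside(shape, q) and mask[q]:
                        nbrs.append(levels[q])
                if not nbrs:
                    continue
                n += 1
                lev = levels[x, y, z]
                counts[lev - 1] += 1
                s[lev - 1] += abs(lev - sum(nbrs) / len(nbrs))
    return s, counts, n


def ngtdm_feature_tuple(s, p, n_gp, n, eps=1e-6, cap=1e6):
    n_bins = len(s)
    psum = sum(p[i] * s[i] for i in range(n_bins))
    coarseness = min(1.0 / (eps + psum), cap)
    if n_gp <= 1:
        contrast = 0.0
    else:
        acc = 0.0
        for i in range(n_bins):
            for j in range(n_bins):
                acc += p[i] * p[j] * (i - j) ** 2
        contrast = acc / (n_gp * (n_gp - 1)) * (sum(s) / n)
    denom = 0.0
    comp = 0.0
    for i in range(n_bins):
        if p[i] == 0:
            continue
        for j in range(n_bins):
            if p[j] == 0:
                continue
            denom += abs((i + 1) * p[i] - (j + 1) * p[j])
            comp += abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (n * (p[i] + p[j]))
    busyness = 0.0 if denom == 0 else psum / denom
    return coarseness, busyness, contrast, comp


def glszm_zones(levels: np.ndarray, mask: np.ndarray):
    """Flood-fill zone enumeration: multiset of (level, size)."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z] or seen[x, y, z]:
                    continue
                lev = levels[x, y, z]
                queue = deque([(x, y, z)])
                seen[x, y, z] = True
                size = 0
                while queue:
                    p = queue.popleft()
                    size += 1
                    for off in NEIGH26:
                        q = (p[0] + off[0], p[1] + off[1], p[2] + off[2])
                        if (_inside(shape, q) and mask[q] and not seen[q]
                                and levels[q] == lev):
                            seen[q] = True
                            queue.append(q)
                zones.append((int(lev), size))
    return sorted(zones)


def glszm_feature_tuple(zones, n_z):
    from collections import Counter

    row = Counter()
    col = Counter()
    hglze = 0.0
    for lev, size in zones:
        row[lev] += 1
        col[size] += 1
        hglze += lev**2 * size**2
    glnu = sum(c**2 for c in row.values()) / n_z
    zsnu = sum(c**2 for c in col.values()) / n_z
    return glnu, zsnu, hglze / n_z


def flood_fill_threshold(values: np.ndarray, threshold: float, start):
    """26-connected region of voxels >= threshold containing `start`."""
    shape = values.shape
    out = np.zeros(shape, dtype=bool)
    if values[start] < threshold:
        return out
    queue = deque([start])
    out[start] = True
    while queue:
        p = queue.popleft()
        for off in NEIGH26:
            q = (p[0] + off[0], p[1] + off[1], p[2] + off[2])
            if _inside(shape, q) and not out[q] and values[q] >= threshold:
                out[q] = True
                queue.append(q)
    return out


def icc_two_way(a: np.ndarray, b: np.ndarray) -> float:
    """ICC(2,1) point estimate from explicitly assembled ANOVA sums."""
    x = np.column_stack([a, b])
    n, k = x.shape
    grand = x.mean()
    ss_rows = k * sum((x[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = n * sum((x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = ((x - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def cox_binary_beta(times, events, group) -> float:
    """Direct 1D maximization of the Cox partial likelihood (no ties),
    via root-finding on the written-out score function."""
    from scipy.optimize import brentq

    times = np.asarray(times, float)
    events = np.asarray(events, int)
    group = np.asarray(group, float)

    def score(beta):
        u = 0.0
        for i in np.flatnonzero(events == 1):
            risk = times >= times[i]
            w = np.exp(beta * group[risk])
            u += group[i] - (group[risk] * w).sum() / w.sum()
        return u

    return float(brentq(score, -10, 10, xtol=1e-12))


def logrank_statistic(times, events, group):
    """Observed-minus-expected log-rank chi-square for two groups."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    group = np.asarray(group, int)
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (group == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def direct_gaussian_smooth(white: np.ndarray, sigma_vox, truncate=4.0):
    """Direct separable Gaussian convolution with edge replication."""
    out = white.astype(float)
    for ax, sig in enumerate(sigma_vox):
        if sig == 0:
            continue
        r = int(truncate * sig + 0.5)
        x = np.arange(-r, r + 1)
        k = np.exp(-0.5 * (x / sig) ** 2)
        k /= k.sum()
        padded = np.concatenate(
            [np.repeat(np.take(out, [0], axis=ax), r, axis=ax), out,
             np.repeat(np.take(out, [-1], axis=ax), r, axis=ax)], axis=ax,
        )
        acc = np.zeros_like(out)
        for m, w in enumerate(k):
            sl = [slice(None)] * 3
            sl[ax] = slice(m, m + out.shape[ax])
            acc += w * padded[tuple(sl)]
        out = acc
    return out
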