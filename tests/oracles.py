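"""Independent brute-force reference implementations.

Everything here is deliberately naive — explicit loops over voxels, pairs
and neighbours, straight from the defining formulas — and shares no code
with the package's vectorised implementations.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter, deque

import numpy as np

NEIGHBORS_26 = [d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]
DIRECTIONS_13 = [d for d in itertools.product((-1, 0, 1), repeat=3) if d > (0, 0, 0)]


def bf_wavelet_band(volume: np.ndarray, filters_per_axis) -> np.ndarray:
    """Separable circular filtering, y[n] = sum_k f[k] x[(n+k) mod N] per axis."""
    out = np.asarray(volume, dtype=float)
    for axis, filt in enumerate(filters_per_axis):
        src = np.moveaxis(out, axis, 0)
        res = np.zeros_like(src)
        n = src.shape[0]
        for pos in range(n):
            acc = np.zeros(src.shape[1:])
            for k, fk in enumerate(filt):
                acc += fk * src[(pos + k) % n]
            res[pos] = acc
        out = np.moveaxis(res, 0, axis)
    return out


def bf_discretize(volume: np.ndarray, mask: np.ndarray, bin_width: float):
    vals = volume[mask]
    lo = vals.min()
    levels = np.zeros(volume.shape, dtype=int)
    for idx in np.argwhere(mask):
        levels[tuple(idx)] = math.floor((volume[tuple(idx)] - lo) / bin_width) + 1
    return levels, levels.max()


def bf_glcm(levels: np.ndarray, mask: np.ndarray, distance: int = 1):
    """Per-direction symmetric GLCM features by exhaustive pair enumeration.

    Returns the mean over directions with at least one pair (None if no
    direction has pairs).
    """
    shape = levels.shape
    feats = {"ClusterProminence": [], "ClusterShade": [], "Correlation": []}
    for d in DIRECTIONS_13:
        pairs = Counter()
        for idx in np.argwhere(mask):
            j = tuple(idx[a] + distance * d[a] for a in range(3))
            if all(0 <= j[a] < shape[a] for a in range(3)) and mask[j]:
                i_lvl, j_lvl = levels[tuple(idx)], levels[j]
                pairs[(i_lvl, j_lvl)] += 1
                pairs[(j_lvl, i_lvl)] += 1
        total = sum(pairs.values())
        if total == 0:
            continue
        p = {k: v / total for k, v in pairs.items()}
        mu_x = sum(i * v for (i, _), v in p.items())
        mu_y = sum(j * v for (_, j), v in p.items())
        sd_x = math.sqrt(sum((i - mu_x) ** 2 * v for (i, _), v in p.items()))
        sd_y = math.sqrt(sum((j - mu_y) ** 2 * v for (_, j), v in p.items()))
        feats["ClusterShade"].append(
            sum((i + j - mu_x - mu_y) ** 3 * v for (i, j), v in p.items()))
        feats["ClusterProminence"].append(
            sum((i + j - mu_x - mu_y) ** 4 * v for (i, j), v in p.items()))
        if sd_x * sd_y > 0:
            cov = sum(i * j * v for (i, j), v in p.items()) - mu_x * mu_y
            feats["Correlation"].append(cov / (sd_x * sd_y))
        else:
            feats["Correlation"].append(1.0)
    if not feats["Correlation"]:
        return {"ClusterProminence": 0.0, "ClusterShade": 0.0, "Correlation": 1.0}
    return {k: float(np.mean(v)) for k, v in feats.items()}


def bf_zones(levels: np.ndarray, mask: np.ndarray, connectivity: int = 26):
    """(level, size) zones by explicit breadth-first flood fill."""
    offsets = (NEIGHBORS_26 if connectivity == 26 else
               [d for d in NEIGHBORS_26 if sum(map(abs, d)) == 1])
    seen = np.zeros(levels.shape, dtype=bool)
    zones = []
    shape = levels.shape
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        lvl = levels[start]
        queue = deque([start])
        seen[start] = True
        size = 0
        while queue:
            cur = queue.popleft()
            size += 1
            for d in offsets:
                nb = tuple(cur[a] + d[a] for a in range(3))
                if all(0 <= nb[a] < shape[a] for a in range(3)) \
                        and mask[nb] and not seen[nb] and levels[nb] == lvl:
                    seen[nb] = True
                    queue.append(nb)
        zones.append((int(lvl), size))
    return zones


def bf_glszm(levels: np.ndarray, mask: np.ndarray, connectivity: int = 26):
    zones = bf_zones(levels, mask, connectivity)
    nz = len(zones)
    counts = Counter(zones)
    by_level = Counter()
    by_size = Counter()
    for (i, s), c in counts.items():
        by_level[i] += c
        by_size[s] += c
    p = {k: c / nz for k, c in counts.items()}
    return {
        "ZoneEntropy": -sum(v * math.log2(v) for v in p.values()),
        "GrayLevelNonUniformity": sum(c * c for c in by_level.values()) / nz,
        "LargeAreaHighGrayLevelEmphasis":
            sum(c * i * i * s * s for (i, s), c in counts.items()) / nz,
        "SizeZoneNonUniformityNormalized":
            sum(c * c for c in by_size.values()) / nz**2,
        "SmallAreaHighGrayLevelEmphasis":
            sum(c * i * i / (s * s) for (i, s), c in counts.items()) / nz,
    }


def bf_gldm_ldlgle(levels: np.ndarray, mask: np.ndarray, alpha: float = 0.0):
    shape = levels.shape
    acc = 0.0
    n = 0
    for idx in map(tuple, np.argwhere(mask)):
        d = 1
        for off in NEIGHBORS_26:
            nb = tuple(idx[a] + off[a] for a in range(3))
            if all(0 <= nb[a] < shape[a] for a in range(3)) and mask[nb] \
                    and abs(int(levels[nb]) - int(levels[idx])) <= alpha:
                d += 1
        acc += d * d / (int(levels[idx]) ** 2)
        n += 1
    return acc / n


def bf_firstorder(volume: np.ndarray, mask: np.ndarray):
    vals = sorted(float(volume[tuple(i)]) for i in np.argwhere(mask))
    n = len(vals)
    mean = sum(vals) / n
    m2 = sum((v - mean) ** 2 for v in vals) / n
    m3 = sum((v - mean) ** 3 for v in vals) / n
    med = (vals[n // 2] if n % 2 else (vals[n // 2 - 1] + vals[n // 2]) / 2)
    return {
        "Range": vals[-1] - vals[0],
        "Median": med,
        "Skewness": (m3 / m2**1.5) if m2 > 0 else 0.0,
    }


def bf_auc(scores, labels) -> float:
    """Concordant-pair fraction with ties counted half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def bf_kappa(calls, labels) -> float:
    n = len(calls)
    p_o = sum(c == l for c, l in zip(calls, labels)) / n
    p_call1 = sum(calls) / n
    p_lab1 = sum(labels) / n
    p_e = p_call1 * p_lab1 + (1 - p_call1) * (1 - p_lab1)
    return (p_o - p_e) / (1 - p_e)


def bf_mlad(p_svm: float, p_rf: float, v_r: int) -> float:
    s_svm = abs(0.5 - p_svm)
    s_rf = abs(0.5 - p_rf)
    inner = (s_rf / 0.5) * p_rf + ((0.5 - s_rf) / 0.5) * v_r
    return (s_svm / 0.5) * p_svm + ((0.5 - s_svm) / 0.5) * inner
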