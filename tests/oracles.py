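"""Independent brute-force oracles used only by the test suite.

Everything here is written for clarity over speed, with algorithms that are
structurally different from the package implementation (pair enumeration,
line splitting, breadth-first flood fill, explicit contingency tables), so
agreement is evidence rather than tautology.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter, deque

import numpy as np

_OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


# ----------------------------------------------------------------- GLCM

def glcm_counts_bruteforce(levels, mask, n_levels, directions):
    """Ordered-pair enumeration over +/- of every direction (equivalent to
    symmetrizing the one-sided count matrix)."""
    counts = np.zeros((n_levels, n_levels))
    voxels = list(zip(*np.nonzero(mask)))
    voxset = set(voxels)
    for v in voxels:
        for d in directions:
            for sign in (1, -1):
                w = tuple(v[a] + sign * d[a] for a in range(3))
                if w in voxset:
                    counts[levels[v] - 1, levels[w] - 1] += 1
    return counts


def glcm_features_bruteforce(levels, mask, n_levels, directions):
    counts = glcm_counts_bruteforce(levels, mask, n_levels, directions)
    total = counts.sum()
    if total == 0:
        return {"Homogeneity": 1.0, "Energy": 1.0, "Contrast": 0.0,
                "Correlation": 1.0, "Entropy": 0.0, "Entropy_log2": 0.0,
                "Dissimilarity": 0.0}
    p = counts / total
    homo = energy = contrast = entropy = dissim = 0.0
    mu_i = mu_j = 0.0
    for i in range(n_levels):
        for j in range(n_levels):
            pij = p[i, j]
            gi, gj = i + 1, j + 1
            homo += pij / (1 + abs(gi - gj))
            energy += pij**2
            contrast += pij * (gi - gj) ** 2
            dissim += pij * abs(gi - gj)
            if pij > 0:
                entropy -= pij * math.log(pij)
            mu_i += pij * gi
            mu_j += pij * gj
    var_i = sum(
        p[i, j] * (i + 1 - mu_i) ** 2 for i in range(n_levels) for j in range(n_levels)
    )
    var_j = sum(
        p[i, j] * (j + 1 - mu_j) ** 2 for i in range(n_levels) for j in range(n_levels)
    )
    if var_i > 0 and var_j > 0:
        corr = sum(
            p[i, j] * (i + 1 - mu_i) * (j + 1 - mu_j)
            for i in range(n_levels)
            for j in range(n_levels)
        ) / math.sqrt(var_i * var_j)
    else:
        corr = 1.0
    return {"Homogeneity": homo, "Energy": energy, "Contrast": contrast,
            "Correlation": corr, "Entropy": entropy,
            "Entropy_log2": entropy / math.log(2), "Dissimilarity": dissim}


# ----------------------------------------------------------------- GLRLM

def glrlm_counts_bruteforce(levels, mask, n_levels, directions):
    """Line-splitting enumeration: walk every full grid line per direction,
    split by VOI membership, group equal-level segments into runs."""
    shape = levels.shape
    max_run = max(shape)
    counts = np.zeros((n_levels, max_run))
    all_idx = list(itertools.product(*[range(s) for s in shape]))
    for d in directions:
        starts = [
            v for v in all_idx
            if not all(0 <= v[a] - d[a] < shape[a] for a in range(3))
        ]
        for v in starts:
            seq = []
            w = v
            while all(0 <= w[a] < shape[a] for a in range(3)):
                seq.append(levels[w] if mask[w] else None)
                w = tuple(w[a] + d[a] for a in range(3))
            for key, grp in itertools.groupby(seq):
                if key is not None:
                    counts[key - 1, len(list(grp)) - 1] += 1
    return counts


def run_zone_features_bruteforce(counts, n_vox, short, long_, low, high,
                                 sl, sh, ll, lh, nu2, pct, n_dirs=1):
    total = counts.sum()
    out = {short: 0.0, long_: 0.0, low: 0.0, high: 0.0, sl: 0.0, sh: 0.0,
           ll: 0.0, lh: 0.0}
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            c = counts[i, j] / total
            gi, rj = i + 1, j + 1
            out[short] += c / rj**2
            out[long_] += c * rj**2
            out[low] += c / gi**2
            out[high] += c * gi**2
            out[sl] += c / (gi**2 * rj**2)
            out[sh] += c * gi**2 / rj**2
            out[ll] += c * rj**2 / gi**2
            out[lh] += c * gi**2 * rj**2
    out["GLNU"] = sum(counts[i, :].sum() ** 2 for i in range(counts.shape[0])) / total
    out[nu2] = sum(counts[:, j].sum() ** 2 for j in range(counts.shape[1])) / total
    out[pct] = total / (n_vox * n_dirs)
    return out


# ----------------------------------------------------------------- GLZLM

def glzlm_zones_bruteforce(levels, mask):
    """Breadth-first flood fill of 26-connected equal-level zones."""
    shape = levels.shape
    seen = np.zeros(shape, bool)
    zones = []
    for v in zip(*np.nonzero(mask)):
        if seen[v]:
            continue
        level = levels[v]
        size = 0
        queue = deque([v])
        seen[v] = True
        while queue:
            w = queue.popleft()
            size += 1
            for d in _OFFSETS_26:
                u = tuple(w[a] + d[a] for a in range(3))
                if (
                    all(0 <= u[a] < shape[a] for a in range(3))
                    and mask[u] and not seen[u] and levels[u] == level
                ):
                    seen[u] = True
                    queue.append(u)
        zones.append((level, size))
    return zones


def glzlm_counts_bruteforce(levels, mask, n_levels):
    zones = glzlm_zones_bruteforce(levels, mask)
    max_size = max(s for _, s in zones)
    counts = np.zeros((n_levels, max_size))
    for level, size in zones:
        counts[level - 1, size - 1] += 1
    return counts


# ----------------------------------------------------------------- NGLDM

def ngldm_features_bruteforce(levels, mask, n_levels, cap=1e6):
    shape = levels.shape
    s = Counter()
    n_i = Counter()
    n_valid = 0
    for v in zip(*np.nonzero(mask)):
        neigh = []
        for d in _OFFSETS_26:
            w = tuple(v[a] + d[a] for a in range(3))
            if all(0 <= w[a] < shape[a] for a in range(3)) and mask[w]:
                neigh.append(levels[w])
        if not neigh:
            continue
        n_valid += 1
        lev = levels[v]
        n_i[lev] += 1
        s[lev] += abs(lev - sum(neigh) / len(neigh))
    if n_valid == 0:
        return {"Coarseness": cap, "Contrast": 0.0, "Busyness": 0.0}
    p = {lev: n / n_valid for lev, n in n_i.items()}
    dc = sum(p[lev] * s[lev] for lev in p)
    coarse = min(1.0 / dc, cap) if dc > 0 else cap
    occ = sorted(p)
    ng = len(occ)
    if ng > 1:
        contrast = (
            sum(p[a] * p[b] * (a - b) ** 2 for a in occ for b in occ)
            / (ng * (ng - 1))
            * (sum(s.values()) / n_valid)
        )
        bd = sum(abs(a * p[a] - b * p[b]) for a in occ for b in occ)
        busy = dc / bd if bd > 0 else 0.0
    else:
        contrast, busy = 0.0, 0.0
    return {"Coarseness": coarse, "Contrast": contrast, "Busyness": busy}


# ------------------------------------------------------------------- misc

def auc_pair_counting(scores, labels):
    """AUC by exhaustive positive/negative pair enumeration, ties half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def mutual_information_table(x, y):
    """MI (nats) from the explicit joint contingency table."""
    n = len(x)
    joint = Counter(zip(x, y))
    px = Counter(x)
    py = Counter(y)
    mi = 0.0
    for (a, b), c in joint.items():
        pxy = c / n
        mi += pxy * math.log(pxy / (px[a] / n * py[b] / n))
    return mi


def mrmr_greedy_bruteforce(columns: dict, labels, k, tol=1e-9):
    """Greedy MID selection with explicit-table MI (3-state inputs).

    Ties (within float tolerance) break toward the earlier feature, the
    stated canonical-order convention.
    """
    names = list(columns)
    selected = []
    remaining = list(names)
    for _ in range(k):
        best, best_score = None, -math.inf
        for f in remaining:
            rel = mutual_information_table(columns[f], labels)
            red = (
                sum(mutual_information_table(columns[f], columns[s]) for s in selected)
                / len(selected)
                if selected
                else 0.0
            )
            if rel - red > best_score + tol:
                best, best_score = f, rel - red
        selected.append(best)
        remaining.remove(best)
    return selected
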