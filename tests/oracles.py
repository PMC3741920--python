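"""Independent brute-force oracles, implemented separately from the package.

Each function re-derives an expected result by the most direct method
available (double loops, exhaustive search, textbook formulas) so the
package implementations can be checked against them exactly.
"""
from __future__ import annotations

import numpy as np


def brute_direction_map(A: np.ndarray) -> np.ndarray:
    """Per-pixel 4-direction run counter, one pixel at a time."""
    A = np.asarray(A, dtype=bool)
    h, w = A.shape
    H = np.zeros((h, w), dtype=float)
    for i in range(h):
        for j in range(w):
            if not A[i, j]:
                continue
            total = 0.0
            for di, dj in ((0, -1), (0, 1), (-1, 0), (1, 0)):
                run = 0
                r, c = i + di, j + dj
                while 0 <= r < h and 0 <= c < w and A[r, c]:
                    run += 1
                    r += di
                    c += dj
                total += np.sqrt(run)
            H[i, j] = total
    return H


def brute_epithelial(centroids: np.ndarray, boundary_pts: np.ndarray):
    """Algorithm-1 style double loop: nearest nucleus per boundary point."""
    selected = set()
    for p in boundary_pts:
        best, best_d = None, np.inf
        for idx, c in enumerate(centroids):
            d = np.hypot(p[0] - c[0], p[1] - c[1])
            if d < best_d:  # strict: ties keep the smallest index
                best, best_d = idx, d
        selected.add(best)
    epi = sorted(selected)
    non = [i for i in range(len(centroids)) if i not in selected]
    return epi, non


def brute_feret(points: np.ndarray) -> float:
    best = 0.0
    for i in range(len(points)):
        for j in range(i + 1, len(points)):
            d = np.hypot(*(points[i] - points[j]))
            best = max(best, d)
    return best


def brute_pips(points: np.ndarray, T: float) -> list[int]:
    """Recursive max-VD subdivision, written independently as a recursion."""

    def vd(s: int, e: int, i: int) -> float:
        p, q, r = points[s], points[e], points[i]
        chord = q - p
        L = np.hypot(*chord)
        if L == 0:
            return np.hypot(*(r - p))
        return abs(chord[0] * (r[1] - p[1]) - chord[1] * (r[0] - p[0])) / L

    found: set[int] = set()

    def recurse(s: int, e: int) -> None:
        if e - s < 2:
            return
        dists = [vd(s, e, i) for i in range(s + 1, e)]
        j = int(np.argmax(dists))
        if dists[j] > T:
            k = s + 1 + j
            found.add(k)
            recurse(s, k)
            recurse(k, e)

    recurse(0, len(points) - 1)
    return sorted(found | {0, len(points) - 1})


def prune_pips(points: np.ndarray, indices: list[int], theta_min: float):
    """Iteratively drop the interior PIP with the smallest turning angle."""
    idx = list(indices)
    while len(idx) > 2:
        angles = []
        for pos in range(1, len(idx) - 1):
            a = points[idx[pos]] - points[idx[pos - 1]]
            b = points[idx[pos + 1]] - points[idx[pos]]
            cosang = np.dot(a, b) / (np.hypot(*a) * np.hypot(*b))
            angles.append(np.arccos(np.clip(cosang, -1, 1)))
        k = int(np.argmin(angles))
        if angles[k] >= theta_min:
            break
        del idx[k + 1]
    return idx


def auc_pair_count(scores, labels) -> float:
    """Mann-Whitney concordant-pair AUC; ties count one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels != 1]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def textbook_anova(groups: list[np.ndarray]):
    """One-way ANOVA sums of squares computed longhand."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    F = (ssb / df_b) / (ssw / df_w) if ssw > 0 else (0.0 if ssb == 0 else np.inf)
    return F, df_b, df_w, ssw / df_w


def textbook_lsd_flags(groups: list[np.ndarray], alpha: float):
    """Pairwise Fisher-LSD decisions from the classic formula."""
    from scipy import stats

    _, _, df_w, msw = textbook_anova(groups)
    t_crit = stats.t.ppf(1 - alpha / 2, df_w)
    flags = {}
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            lsd = t_crit * np.sqrt(msw * (1 / len(groups[i]) + 1 / len(groups[j])))
            diff = abs(groups[i].mean() - groups[j].mean())
            flags[(i, j)] = diff > lsd
    return flags
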