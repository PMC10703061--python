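"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately written as plain nested loops over pixels /
set elements, independent of the vectorized implementations under test.
"""

from __future__ import annotations

import numpy as np


def median_oracle(image: np.ndarray, window: int) -> np.ndarray:
    """Sliding-window median with edge replication, by explicit loops."""
    h, w = image.shape
    r = window // 2
    out = np.empty_like(image)
    for i in range(h):
        for j in range(w):
            vals = []
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    ii = min(max(i + di, 0), h - 1)
                    jj = min(max(j + dj, 0), w - 1)
                    vals.append(image[ii, jj])
            out[i, j] = np.median(vals)
    return out


def dilate_oracle(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Minkowski dilation as a union of shifted footprints."""
    h, w = mask.shape
    fr, fc = footprint.shape
    cr, cc = fr // 2, fc // 2
    out = np.zeros_like(mask, dtype=bool)
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            for di in range(fr):
                for dj in range(fc):
                    if not footprint[di, dj]:
                        continue
                    ii, jj = i + di - cr, j + dj - cc
                    if 0 <= ii < h and 0 <= jj < w:
                        out[ii, jj] = True
    return out


def glcm_oracle(image: np.ndarray, offset: tuple[int, int], L: int,
                symmetric: bool, normalize: bool) -> np.ndarray:
    """Ordered pair counting by double loop over all pixels."""
    h, w = image.shape
    dr, dc = offset
    C = np.zeros((L, L), dtype=float)
    for i in range(h):
        for j in range(w):
            ii, jj = i + dr, j + dc
            if 0 <= ii < h and 0 <= jj < w:
                C[image[i, j], image[ii, jj]] += 1
    if symmetric:
        C = C + C.T
    if normalize and C.sum() > 0:
        C = C / C.sum()
    return C


def conv_bank_oracle(image01: np.ndarray, kernel: np.ndarray, bias: float,
                     stride: int, pool: int) -> np.ndarray:
    """Valid cross-correlation + bias + ReLU + non-overlapping max-pool."""
    h, w = image01.shape
    k = kernel.shape[0]
    oh, ow = h - k + 1, w - k + 1
    fmap = np.zeros((oh, ow))
    for i in range(oh):
        for j in range(ow):
            acc = 0.0
            for di in range(k):
                for dj in range(k):
                    acc += image01[i + di, j + dj] * kernel[di, dj]
            fmap[i, j] = max(acc + bias, 0.0)
    fmap = fmap[::stride, ::stride]
    hp, wp = fmap.shape[0] // pool, fmap.shape[1] // pool
    out = np.zeros((hp, wp))
    for i in range(hp):
        for j in range(wp):
            out[i, j] = fmap[i * pool:(i + 1) * pool, j * pool:(j + 1) * pool].max()
    return out


def confusion_oracle(labels, predictions, positive) -> tuple[int, int, int, int]:
    """Per-sample confusion counting."""
    tp = tn = fp = fn = 0
    for y, p in zip(labels, predictions):
        if y == positive and p == positive:
            tp += 1
        elif y == positive:
            fn += 1
        elif p == positive:
            fp += 1
        else:
            tn += 1
    return tp, tn, fp, fn


def multiotsu_oracle(hist: np.ndarray, n_levels: int) -> tuple:
    """Exhaustive search over all threshold tuples, computing between-class
    variance directly from its definition for each candidate."""
    from itertools import combinations

    hist = np.asarray(hist, dtype=float)
    n_bins = hist.size
    p = hist / hist.sum()
    bins = np.arange(n_bins)
    best, best_score = None, -np.inf
    for edges in combinations(range(n_bins - 1), n_levels - 1):
        bounds = [-1, *edges, n_bins - 1]
        score = 0.0
        for k in range(n_levels):
            sel = (bins > bounds[k]) & (bins <= bounds[k + 1])
            w = p[sel].sum()
            if w > 0:
                m = (p[sel] * bins[sel]).sum() / w
                score += w * m * m
        if score > best_score:
            best_score, best = score, edges
    return best
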