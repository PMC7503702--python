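"""Independent brute-force oracles, written without reference to the
implementation paths they check (no FFT, no vectorized distance tricks)."""

from __future__ import annotations

import math

import numpy as np


def brute_force_s2(pixels: np.ndarray, max_bin: int) -> np.ndarray:
    """Radially averaged normalized two-point correlation by explicit
    per-lag pair counting.

    For every integer lag (dy, dx) the number of foreground-foreground
    pairs and the number of valid in-image pairs are counted directly on
    array slices; the per-lag hit probability is normalized to
    (prob - p^2)/(p - p^2) and averaged over annuli [k, k+1) pixels.
    """
    img = np.asarray(pixels, dtype=bool)
    ny, nx = img.shape
    p = img.sum() / img.size
    sums = np.zeros(max_bin + 1)
    counts = np.zeros(max_bin + 1, dtype=int)
    for dy in range(-(ny - 1), ny):
        for dx in range(-(nx - 1), nx):
            r = math.hypot(dy, dx)
            b = int(r)
            if b > max_bin:
                continue
            y0, y1 = max(0, -dy), min(ny, ny - dy)
            x0, x1 = max(0, -dx), min(nx, nx - dx)
            a_sl = img[y0:y1, x0:x1]
            b_sl = img[y0 + dy : y1 + dy, x0 + dx : x1 + dx]
            n_valid = (y1 - y0) * (x1 - x0)
            hits = int(np.logical_and(a_sl, b_sl).sum())
            prob = hits / n_valid
            sums[b] += (prob - p * p) / (p - p * p)
            counts[b] += 1
    out = np.full(max_bin + 1, np.nan)
    nz = counts > 0
    out[nz] = sums[nz] / counts[nz]
    if not nz.all():
        idx = np.arange(max_bin + 1)
        out[~nz] = np.interp(idx[~nz], idx[nz], out[nz])
    return out


def brute_force_within(points: np.ndarray, labels: np.ndarray, centroids: np.ndarray):
    """W per cluster and totW by an explicit double loop."""
    k = len(centroids)
    per = [0.0] * k
    for (x, y), lab in zip(points, labels):
        cx, cy = centroids[lab]
        per[lab] += (x - cx) ** 2 + (y - cy) ** 2
    return np.array(per), float(sum(per))


def brute_force_silhouette(points: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-point silhouette coefficients by explicit pairwise loops."""
    n = len(points)
    coefs = np.zeros(n)
    clusters = sorted(set(int(l) for l in labels))
    for i in range(n):
        own = labels[i]
        same = [j for j in range(n) if labels[j] == own and j != i]
        if not same:
            coefs[i] = 0.0
            continue
        y = sum(math.dist(points[i], points[j]) for j in same) / len(same)
        x = math.inf
        for c in clusters:
            if c == own:
                continue
            other = [j for j in range(n) if labels[j] == c]
            d = sum(math.dist(points[i], points[j]) for j in other) / len(other)
            x = min(x, d)
        coefs[i] = (x - y) / max(x, y)
    return coefs
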