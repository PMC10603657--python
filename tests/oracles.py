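"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's fast implementations (distance
transforms, the autograd engine): everything is a plain double loop or a
direct numpy/scipy computation, so agreement is meaningful evidence.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import correlate2d


def brute_force_distance_map(coords: np.ndarray, height: int, width: int, truncation: float) -> np.ndarray:
    """Eq.-style distance map: min Euclidean distance per pixel, clipped."""
    out = np.full((height, width), truncation, dtype=np.float64)
    for i in range(height):
        for j in range(width):
            for r, c in coords:
                d = np.sqrt((i - r) ** 2 + (j - c) ** 2)
                if d < out[i, j]:
                    out[i, j] = d
    return out


def brute_force_phi(p: tuple[int, int], region_mask: np.ndarray) -> float:
    """Shortest distance from p to any True pixel (inf if none)."""
    best = np.inf
    rows, cols = np.nonzero(region_mask)
    for r, c in zip(rows, cols):
        d = np.hypot(p[0] - r, p[1] - c)
        if d < best:
            best = d
    return float(best)


def brute_force_phi_points(p: tuple[int, int], coords: np.ndarray) -> float:
    best = np.inf
    for r, c in coords:
        d = np.hypot(p[0] - r, p[1] - c)
        if d < best:
            best = d
    return float(best)


def enumerate_positive_candidates(mask: np.ndarray, p1: float, p2: float, positives: np.ndarray) -> np.ndarray:
    """Exhaustive evaluation of the positive-click candidate set."""
    h, w = mask.shape
    bg = ~mask.astype(bool)
    out = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            if brute_force_phi((i, j), bg) <= p1:
                continue
            if positives.shape[0] and brute_force_phi_points((i, j), positives) <= p2:
                continue
            out[i, j] = True
    return out


def enumerate_negative_candidates(
    mask: np.ndarray, n1: float, n2: float, n3: float, negatives: np.ndarray
) -> np.ndarray:
    """Exhaustive evaluation of the negative-click candidate set."""
    h, w = mask.shape
    fg = mask.astype(bool)
    out = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            if mask[i, j]:
                continue
            d = brute_force_phi((i, j), fg)
            if not (n1 < d < n2):
                continue
            if negatives.shape[0] and brute_force_phi_points((i, j), negatives) <= n3:
                continue
            out[i, j] = True
    return out


def phi_map_direct(region_mask: np.ndarray) -> np.ndarray:
    """phi(p, region) for every pixel p, by direct pairwise distances.

    Exhaustive evaluation via scipy's cdist (no distance transform), so it is
    an independent check of the EDT-backed implementations at scales where
    the pure-python loops are impractical.
    """
    from scipy.spatial.distance import cdist

    h, w = region_mask.shape
    coords = np.argwhere(region_mask)
    pixels = np.argwhere(np.ones_like(region_mask, dtype=bool))
    if coords.shape[0] == 0:
        return np.full((h, w), np.inf)
    d = cdist(pixels.astype(float), coords.astype(float)).min(axis=1)
    return d.reshape(h, w)


def phi_points_direct(p: tuple[int, int], coords: np.ndarray) -> float:
    """min Euclidean distance from p to a point set (inf if empty)."""
    if coords.shape[0] == 0:
        return float("inf")
    return float(np.hypot(coords[:, 0] - p[0], coords[:, 1] - p[1]).min())


def enumerate_positive_candidates_direct(
    mask: np.ndarray, p1: float, p2: float, positives: np.ndarray
) -> np.ndarray:
    """Exhaustive Cp evaluation built on pairwise distances only."""
    fg = mask.astype(bool)
    phi_bg = phi_map_direct(~fg)
    out = fg & (phi_bg > p1)
    if positives.shape[0]:
        h, w = mask.shape
        for i in range(h):
            for j in range(w):
                if out[i, j] and phi_points_direct((i, j), positives) <= p2:
                    out[i, j] = False
    return out


def enumerate_negative_candidates_direct(
    mask: np.ndarray, n1: float, n2: float, n3: float, negatives: np.ndarray
) -> np.ndarray:
    """Exhaustive Cn evaluation built on pairwise distances only."""
    fg = mask.astype(bool)
    phi_fg = phi_map_direct(fg)
    out = (~fg) & (phi_fg > n1) & (phi_fg < n2)
    if negatives.shape[0]:
        h, w = mask.shape
        for i in range(h):
            for j in range(w):
                if out[i, j] and phi_points_direct((i, j), negatives) <= n3:
                    out[i, j] = False
    return out


def conv2d_direct(x: np.ndarray, w: np.ndarray, b: np.ndarray | None = None, pad: int = 0) -> np.ndarray:
    """Stride-1 cross-correlation via scipy, NCHW / (O, C, KH, KW)."""
    n, c, h, wd = x.shape
    o = w.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = xp.shape[2] - w.shape[2] + 1
    ow = xp.shape[3] - w.shape[3] + 1
    out = np.zeros((n, o, oh, ow))
    for ni in range(n):
        for oi in range(o):
            acc = np.zeros((oh, ow))
            for ci in range(c):
                acc += correlate2d(xp[ni, ci], w[oi, ci], mode="valid")
            out[ni, oi] = acc + (b[oi] if b is not None else 0.0)
    return out


def bilinear_matrix(out_size: int, in_size: int) -> np.ndarray:
    """Half-pixel-centre bilinear interpolation matrix (independent copy)."""
    a = np.zeros((out_size, in_size))
    if in_size == 1:
        a[:, 0] = 1.0
        return a
    for o in range(out_size):
        src = (o + 0.5) * in_size / out_size - 0.5
        src = min(max(src, 0.0), in_size - 1)
        i0 = int(np.floor(src))
        i1 = min(i0 + 1, in_size - 1)
        frac = src - i0
        a[o, i0] += 1 - frac
        a[o, i1] += frac
    return a


def upsample2x_bilinear(x: np.ndarray) -> np.ndarray:
    """2x bilinear upsample of an NCHW array via the matrix form."""
    n, c, h, w = x.shape
    ah = bilinear_matrix(2 * h, h)
    aw = bilinear_matrix(2 * w, w)
    return np.einsum("oh,nchw,pw->ncop", ah, x, aw)


def mhff_manual(
    high: np.ndarray,
    low: np.ndarray,
    w_high: np.ndarray,
    b_high: np.ndarray,
    w_low: np.ndarray,
    b_low: np.ndarray,
    w_fuse: np.ndarray,
    b_fuse: np.ndarray,
) -> np.ndarray:
    """Step-by-step execution of the five-step multi-head fusion procedure."""
    step1 = conv2d_direct(high, w_high, b_high, pad=1)  # map high -> fusion space
    step2 = conv2d_direct(low, w_low, b_low, pad=1)  # map low -> fusion space
    step3 = upsample2x_bilinear(step1)  # 2x upsample of step 1
    step4 = np.concatenate([step2, step3], axis=1)  # concatenate
    return conv2d_direct(step4, w_fuse, b_fuse, pad=1)  # fuse to 48-wide space


def ua_manual(
    high: np.ndarray,
    low: np.ndarray,
    w1: np.ndarray,
    b1: np.ndarray,
    w2: np.ndarray,
    b2: np.ndarray,
) -> np.ndarray:
    """Hand evaluation of squeeze-excitation-scale channel gating."""
    n = high.shape[0]
    out = np.empty_like(low, dtype=np.float64)
    for ni in range(n):
        avg = high[ni].mean(axis=(1, 2))
        mx = high[ni].max(axis=(1, 2))
        z_avg = np.maximum(avg @ w1 + b1, 0.0) @ w2 + b2
        z_max = np.maximum(mx @ w1 + b1, 0.0) @ w2 + b2
        weights = 1.0 / (1.0 + np.exp(-(z_avg + z_max)))
        out[ni] = low[ni] * weights[:, None, None]
    return out


def random_blob_mask(size: int, rng: np.random.Generator, radius_range=(4, 12)) -> np.ndarray:
    """A filled disk-ish blob, independent of the package's generator."""
    r = rng.uniform(*radius_range)
    cy = rng.uniform(r + 1, size - r - 1)
    cx = rng.uniform(r + 1, size - r - 1)
    yy, xx = np.mgrid[0:size, 0:size]
    wobble = 1.0 + 0.2 * np.sin(3 * np.arctan2(yy - cy, xx - cx) + rng.uniform(0, 6.28))
    mask = ((yy - cy) ** 2 + (xx - cx) ** 2) <= (r * wobble) ** 2
    return mask.astype(np.uint8)
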