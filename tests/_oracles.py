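"""Independent oracles used to validate the implementation.

Each oracle is a deliberately naive, self-contained implementation (explicit
loops, brute-force scans, direct quadrature) sharing no code with the package.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import integrate
from scipy import stats as sps


# ---------------------------------------------------------------------------
# connected components: stack-based flood fill


def flood_fill_labels(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Label connected components by explicit flood fill; labels follow raster
    order of each component's first pixel."""
    mask = np.asarray(mask, dtype=bool)
    if connectivity == 4:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        neigh = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=int)
    nxt = 0
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and labels[r0, c0] == 0:
                nxt += 1
                stack = [(r0, c0)]
                labels[r0, c0] = nxt
                while stack:
                    r, c = stack.pop()
                    for dr, dc in neigh:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and labels[rr, cc] == 0:
                            labels[rr, cc] = nxt
                            stack.append((rr, cc))
    return labels


def canonical_partition(labels: np.ndarray) -> set[frozenset]:
    """Partition of labelled pixels as a set of pixel-index sets."""
    out = []
    for lab in np.unique(labels):
        if lab > 0:
            out.append(frozenset(map(tuple, np.argwhere(labels == lab))))
    return set(out)


# ---------------------------------------------------------------------------
# triangle threshold: brute-force point-to-line distance maximiser


def triangle_bin_bruteforce(hist) -> int:
    """Scan every bin between the peak and the far end of the longer tail and
    maximise the perpendicular distance to the peak-tail chord (line written
    in ax + by + c = 0 form; ties broken toward the peak)."""
    hist = [float(v) for v in hist]
    peak = max(range(len(hist)), key=lambda i: (hist[i], -i))
    occupied = [i for i, v in enumerate(hist) if v > 0]
    left, right = peak - occupied[0], occupied[-1] - peak
    tail = occupied[-1] if right >= left else occupied[0]
    if tail == peak:
        return peak
    # line through (peak, hist[peak]) and (tail, hist[tail])
    a = hist[tail] - hist[peak]
    b = float(peak - tail)
    c = -(a * peak + b * hist[peak])
    denom = math.hypot(a, b)
    step = 1 if tail > peak else -1
    best, best_d = peak, -1.0
    for i in range(peak, tail + step, step):
        d = abs(a * i + b * hist[i] + c) / denom
        if d > best_d:
            best, best_d = i, d
    return best


# ---------------------------------------------------------------------------
# rolling ball: shift-stack grayscale opening


def rolling_ball_oracle(img: np.ndarray, radius: float) -> np.ndarray:
    """Background subtraction via explicit erosion-then-dilation with a
    spherical-cap element, realised as a stack of shifted arrays."""
    img = np.asarray(img, dtype=np.float64)
    r = int(math.ceil(radius))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = (yy * yy + xx * xx).astype(float)
    inside = d2 <= radius * radius
    height = np.where(inside, np.sqrt(np.maximum(radius * radius - d2, 0.0)), np.nan)
    h, w = img.shape
    offsets = [(dr, dc) for dr in range(-r, r + 1) for dc in range(-r, r + 1)
               if inside[dr + r, dc + r]]

    pad = np.pad(img, r, mode="edge")
    ero = np.full((h, w), np.inf)
    for dr, dc in offsets:
        ero = np.minimum(ero, pad[r + dr : r + dr + h, r + dc : r + dc + w]
                         - height[dr + r, dc + r])
    pad2 = np.pad(ero, r, mode="edge")
    dil = np.full((h, w), -np.inf)
    for dr, dc in offsets:
        dil = np.maximum(dil, pad2[r - dr : r - dr + h, r - dc : r - dc + w]
                         + height[dr + r, dc + r])
    return np.clip(img - dil, 0.0, None)


# ---------------------------------------------------------------------------
# marching-squares perimeter


def marching_squares_perimeter(mask: np.ndarray) -> float:
    """Perimeter as the length of the 0.5-level contour of the binary mask."""
    from skimage import measure

    total = 0.0
    for contour in measure.find_contours(np.asarray(mask, float), 0.5):
        total += float(np.sum(np.hypot(*np.diff(contour, axis=0).T)))
    return total


# ---------------------------------------------------------------------------
# balanced two-way ANOVA sums of squares (closed form)


def balanced_twoway_ss(y: np.ndarray, a: np.ndarray, b: np.ndarray) -> dict[str, float]:
    """Classical closed-form sums of squares for a balanced two-factor design."""
    y = np.asarray(y, float)
    a = np.asarray(a)
    b = np.asarray(b)
    levels_a, levels_b = np.unique(a), np.unique(b)
    n = len(y) // (len(levels_a) * len(levels_b))
    grand = y.mean()
    ss_a = n * len(levels_b) * sum((y[a == la].mean() - grand) ** 2 for la in levels_a)
    ss_b = n * len(levels_a) * sum((y[b == lb].mean() - grand) ** 2 for lb in levels_b)
    ss_cells = 0.0
    ss_err = 0.0
    for la in levels_a:
        for lb in levels_b:
            cell = y[(a == la) & (b == lb)]
            ss_cells += n * (cell.mean() - grand) ** 2
            ss_err += ((cell - cell.mean()) ** 2).sum()
    ss_ab = ss_cells - ss_a - ss_b
    return {"location": ss_a, "brain_area": ss_b, "interaction": ss_ab, "residual": ss_err}


# ---------------------------------------------------------------------------
# studentized range CDF by direct quadrature


def studentized_range_cdf_quadrature(q: float, k: int, df: int) -> float:
    """P(Q <= q) for the studentized range of k groups with df residual
    degrees of freedom, by nested numerical integration."""

    def inner(s: float) -> float:
        def g(z: float) -> float:
            return sps.norm.pdf(z) * (sps.norm.cdf(z) - sps.norm.cdf(z - q * s)) ** (k - 1)

        val, _ = integrate.quad(g, -12, 12, epsabs=1e-10, limit=200)
        return k * val

    # density of s = chi_df / sqrt(df)
    log_norm = (df / 2.0) * math.log(df / 2.0) - math.lgamma(df / 2.0)

    def outer(s: float) -> float:
        log_f = log_norm + (df - 1) * math.log(s) - df * s * s / 2.0 + math.log(2.0)
        return math.exp(log_f) * inner(s)

    hi = 1.0 + 10.0 / math.sqrt(2.0 * df)
    lo = max(1e-9, 1.0 - 10.0 / math.sqrt(2.0 * df))
    val, _ = integrate.quad(outer, lo, hi, epsabs=1e-8, limit=200)
    return val
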