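"""Background subtraction and binarisation.

The processing chain mirrors the standard Fiji workflow for punctate
immunofluorescence: rolling-ball background subtraction (grayscale opening by
a spherical-cap structuring element), then triangle autothresholding — the
method of choice for histograms whose peak sits at one extreme, as is the case
for sparse puncta over dark neuropil.  For intensity-correlation analyses a
Costes-style automatic threshold pair is provided.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .imaging import BinaryMask, CalibratedImage, Roi

__all__ = [
    "ThresholdMethod",
    "ThresholdResult",
    "ball_element",
    "rolling_ball_subtract",
    "triangle_bin",
    "triangle_threshold",
    "costes_auto_threshold",
]


class ThresholdMethod(str, enum.Enum):
    TRIANGLE = "TRIANGLE"
    COSTES = "COSTES"
    FIXED = "FIXED"


@dataclass
class ThresholdResult:
    """A threshold value, the method that produced it, and the resulting mask.

    The mask is strict: every true pixel has source intensity > threshold.
    """

    threshold: float
    method: ThresholdMethod
    mask: BinaryMask


def ball_element(radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Footprint and height profile of a spherical-cap structuring element.

    Heights are ``sqrt(r^2 - d^2)`` on the disc ``d <= r`` — the ball that
    "rolls" under the intensity surface.
    """
    r = int(np.ceil(radius))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = (xx * xx + yy * yy).astype(np.float64)
    footprint = d2 <= radius * radius
    heights = np.zeros_like(d2)
    heights[footprint] = np.sqrt(radius * radius - d2[footprint])
    return footprint, heights


def rolling_ball_subtract(img: CalibratedImage, radius_px: int = 50) -> CalibratedImage:
    """Subtract the rolling-ball background estimate (default radius 50 px).

    The background is the grayscale opening of the image by a ball of the
    given radius: erosion (ball rolled under the surface) followed by
    dilation (surface traced by the ball top).  Output is clipped at zero and
    never exceeds the input anywhere.  No down-scaling shortcut is used.
    """
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    h, w = img.shape
    if radius_px > h and radius_px > w:
        raise ValueError(f"rolling-ball radius {radius_px} exceeds both image dimensions {h}x{w}")
    footprint, heights = ball_element(radius_px)
    f = img.pixels.astype(np.float64, copy=False)
    eroded = ndi.grey_erosion(f, footprint=footprint, structure=heights, mode="nearest")
    background = ndi.grey_dilation(eroded, footprint=footprint, structure=heights, mode="nearest")
    out = np.clip(f - background, 0.0, None)
    return CalibratedImage(out, img.pixel_size_nm, img.channel_label)


def triangle_bin(hist: np.ndarray) -> int:
    """Index of the triangle-threshold bin of a histogram.

    Geometry: draw the chord from the histogram peak to the farthest non-empty
    bin on the longer tail (tie -> higher-intensity tail) and return the bin
    between them maximising perpendicular distance to that chord.  Ties are
    broken toward the peak (first maximum scanning peak -> tail).
    """
    hist = np.asarray(hist, dtype=np.float64)
    nonzero = np.flatnonzero(hist)
    if nonzero.size == 0:
        raise ValueError("empty histogram")
    peak = int(np.argmax(hist))
    left_extent = peak - nonzero[0]
    right_extent = nonzero[-1] - peak
    if right_extent >= left_extent:  # tie -> higher-intensity tail
        tail = int(nonzero[-1])
    else:
        tail = int(nonzero[0])
    if tail == peak:
        return peak
    step = 1 if tail > peak else -1
    x1, y1 = float(peak), hist[peak]
    x2, y2 = float(tail), hist[tail]
    norm = np.hypot(x2 - x1, y2 - y1)
    best_bin, best_d = peak, -1.0
    for b in range(peak, tail + step, step):
        d = abs((x2 - x1) * (y1 - hist[b]) - (x1 - b) * (y2 - y1)) / norm
        if d > best_d:
            best_d, best_bin = d, b
    return best_bin


def triangle_threshold(
    img: CalibratedImage,
    mask_scope: Roi | None = None,
    n_bins: int = 256,
) -> ThresholdResult:
    """Binarise by the triangle method (256 bins over the scoped value range).

    The returned mask keeps pixels strictly above the threshold, restricted to
    ``mask_scope`` when one is given.  A constant image (a degenerate
    histogram) yields the single occupied value as threshold and an empty
    mask.
    """
    values = img.pixels[mask_scope.mask] if mask_scope is not None else img.pixels.ravel()
    values = values.astype(np.float64, copy=False)
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        thr = lo
    else:
        hist, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
        b = triangle_bin(hist)
        thr = float(0.5 * (edges[b] + edges[b + 1]))
    above = img.pixels.astype(np.float64, copy=False) > thr
    if mask_scope is not None:
        above &= mask_scope.mask
    return ThresholdResult(
        threshold=thr,
        method=ThresholdMethod.TRIANGLE,
        mask=BinaryMask(above, {"method": "TRIANGLE", "threshold": thr, "n_bins": n_bins}),
    )


def costes_auto_threshold(
    imgA: CalibratedImage,
    imgB: CalibratedImage,
    roi: Roi,
    n_steps: int = 256,
) -> tuple[ThresholdResult, ThresholdResult]:
    """Costes automatic threshold pair for two channels within an ROI.

    Fits the orthogonal (major-axis) regression of B on A over the ROI, then
    lowers a candidate threshold T along A — with the paired B threshold taken
    from the regression line — until the Pearson correlation of the pixels at
    or below both thresholds first drops to <= 0.  Pixels strictly above the
    per-channel thresholds form the retained masks.
    """
    if imgA.shape != imgB.shape:
        raise ValueError("channels must be congruent")
    a = imgA.pixels[roi.mask].astype(np.float64)
    b = imgB.pixels[roi.mask].astype(np.float64)
    if a.size < 2:
        raise ValueError("ROI too small for regression")
    am, bm = a.mean(), b.mean()
    saa = np.sum((a - am) ** 2)
    sbb = np.sum((b - bm) ** 2)
    sab = np.sum((a - am) * (b - bm))
    if saa == 0 or sbb == 0:
        raise ValueError("zero variance in a channel: regression undefined")
    if sab == 0:
        slope = np.sqrt(sbb / saa)  # degenerate orthogonal fit: axis-ratio slope
    else:
        slope = (sbb - saa + np.hypot(sbb - saa, 2 * sab)) / (2 * sab)
    intercept = bm - slope * am
    lo, hi = float(a.min()), float(a.max())
    candidates = np.linspace(hi, lo, n_steps)
    thr_a = None
    for t in candidates:
        below = (a <= t) & (b <= slope * t + intercept)
        if below.sum() < 2:
            continue
        ab, bb_ = a[below], b[below]
        if ab.std() == 0 or bb_.std() == 0:
            continue  # constant below-set carries no anticorrelation evidence
        r = float(np.corrcoef(ab, bb_)[0, 1])
        if r <= 0:
            thr_a = float(t)
            break
    if thr_a is None:
        # correlation never vanished (e.g. B == A): retain everything
        thr_a = lo - 1.0
    thr_b = float(slope * thr_a + intercept)

    def _result(img: CalibratedImage, thr: float) -> ThresholdResult:
        above = (img.pixels.astype(np.float64, copy=False) > thr) & roi.mask
        return ThresholdResult(
            threshold=thr,
            method=ThresholdMethod.COSTES,
            mask=BinaryMask(above, {"method": "COSTES", "threshold": thr}),
        )

    return _result(imgA, thr_a), _result(imgB, thr_b)
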