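"""ROI-restricted colocalization: Pearson correlation, Manders coefficients on
binarised channels, and the ankyrin-G overlap check used to validate AIS ROIs.

On binary masks the Manders coefficients reduce to overlap-area fractions:
M1 = |A n B n roi| / |A n roi| (fraction of subunit signal on the partner),
M2 = |A n B n roi| / |B n roi| (fraction of partner signal on the subunit).
An intensity-weighted variant is provided but is not the default, because the
quantification convention here derives colocalization from binarised images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .imaging import BinaryMask, CalibratedImage, Roi

__all__ = [
    "ColocResult",
    "pearson_roi",
    "manders_binary",
    "manders_intensity",
    "validate_ais_roi",
]


@dataclass
class ColocResult:
    roi_label: int
    pearson_r: float
    m1: float
    m2: float
    n_pixels: int


def pearson_roi(
    imgA: CalibratedImage,
    imgB: CalibratedImage,
    roi: Roi,
    thresholds: tuple[float, float] | None = None,
) -> float:
    """Pearson correlation of the two channels over ROI pixels.

    With ``thresholds`` given, only pixels strictly above both per-channel
    thresholds enter the correlation (the Costes-style convention); otherwise
    all ROI pixels are used.  Zero variance in either channel over the
    evaluation set makes the correlation undefined: NaN with a warning.
    """
    if imgA.shape != imgB.shape:
        raise ValueError("channels must be congruent")
    if not roi.mask.any():
        raise ValueError("empty ROI")
    a = imgA.pixels.astype(np.float64, copy=False)
    b = imgB.pixels.astype(np.float64, copy=False)
    sel = roi.mask
    if thresholds is not None:
        sel = sel & (a > thresholds[0]) & (b > thresholds[1])
        if sel.sum() < 2:
            raise ValueError("fewer than 2 pixels survive the thresholds")
    av, bv = a[sel], b[sel]
    if av.std() == 0 or bv.std() == 0:
        warnings.warn("zero variance in a channel: Pearson r undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(av, bv)[0, 1])


def manders_binary(maskA: BinaryMask, maskB: BinaryMask, roi: Roi) -> tuple[float, float]:
    """Binary Manders overlap fractions (M1, M2) within the ROI.

    An empty reference mask within the ROI makes the corresponding
    coefficient missing (NaN).
    """
    if maskA.pixels.shape != maskB.pixels.shape or maskA.pixels.shape != roi.mask.shape:
        raise ValueError("masks and ROI must be congruent")
    a = maskA.pixels & roi.mask
    b = maskB.pixels & roi.mask
    inter = int((a & b).sum())
    na, nb = int(a.sum()), int(b.sum())
    m1 = inter / na if na else float("nan")
    m2 = inter / nb if nb else float("nan")
    return m1, m2


def manders_intensity(
    imgA: CalibratedImage,
    imgB: CalibratedImage,
    maskA: BinaryMask,
    maskB: BinaryMask,
    roi: Roi,
) -> tuple[float, float]:
    """Intensity-weighted Manders variant (off by default in the pipeline)."""
    a = imgA.pixels.astype(np.float64, copy=False)
    b = imgB.pixels.astype(np.float64, copy=False)
    in_a = maskA.pixels & roi.mask
    in_b = maskB.pixels & roi.mask
    sum_a = a[in_a].sum()
    sum_b = b[in_b].sum()
    m1 = a[in_a & maskB.pixels].sum() / sum_a if sum_a > 0 else float("nan")
    m2 = b[in_b & maskA.pixels].sum() / sum_b if sum_b > 0 else float("nan")
    return m1, m2


def validate_ais_roi(
    subunit_mask: BinaryMask,
    ankg_mask: BinaryMask,
    roi: Roi,
    min_overlap_fraction: float = 0.5,
) -> bool:
    """Check that a candidate AIS ROI lies on ankyrin-G-positive territory.

    True when the fraction of subunit-positive ROI pixels falling on
    AnkG-positive pixels reaches ``min_overlap_fraction``.  An ROI without
    subunit signal cannot be validated: False with a warning.
    """
    sub = subunit_mask.pixels & roi.mask
    n_sub = int(sub.sum())
    if n_sub == 0:
        warnings.warn(
            f"ROI {roi.label}: no subunit-positive pixels, cannot validate", stacklevel=2
        )
        return False
    frac = int((sub & ankg_mask.pixels).sum()) / n_sub
    return frac >= min_overlap_fraction
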