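"""The AIS enrichment ratio and per-pair auxiliary ratios.

The reported statistic is the ratio of the two group means:
mean percent area over AIS ROIs divided by mean percent area over non-AIS
ROIs.  It is deliberately *not* the mean of per-pair ratios (Jensen gap on
skewed data); per-pair ratios are auxiliary output for distributional
summaries and the across-area ANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .particles import RoiClusterStats

__all__ = ["EnrichmentResult", "enrichment_ratio", "per_roi_enrichment"]


@dataclass
class EnrichmentResult:
    brain_area: str
    mean_percent_area_ais: float
    mean_percent_area_non_ais: float
    enrichment_ratio: float  # NaN when the non-AIS mean percent area is 0
    n_ais_rois: int
    n_non_ais_rois: int


def _mean_percent_area(stats: list[RoiClusterStats]) -> float:
    # percent_area is well-defined (0) for zero-puncta ROIs; only mean size
    # is missing there, so no listwise dropping happens here.
    vals = np.array([s.percent_area for s in stats], dtype=float)
    return float(np.nan_to_num(vals, nan=0.0).mean())


def enrichment_ratio(
    ais_stats: list[RoiClusterStats],
    non_ais_stats: list[RoiClusterStats],
    brain_area: str = "",
) -> EnrichmentResult:
    """Ratio of mean AIS percent area to mean non-AIS percent area.

    A zero non-AIS mean percent area signals a degenerate control region; the
    ratio is then reported missing (NaN) with a warning.
    """
    if not ais_stats or not non_ais_stats:
        raise ValueError("both ROI stat lists must be nonempty")
    m_ais = _mean_percent_area(ais_stats)
    m_non = _mean_percent_area(non_ais_stats)
    if m_non > 0:
        ratio = m_ais / m_non
    else:
        warnings.warn(
            f"non-AIS mean percent area is 0 in {brain_area or 'region'}; "
            "enrichment ratio undefined",
            stacklevel=2,
        )
        ratio = float("nan")
    return EnrichmentResult(brain_area, m_ais, m_non, ratio, len(ais_stats), len(non_ais_stats))


def per_roi_enrichment(
    paired_stats: list[tuple[RoiClusterStats, RoiClusterStats]],
) -> list[float]:
    """Per-pair percent-area ratios (AIS / non-AIS); NaN where non-AIS is 0."""
    out = []
    for ais, non in paired_stats:
        if non.percent_area > 0:
            out.append(ais.percent_area / non.percent_area)
        else:
            out.append(float("nan"))
    return out
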