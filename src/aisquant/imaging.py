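"""Shared data model for calibrated images, ROIs and binary masks, plus TIFF I/O.

Conventions: rasters are row-major with the origin at the top-left corner and
0-based (row, col) indices.  Regions of interest are exchanged as integer
label-mask TIFFs (0 = background, each positive label one ROI) plus a CSV
sidecar table mapping ``label -> location_class, brain_area, pair_id``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "Location",
    "CalibratedImage",
    "Roi",
    "RoiPair",
    "BinaryMask",
    "read_image",
    "write_image",
    "read_roi_labels",
    "write_roi_labels",
    "pair_rois",
    "load_roi_set",
]


class Location(str, enum.Enum):
    """Whether an ROI sits on an axon initial segment or in control neuropil."""

    AIS = "AIS"
    NON_AIS = "NON_AIS"


@dataclass
class CalibratedImage:
    """One channel's intensity raster with its physical pixel size.

    Parameters
    ----------
    pixels : ndarray, shape (H, W)
        Non-negative, finite intensities.  The dtype is preserved as stored;
        no rescaling is applied on read.
    pixel_size_nm : float
        Physical edge length of one pixel in nanometres (the study's native
        scale is ~64 nm/pixel).
    channel_label : str
        Free-text channel name, e.g. ``"alpha2"``, ``"AnkG"``, ``"Geph"``.
    """

    pixels: np.ndarray
    pixel_size_nm: float
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or 0 in self.pixels.shape:
            raise ValueError(
                f"expected a non-empty 2D raster, got shape {self.pixels.shape}"
            )
        if not self.pixel_size_nm > 0:
            raise ValueError(f"pixel_size_nm must be > 0, got {self.pixel_size_nm}")
        vals = self.pixels.astype(np.float64, copy=False)
        if not np.all(np.isfinite(vals)):
            raise ValueError("image intensities must be finite")
        if vals.min() < 0:
            raise ValueError("image intensities must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def um2_per_px(self) -> float:
        """Area of one pixel in square micrometres."""
        return (self.pixel_size_nm / 1000.0) ** 2


@dataclass
class Roi:
    """A region of interest given as a boolean mask congruent with its image."""

    mask: np.ndarray
    label: int
    location_class: Location
    brain_area: str = ""
    pair_id: int = -1

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2D")
        if not self.mask.any():
            raise ValueError(f"ROI {self.label} has an empty mask")
        self.location_class = Location(self.location_class)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def area_um2(self, pixel_size_nm: float) -> float:
        return self.n_pixels * (pixel_size_nm / 1000.0) ** 2


@dataclass
class RoiPair:
    """An AIS region and its congruent (equal-area, disjoint) non-AIS partner."""

    ais: Roi
    non_ais: Roi
    area_tolerance_px: int = 0

    def __post_init__(self) -> None:
        if self.ais.location_class is not Location.AIS:
            raise ValueError("RoiPair.ais must have location_class AIS")
        if self.non_ais.location_class is not Location.NON_AIS:
            raise ValueError("RoiPair.non_ais must have location_class NON_AIS")
        d = abs(self.ais.n_pixels - self.non_ais.n_pixels)
        if d > self.area_tolerance_px:
            raise ValueError(
                f"paired ROIs {self.ais.label}/{self.non_ais.label} differ by "
                f"{d} px (> tolerance {self.area_tolerance_px})"
            )
        if np.logical_and(self.ais.mask, self.non_ais.mask).any():
            raise ValueError(
                f"paired ROIs {self.ais.label}/{self.non_ais.label} overlap"
            )


@dataclass
class BinaryMask:
    """A boolean raster plus a record of how it was produced."""

    pixels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("binary mask must be 2D")


def read_image(path: str | Path, pixel_size_nm: float, channel_label: str = "") -> CalibratedImage:
    """Read a single-plane grayscale TIFF as a :class:`CalibratedImage`.

    Intensities are returned exactly as stored.  Multi-plane or RGB layouts
    raise ``ValueError``: the pipeline quantifies single optical sections.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ValueError(
            f"{path}: expected a single-plane grayscale image, got shape {arr.shape}"
        )
    return CalibratedImage(arr, pixel_size_nm, channel_label)


def write_image(img: CalibratedImage, path: str | Path) -> None:
    """Write the raster to TIFF, dtype preserved (lossless for integer data)."""
    tifffile.imwrite(Path(path), img.pixels)


def read_roi_labels(
    path: str | Path,
    location_class: dict[int, Location | str],
    brain_area: dict[int, str] | None = None,
    pair_id: dict[int, int] | None = None,
) -> list[Roi]:
    """Read an integer label-mask TIFF into one :class:`Roi` per positive label.

    Every label present in the mask must appear in ``location_class``;
    an unmapped label is an error (it would silently drop data otherwise).
    """
    arr = tifffile.imread(Path(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: label mask must be 2D, got shape {arr.shape}")
    labels = sorted(int(v) for v in np.unique(arr) if v > 0)
    missing = [v for v in labels if v not in location_class]
    if missing:
        raise ValueError(f"labels {missing} present in mask but absent from mapping")
    rois = []
    for lab in labels:
        rois.append(
            Roi(
                mask=arr == lab,
                label=lab,
                location_class=Location(location_class[lab]),
                brain_area=(brain_area or {}).get(lab, ""),
                pair_id=(pair_id or {}).get(lab, -1),
            )
        )
    return rois


def write_roi_labels(rois: list[Roi], mask_path: str | Path, sidecar_path: str | Path) -> None:
    """Write ROIs as a uint16 label mask plus the CSV sidecar table."""
    if not rois:
        raise ValueError("no ROIs to write")
    shape = rois[0].mask.shape
    out = np.zeros(shape, dtype=np.uint16)
    rows = []
    for roi in rois:
        if roi.mask.shape != shape:
            raise ValueError("ROIs have inconsistent shapes")
        if (out[roi.mask] != 0).any():
            raise ValueError(f"ROI {roi.label} overlaps a previously written ROI")
        out[roi.mask] = roi.label
        rows.append(
            {
                "label": roi.label,
                "location_class": roi.location_class.value,
                "brain_area": roi.brain_area,
                "pair_id": roi.pair_id,
            }
        )
    tifffile.imwrite(Path(mask_path), out)
    pd.DataFrame(rows).to_csv(sidecar_path, index=False)


def pair_rois(
    rois: list[Roi],
    pairing: dict[int, int],
    area_tolerance_px: int = 0,
) -> list[RoiPair]:
    """Pair AIS ROIs with their congruent non-AIS partners.

    ``pairing`` maps AIS label -> non-AIS label.  Congruence defaults to exact
    pixel-count equality; ``area_tolerance_px`` exists because rasterised
    translated contours can differ by aliasing.
    """
    by_label = {r.label: r for r in rois}
    pairs = []
    for ais_lab, non_lab in sorted(pairing.items()):
        for lab in (ais_lab, non_lab):
            if lab not in by_label:
                raise ValueError(f"pairing references unknown ROI label {lab}")
        pairs.append(
            RoiPair(by_label[ais_lab], by_label[non_lab], area_tolerance_px=area_tolerance_px)
        )
    return pairs


def load_roi_set(
    mask_path: str | Path,
    sidecar_path: str | Path,
    area_tolerance_px: int = 0,
) -> tuple[list[Roi], list[RoiPair]]:
    """Read a label mask + sidecar CSV and assemble validated ROI pairs.

    The sidecar has columns ``label, location_class, brain_area, pair_id``;
    the AIS and non-AIS member of each ``pair_id`` form one :class:`RoiPair`.
    """
    table = pd.read_csv(sidecar_path)
    loc = {int(r.label): Location(r.location_class) for r in table.itertuples()}
    area = {int(r.label): str(r.brain_area) for r in table.itertuples()}
    pid = {int(r.label): int(r.pair_id) for r in table.itertuples()}
    rois = read_roi_labels(mask_path, loc, area, pid)
    pairing: dict[int, int] = {}
    by_pair: dict[int, dict[Location, int]] = {}
    for roi in rois:
        if roi.pair_id >= 0:
            by_pair.setdefault(roi.pair_id, {})[roi.location_class] = roi.label
    for pid_, members in sorted(by_pair.items()):
        if set(members) == {Location.AIS, Location.NON_AIS}:
            pairing[members[Location.AIS]] = members[Location.NON_AIS]
    return rois, pair_rois(rois, pairing, area_tolerance_px=area_tolerance_px)
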