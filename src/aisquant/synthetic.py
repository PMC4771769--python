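"""Synthetic multi-channel fluorescence scenes with planted ground truth.

Every pipeline stage is testable without external data: scenes emulate the
study's raw material — axon-initial-segment (AIS) trajectories as smooth
random curves carrying subunit puncta in a "beads along a string" layout, an
ankyrin-G-like structural ribbon coextensive with each trajectory, a diffuse
non-AIS punctum field, partner channels (gephyrin / vGAT) apposed to a
Bernoulli subset of subunit puncta, and a background gradient with
Poisson + Gaussian read noise.

Layout uses a deterministic tile grid: each AIS trajectory occupies the upper
band of its tile and its congruent non-AIS ROI is the same pixel set
translated into the lower band, which only ever contains field puncta.  This
guarantees the congruence (equal pixel count) and disjointness invariants by
construction.

Puncta are placed by sequential spatial inhibition (minimum separation of
roughly one punctum diameter): receptor clusters are discrete objects that do
not interpenetrate, and this keeps planted counts recoverable at the
densities studied (a pure Poisson process would merge a substantial fraction
of neighbours at 40 per 100 um^2).

All randomness derives from ``config.seed`` through named substreams, so a
scene is a pure function of its config; knockout thinning uses its own
substream and therefore leaves every other channel bit-identical.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import ndimage as ndi
from scipy.interpolate import CubicSpline

from .imaging import CalibratedImage, Location, Roi, RoiPair, write_roi_labels, load_roi_set

__all__ = ["SceneConfig", "SceneGroundTruth", "Scene", "generate_scene", "generate_ko_scene", "write_scene", "read_scene"]

_PARTNER_LABELS = {"Geph", "vGAT"}
_STRUCT_LABEL = "AnkG"


@dataclass
class SceneConfig:
    """Parameters of one synthetic scene; defaults are the study conditions.

    The native raster matches the source imagery (64 nm/pixel); densities are
    clusters per 100 um^2, geometry in micrometres.  ``channels`` selects what
    to render: "AnkG" is the structural ribbon channel, "Geph"/"vGAT" are
    partner channels apposed to the first subunit channel, anything else is a
    subunit channel with its own independently placed puncta.
    """

    image_size_px: tuple[int, int] = (1024, 1024)
    pixel_size_nm: float = 64.0
    n_ais: int = 12
    ais_length_um: float = 16.0
    ais_width_um: float = 1.2
    ais_wiggle_um: float = 0.7
    bead_spacing_um: float | None = None  # overrides density-driven AIS placement
    ais_puncta_density_per_100um2: float = 30.0
    nonais_puncta_density_per_100um2: float = 10.0
    puncta_radius_um_mean: float = 0.25
    puncta_radius_um_sd: float = 0.04
    puncta_amplitude_mean: float = 120.0
    puncta_amplitude_sd: float = 25.0
    coloc_fraction_geph: float = 0.5
    coloc_fraction_vgat: float = 0.5
    coloc_fraction_ais: float | None = None  # per-location overrides
    coloc_fraction_nonais: float | None = None
    apposition_offset_um: float = 0.12
    partner_radius_scale: float = 0.8
    psf_sigma_um: float = 0.02
    ankg_amplitude: float = 100.0
    background_level: float = 12.0
    background_gradient_amplitude: float = 8.0
    poisson_noise: bool = True
    gaussian_read_sd: float = 2.0
    #: minimum in-ROI footprint for a planted punctum to count toward that
    #: ROI's true density — the field-standard minimum quantifiable area,
    #: matching the particle filter's default lower gate
    min_footprint_um2: float = 0.05
    channels: tuple[str, ...] = ("alpha2", "AnkG")
    brain_area: str = "BLA"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        for name in (
            "ais_puncta_density_per_100um2",
            "nonais_puncta_density_per_100um2",
            "puncta_radius_um_mean",
            "puncta_amplitude_mean",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("coloc_fraction_geph", "coloc_fraction_vgat"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        self.channels = tuple(self.channels)

    @property
    def px_um(self) -> float:
        return self.pixel_size_nm / 1000.0

    def subunit_labels(self) -> list[str]:
        return [c for c in self.channels if c != _STRUCT_LABEL and c not in _PARTNER_LABELS]

    def coloc_fraction(self, partner: str) -> float:
        return self.coloc_fraction_geph if partner == "Geph" else self.coloc_fraction_vgat


@dataclass
class SceneGroundTruth:
    """Planted parameters of a scene, recorded before noise."""

    puncta: pd.DataFrame  # channel, punctum_id, row_px, col_px, radius_um, amplitude, on_ais, pair_id, partner_of
    roi_table: pd.DataFrame  # label, location_class, brain_area, pair_id
    roi_truth: pd.DataFrame  # channel, roi_label, location_class, pair_id, n_puncta, density, mean_size, percent_area
    true_enrichment_ratio: float  # config-level: AIS / non-AIS planted density ratio
    realized_enrichment_ratio: dict[str, float]  # per subunit channel, from rasterised coverage
    coloc_fractions: dict[str, float]


@dataclass
class Scene:
    channels: dict[str, CalibratedImage]
    rois: list[Roi]
    pairs: list[RoiPair]
    truth: SceneGroundTruth
    config: SceneConfig


def _rng(seed: int, key: str) -> np.random.Generator:
    """Named, platform-stable substream of the scene seed."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(key.encode())])


# --------------------------------------------------------------------------
# geometry


@dataclass
class _Trajectory:
    pair_id: int
    points_px: np.ndarray  # (N, 2) float (row, col) along the curve
    tangents: np.ndarray  # (N, 2) unit tangents
    arclength_um: np.ndarray  # cumulative, same length
    ais_mask: np.ndarray
    non_ais_mask: np.ndarray


def _layout_grid(cfg: SceneConfig) -> tuple[int, int, float, float]:
    h_um = cfg.image_size_px[0] * cfg.px_um
    w_um = cfg.image_size_px[1] * cfg.px_um
    cols = max(1, int(w_um // (cfg.ais_length_um + 4.0)))
    rows = int(np.ceil(cfg.n_ais / cols))
    tile_w, tile_h = w_um / cols, h_um / rows
    band = cfg.ais_wiggle_um + cfg.ais_width_um / 2.0 + 0.5
    if rows * cols < cfg.n_ais or tile_w < cfg.ais_length_um + 2.0 or tile_h / 4.0 < band:
        raise ValueError(
            f"infeasible placement: {cfg.n_ais} AIS of {cfg.ais_length_um} um do not fit "
            f"a {w_um:.0f}x{h_um:.0f} um field with congruent non-AIS copies"
        )
    return rows, cols, tile_w, tile_h


def _make_trajectory(cfg: SceneConfig, rng: np.random.Generator, pair_id: int,
                     tile_rc: tuple[int, int], tile_wh: tuple[float, float]) -> _Trajectory:
    tile_w, tile_h = tile_wh
    x0 = tile_rc[1] * tile_w + (tile_w - cfg.ais_length_um) / 2.0
    y_center = tile_rc[0] * tile_h + tile_h / 4.0
    n_way = 5
    xs = x0 + np.linspace(0.0, cfg.ais_length_um, n_way)
    ys = y_center + rng.uniform(-cfg.ais_wiggle_um, cfg.ais_wiggle_um, n_way)
    spline = CubicSpline(xs, ys)
    x_dense = np.arange(xs[0], xs[-1], 0.25 * cfg.px_um)
    y_dense = spline(x_dense)
    dy = spline(x_dense, 1)
    pts = np.column_stack([y_dense / cfg.px_um, x_dense / cfg.px_um])  # (row, col)
    tang = np.column_stack([dy, np.ones_like(dy)])
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    seg = np.hypot(np.diff(x_dense, prepend=x_dense[0]), np.diff(y_dense, prepend=y_dense[0]))
    arclen = np.cumsum(seg)

    h, w = cfg.image_size_px
    half_w_px = (cfg.ais_width_um / 2.0) / cfg.px_um
    pad = int(np.ceil(half_w_px)) + 2
    r_int = np.round(pts[:, 0]).astype(int)
    c_int = np.round(pts[:, 1]).astype(int)
    r0, r1 = r_int.min() - pad, r_int.max() + pad + 1
    c0, c1 = c_int.min() - pad, c_int.max() + pad + 1
    local = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    local[r_int - r0, c_int - c0] = True
    ribbon_local = ndi.distance_transform_edt(~local) <= half_w_px
    ais = np.zeros((h, w), dtype=bool)
    ais[r0:r1, c0:c1] = ribbon_local

    dy_px = int(round((tile_h / 2.0) / cfg.px_um))
    if r0 < 0 or r1 + dy_px > h or c0 < 0 or c1 > w:
        raise ValueError(
            "infeasible placement: ribbon or its translated non-AIS copy leaves the image"
        )
    non = np.zeros_like(ais)
    non[r0 + dy_px : r1 + dy_px, c0:c1] = ribbon_local
    return _Trajectory(pair_id, pts, tang, arclen, ais, non)


# --------------------------------------------------------------------------
# punctum placement


def _sequential_inhibition(
    rng: np.random.Generator,
    allowed: np.ndarray,
    n_target: int,
    min_sep_px: float,
) -> np.ndarray:
    """Uniform points in ``allowed`` with a hard minimum separation."""
    h, w = allowed.shape
    if n_target == 0:
        return np.empty((0, 2))
    cell = max(min_sep_px, 1.0)
    grid: dict[tuple[int, int], list[tuple[float, float]]] = {}
    accepted: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = 60 * n_target
    while len(accepted) < n_target and attempts < max_attempts:
        attempts += 1
        r = rng.uniform(0, h - 1)
        c = rng.uniform(0, w - 1)
        if not allowed[int(round(r)), int(round(c))]:
            continue
        key = (int(r // cell), int(c // cell))
        ok = True
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                for (pr, pc) in grid.get((key[0] + dr, key[1] + dc), ()):
                    if (pr - r) ** 2 + (pc - c) ** 2 < min_sep_px**2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            accepted.append((r, c))
            grid.setdefault(key, []).append((r, c))
    if len(accepted) < n_target:
        warnings.warn(
            f"sequential inhibition placed {len(accepted)}/{n_target} puncta "
            "(packing limit reached)",
            stacklevel=2,
        )
    return np.array(accepted)


def _draw_radius_amp(cfg: SceneConfig, rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    radius = rng.normal(cfg.puncta_radius_um_mean, cfg.puncta_radius_um_sd, n)
    radius = np.clip(radius, 0.6 * cfg.puncta_radius_um_mean, 2.5 * cfg.puncta_radius_um_mean)
    amp = rng.normal(cfg.puncta_amplitude_mean, cfg.puncta_amplitude_sd, n)
    amp = np.clip(amp, 0.25 * cfg.puncta_amplitude_mean, None)
    return radius, amp


def _place_subunit(
    cfg: SceneConfig,
    label: str,
    trajectories: list[_Trajectory],
    allowed_field: np.ndarray,
) -> pd.DataFrame:
    """AIS beads along each trajectory plus a field of non-AIS puncta."""
    rng = _rng(cfg.seed, f"place:{label}")
    rows = []
    pid = 0
    min_sep_um = 2.0 * (cfg.puncta_radius_um_mean + 2.0 * cfg.puncta_radius_um_sd)
    for traj in trajectories:
        roi_area_um2 = traj.ais_mask.sum() * cfg.px_um**2
        total_len = traj.arclength_um[-1]
        if cfg.bead_spacing_um:
            n = int(total_len // cfg.bead_spacing_um)
        else:
            lam = cfg.ais_puncta_density_per_100um2 * roi_area_um2 / 100.0
            n = int(rng.poisson(lam))
        n = min(n, max(int(total_len // min_sep_um), 0))
        if n == 0:
            continue
        spacing = total_len / n
        radius, amp = _draw_radius_amp(cfg, rng, n)
        lateral_cap = max(cfg.ais_width_um / 2.0 - cfg.puncta_radius_um_mean, 0.05)
        for k in range(n):
            s = (k + 0.5) * spacing + rng.uniform(-0.2, 0.2) * spacing
            s = float(np.clip(s, 0.0, total_len - 1e-9))
            idx = int(np.searchsorted(traj.arclength_um, s))
            idx = min(idx, len(traj.points_px) - 1)
            normal = np.array([-traj.tangents[idx, 1], traj.tangents[idx, 0]])
            lat = rng.uniform(-lateral_cap, lateral_cap)
            pos = traj.points_px[idx] + normal * (lat / cfg.px_um)
            rows.append(
                dict(channel=label, punctum_id=pid, row_px=pos[0], col_px=pos[1],
                     radius_um=radius[k], amplitude=amp[k], on_ais=True,
                     pair_id=traj.pair_id, partner_of=-1, bead_index=k)
            )
            pid += 1
    # diffuse field everywhere outside the AIS ribbons
    area_um2 = allowed_field.sum() * cfg.px_um**2
    n_field = int(rng.poisson(cfg.nonais_puncta_density_per_100um2 * area_um2 / 100.0))
    pts = _sequential_inhibition(rng, allowed_field, n_field, min_sep_um / cfg.px_um)
    radius, amp = _draw_radius_amp(cfg, rng, len(pts))
    for k, (r, c) in enumerate(pts):
        rows.append(
            dict(channel=label, punctum_id=pid, row_px=r, col_px=c,
                 radius_um=radius[k], amplitude=amp[k], on_ais=False,
                 pair_id=-1, partner_of=-1, bead_index=-1)
        )
        pid += 1
    return pd.DataFrame(rows, columns=["channel", "punctum_id", "row_px", "col_px",
                                       "radius_um", "amplitude", "on_ais", "pair_id",
                                       "partner_of", "bead_index"])


def _place_partner(
    cfg: SceneConfig,
    partner: str,
    host: pd.DataFrame,
    allowed_field: np.ndarray,
) -> pd.DataFrame:
    """Apposed partner puncta for a Bernoulli subset of host puncta, plus an
    independent diffuse field of the partner's own."""
    rng = _rng(cfg.seed, f"partner:{partner}")
    rows = []
    pid = 0
    base = cfg.coloc_fraction(partner)
    frac_ais = base if cfg.coloc_fraction_ais is None else cfg.coloc_fraction_ais
    frac_non = base if cfg.coloc_fraction_nonais is None else cfg.coloc_fraction_nonais
    off_px = cfg.apposition_offset_um / cfg.px_um
    for rec in host.itertuples():
        frac = frac_ais if rec.on_ais else frac_non
        if rng.uniform() >= frac:
            continue
        if rec.on_ais and rec.bead_index >= 0:
            # apposition alternates sides along the trajectory ("spiraling" in 2D)
            angle = rng.uniform(-0.4, 0.4)
            side = 1.0 if rec.bead_index % 2 == 0 else -1.0
            direction = np.array([side * np.cos(angle), np.sin(angle)])
        else:
            theta = rng.uniform(0, 2 * np.pi)
            direction = np.array([np.cos(theta), np.sin(theta)])
        pos = np.array([rec.row_px, rec.col_px]) + direction * off_px
        radius = max(rec.radius_um * cfg.partner_radius_scale, 0.08)
        amp = np.clip(rng.normal(cfg.puncta_amplitude_mean, cfg.puncta_amplitude_sd),
                      0.25 * cfg.puncta_amplitude_mean, None)
        rows.append(
            dict(channel=partner, punctum_id=pid, row_px=pos[0], col_px=pos[1],
                 radius_um=radius, amplitude=amp, on_ais=bool(rec.on_ais),
                 pair_id=rec.pair_id, partner_of=rec.punctum_id, bead_index=-1)
        )
        pid += 1
    area_um2 = allowed_field.sum() * cfg.px_um**2
    min_sep_um = 2.0 * (cfg.puncta_radius_um_mean + 2.0 * cfg.puncta_radius_um_sd)
    n_field = int(rng.poisson(cfg.nonais_puncta_density_per_100um2 * area_um2 / 100.0))
    pts = _sequential_inhibition(rng, allowed_field, n_field, min_sep_um / cfg.px_um)
    radius, amp = _draw_radius_amp(cfg, rng, len(pts))
    for k, (r, c) in enumerate(pts):
        rows.append(
            dict(channel=partner, punctum_id=pid, row_px=r, col_px=c,
                 radius_um=radius[k] * cfg.partner_radius_scale, amplitude=amp[k],
                 on_ais=False, pair_id=-1, partner_of=-1, bead_index=-1)
        )
        pid += 1
    return pd.DataFrame(rows, columns=host.columns)


# --------------------------------------------------------------------------
# rendering


def _stamp_discs(frame: np.ndarray, puncta: pd.DataFrame, px_um: float,
                 binary: bool = False) -> None:
    h, w = frame.shape
    for rec in puncta.itertuples():
        r_px = rec.radius_um / px_um
        rad = int(np.ceil(r_px)) + 1
        rc, cc = rec.row_px, rec.col_px
        r0, r1 = int(np.floor(rc)) - rad, int(np.floor(rc)) + rad + 1
        c0, c1 = int(np.floor(cc)) - rad, int(np.floor(cc)) + rad + 1
        r0c, r1c = max(r0, 0), min(r1, h)
        c0c, c1c = max(c0, 0), min(c1, w)
        if r0c >= r1c or c0c >= c1c:
            continue
        yy, xx = np.mgrid[r0c:r1c, c0c:c1c]
        disc = (yy - rc) ** 2 + (xx - cc) ** 2 <= r_px**2
        if binary:
            frame[r0c:r1c, c0c:c1c] |= disc
        else:
            frame[r0c:r1c, c0c:c1c] += np.where(disc, rec.amplitude, 0.0)


def _render_channel(cfg: SceneConfig, label: str, puncta: pd.DataFrame,
                    ribbon_union: np.ndarray) -> CalibratedImage:
    h, w = cfg.image_size_px
    yy, xx = np.mgrid[0:h, 0:w]
    ramp = (xx / max(w - 1, 1) + yy / max(h - 1, 1)) / 2.0
    img = cfg.background_level + cfg.background_gradient_amplitude * ramp
    if label == _STRUCT_LABEL:
        img = img + np.where(ribbon_union, cfg.ankg_amplitude, 0.0)
    else:
        _stamp_discs(img, puncta, cfg.px_um)
    sigma_px = cfg.psf_sigma_um / cfg.px_um
    if sigma_px > 0:
        img = ndi.gaussian_filter(img, sigma_px)
    rng = _rng(cfg.seed, f"noise:{label}")
    if cfg.poisson_noise:
        img = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
    if cfg.gaussian_read_sd > 0:
        img = img + rng.normal(0.0, cfg.gaussian_read_sd, img.shape)
    img = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    return CalibratedImage(img, cfg.pixel_size_nm, label)


# --------------------------------------------------------------------------
# ground truth bookkeeping


def _roi_truth(cfg: SceneConfig, label: str, puncta: pd.DataFrame,
               rois: list[Roi]) -> list[dict]:
    """Per-ROI planted truth for one channel, recorded before noise.

    ``n_puncta`` counts puncta whose rasterised footprint overlaps the ROI by
    at least ``min_footprint_um2`` (puncta below the minimum quantifiable
    area in an ROI are not observables of that ROI); ``n_centered`` counts by
    punctum centre, and mean size is the planted area pi*r^2 of the centred
    puncta.
    """
    h, w = cfg.image_size_px
    coverage = np.zeros((h, w), dtype=bool)
    _stamp_discs(coverage, puncta, cfg.px_um, binary=True)
    label_raster = np.zeros((h, w), dtype=np.int32)
    for roi in rois:
        label_raster[roi.mask] = roi.label
    min_px = max(int(np.ceil(cfg.min_footprint_um2 / cfg.px_um**2)), 1)

    footprint_counts: dict[int, int] = {roi.label: 0 for roi in rois}
    centered: dict[int, list[float]] = {roi.label: [] for roi in rois}
    for rec in puncta.itertuples():
        r_px = rec.radius_um / cfg.px_um
        rad = int(np.ceil(r_px)) + 1
        r0 = max(int(np.floor(rec.row_px)) - rad, 0)
        r1 = min(int(np.floor(rec.row_px)) + rad + 1, h)
        c0 = max(int(np.floor(rec.col_px)) - rad, 0)
        c1 = min(int(np.floor(rec.col_px)) + rad + 1, w)
        if r0 >= r1 or c0 >= c1:
            continue
        yy, xx = np.mgrid[r0:r1, c0:c1]
        disc = (yy - rec.row_px) ** 2 + (xx - rec.col_px) ** 2 <= r_px**2
        labs, counts = np.unique(label_raster[r0:r1, c0:c1][disc], return_counts=True)
        for lab, cnt in zip(labs, counts):
            if lab > 0 and cnt >= min_px:
                footprint_counts[int(lab)] += 1
        rc = int(np.clip(round(rec.row_px), 0, h - 1))
        cc = int(np.clip(round(rec.col_px), 0, w - 1))
        center_lab = int(label_raster[rc, cc])
        if center_lab > 0:
            centered[center_lab].append(float(np.pi * rec.radius_um**2))

    rows = []
    for roi in rois:
        area = roi.area_um2(cfg.pixel_size_nm)
        sizes = centered[roi.label]
        rows.append(
            dict(channel=label, roi_label=roi.label,
                 location_class=roi.location_class.value, pair_id=roi.pair_id,
                 n_puncta=footprint_counts[roi.label],
                 n_centered=len(sizes),
                 density_per_100um2=footprint_counts[roi.label] / area * 100.0,
                 mean_size_um2=float(np.mean(sizes)) if sizes else float("nan"),
                 percent_area=100.0 * float((coverage & roi.mask).sum()) / roi.n_pixels)
        )
    return rows


# --------------------------------------------------------------------------
# public API


def generate_scene(config: SceneConfig) -> Scene:
    """Generate a scene and its ground-truth ledger (pure function of config)."""
    cfg = config
    rows_, cols_, tile_w, tile_h = _layout_grid(cfg)
    rng_geom = _rng(cfg.seed, "geometry")
    trajectories = []
    for i in range(cfg.n_ais):
        tile = (i // cols_, i % cols_)
        trajectories.append(_make_trajectory(cfg, rng_geom, i, tile, (tile_w, tile_h)))

    h, w = cfg.image_size_px
    ribbon_union = np.zeros((h, w), dtype=bool)
    for t in trajectories:
        ribbon_union |= t.ais_mask
    margin_px = max(int(np.ceil(0.5 / cfg.px_um)), 1)
    allowed_field = ndi.distance_transform_edt(~ribbon_union) > margin_px

    rois: list[Roi] = []
    for t in trajectories:
        rois.append(Roi(t.ais_mask, 2 * t.pair_id + 1, Location.AIS,
                        cfg.brain_area, t.pair_id))
        rois.append(Roi(t.non_ais_mask, 2 * t.pair_id + 2, Location.NON_AIS,
                        cfg.brain_area, t.pair_id))
    pairs = [RoiPair(rois[2 * i], rois[2 * i + 1]) for i in range(cfg.n_ais)]

    subunits = cfg.subunit_labels()
    placed: dict[str, pd.DataFrame] = {}
    for lab in subunits:
        placed[lab] = _place_subunit(cfg, lab, trajectories, allowed_field)
    host = placed[subunits[0]] if subunits else pd.DataFrame()
    for lab in cfg.channels:
        if lab in _PARTNER_LABELS:
            placed[lab] = _place_partner(cfg, lab, host, allowed_field)

    return _assemble(cfg, placed, rois, pairs, ribbon_union)


def generate_ko_scene(config: SceneConfig, ko_channel: str, residual_fraction: float) -> Scene:
    """Scene with one channel's planted puncta thinned to ``residual_fraction``.

    Emulates a subunit knockout: the named channel keeps each punctum
    independently with probability ``residual_fraction``; every other channel
    is bit-identical to :func:`generate_scene` at the same seed.
    """
    if not 0 <= residual_fraction <= 1:
        raise ValueError("residual_fraction must lie in [0, 1]")
    if ko_channel not in config.channels or ko_channel == _STRUCT_LABEL:
        raise ValueError(f"unknown or non-punctate KO channel {ko_channel!r}")
    scene = generate_scene(config)
    puncta = scene.truth.puncta
    sub = puncta[puncta["channel"] == ko_channel]
    rng = _rng(config.seed, f"thin:{ko_channel}")
    keep_ids = set(sub.loc[rng.uniform(size=len(sub)) < residual_fraction, "punctum_id"])
    placed = {
        lab: puncta[puncta["channel"] == lab].copy()
        for lab in config.channels
        if lab != _STRUCT_LABEL
    }
    placed[ko_channel] = placed[ko_channel][placed[ko_channel]["punctum_id"].isin(keep_ids)]
    ribbon_union = np.zeros(config.image_size_px, dtype=bool)
    for roi in scene.rois:
        if roi.location_class is Location.AIS:
            ribbon_union |= roi.mask
    return _assemble(config, placed, scene.rois, scene.pairs, ribbon_union)


def _assemble(cfg: SceneConfig, placed: dict[str, pd.DataFrame], rois: list[Roi],
              pairs: list[RoiPair], ribbon_union: np.ndarray) -> Scene:
    channels = {}
    for lab in cfg.channels:
        channels[lab] = _render_channel(cfg, lab, placed.get(lab, pd.DataFrame()),
                                        ribbon_union)
    truth_rows: list[dict] = []
    realized: dict[str, float] = {}
    for lab in cfg.subunit_labels():
        rows = _roi_truth(cfg, lab, placed[lab], rois)
        truth_rows.extend(rows)
        ais = [r["percent_area"] for r in rows if r["location_class"] == "AIS"]
        non = [r["percent_area"] for r in rows if r["location_class"] == "NON_AIS"]
        if ais and non and np.mean(non) > 0:
            realized[lab] = float(np.mean(ais) / np.mean(non))
        else:
            realized[lab] = float("nan")
    frames = [df for df in placed.values() if len(df)]
    puncta = (pd.concat(frames, ignore_index=True) if frames
              else next(iter(placed.values())) if placed else pd.DataFrame())
    if cfg.nonais_puncta_density_per_100um2 > 0:
        true_ratio = cfg.ais_puncta_density_per_100um2 / cfg.nonais_puncta_density_per_100um2
    else:
        true_ratio = float("nan")
    truth = SceneGroundTruth(
        puncta=puncta,
        roi_table=pd.DataFrame(
            [dict(label=r.label, location_class=r.location_class.value,
                  brain_area=r.brain_area, pair_id=r.pair_id) for r in rois]
        ),
        roi_truth=pd.DataFrame(truth_rows),
        true_enrichment_ratio=true_ratio,
        realized_enrichment_ratio=realized,
        coloc_fractions={"Geph": cfg.coloc_fraction_geph, "vGAT": cfg.coloc_fraction_vgat},
    )
    return Scene(channels, rois, pairs, truth, cfg)


# --------------------------------------------------------------------------
# persistence


def write_scene(scene: Scene, directory: str | Path) -> dict[str, int]:
    """Write channels (TIFF), ROI label mask + sidecar, truth tables and config.

    Returns the per-channel pixel sums recorded in ``truth.json`` (used to
    verify lossless round trips).  Two runs with the same seed produce
    byte-identical files.
    """
    directory = Path(directory)
    (directory / "channels").mkdir(parents=True, exist_ok=True)
    sums = {}
    for lab, img in scene.channels.items():
        tifffile.imwrite(directory / "channels" / f"{lab}.tif", img.pixels)
        sums[lab] = int(img.pixels.astype(np.uint64).sum())
    write_roi_labels(scene.rois, directory / "roi_labels.tif", directory / "rois.csv")
    scene.truth.puncta.to_csv(directory / "puncta.csv", index=False, float_format="%.6g")
    scene.truth.roi_truth.to_csv(directory / "roi_truth.csv", index=False, float_format="%.6g")
    with open(directory / "truth.json", "w") as fh:
        json.dump(
            {
                "true_enrichment_ratio": scene.truth.true_enrichment_ratio,
                "realized_enrichment_ratio": scene.truth.realized_enrichment_ratio,
                "coloc_fractions": scene.truth.coloc_fractions,
                "pixel_sums": sums,
            },
            fh, indent=2, sort_keys=True, allow_nan=True,
        )
    cfg = asdict(scene.config)
    cfg["image_size_px"] = list(cfg["image_size_px"])
    cfg["channels"] = list(cfg["channels"])
    with open(directory / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return sums


def read_scene(directory: str | Path) -> tuple[dict[str, CalibratedImage], list[Roi], list[RoiPair], dict]:
    """Re-read a written scene: channels, validated ROI pairs, truth scalars."""
    directory = Path(directory)
    with open(directory / "config.yaml") as fh:
        cfg = yaml.safe_load(fh)
    channels = {}
    for tif in sorted((directory / "channels").glob("*.tif")):
        arr = tifffile.imread(tif)
        channels[tif.stem] = CalibratedImage(arr, cfg["pixel_size_nm"], tif.stem)
    rois, pairs = load_roi_set(directory / "roi_labels.tif", directory / "rois.csv")
    with open(directory / "truth.json") as fh:
        truth = json.load(fh)
    return channels, rois, pairs, truth
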