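"""Reusable in-silico experiment protocols over the synthetic scenes.

These functions define the desk-scale study conditions used throughout the
validation suite, the analysis drivers and the acceptance script: scenes are
rasterised at 128 nm/pixel (half the native sampling) with the rolling-ball
radius scaled to 25 px so the physical ball stays 3.2 um, and fields sized to
hold 50 congruent ROI pairs.  Problem sizes are documented in
docs/methods.md; every protocol is a pure function of its seed.
"""

from __future__ import annotations

import numpy as np

from .enrichment import enrichment_ratio
from .imaging import Location
from .particles import quantify_roi
from .preprocess import rolling_ball_subtract, triangle_threshold
from .synthetic import Scene, SceneConfig, generate_ko_scene, generate_scene

__all__ = [
    "DESK_ROLLING_BALL_RADIUS_PX",
    "desk_config",
    "quantify_scene",
    "measure_enrichment",
    "enrichment_recovery",
    "density_size_recovery",
    "ko_experiment",
    "coloc_m1_curve",
]

#: rolling-ball radius matching the native radius-50 ball (3.2 um) at 128 nm/px
DESK_ROLLING_BALL_RADIUS_PX = 25


def desk_config(**overrides) -> SceneConfig:
    """Desk-scale scene: 102 x 82 um at 128 nm/px, 50 congruent ROI pairs."""
    params = dict(
        image_size_px=(800, 640),
        pixel_size_nm=128.0,
        n_ais=50,
        ais_length_um=16.0,
        ais_width_um=1.6,
        ais_wiggle_um=0.5,
        channels=("alpha2",),
    )
    params.update(overrides)
    return SceneConfig(**params)


def quantify_scene(scene: Scene, radius_px: int = DESK_ROLLING_BALL_RADIUS_PX,
                   channel: str | None = None):
    """Rolling ball + triangle threshold + particle stats for every ROI.

    Returns (ais_stats, non_ais_stats) lists ordered like the scene's ROIs.
    """
    label = channel or scene.config.subunit_labels()[0]
    sub = rolling_ball_subtract(scene.channels[label], radius_px)
    thr = triangle_threshold(sub)
    ais, non = [], []
    for roi in scene.rois:
        s = quantify_roi(thr.mask, roi, scene.config.pixel_size_nm)
        (ais if roi.location_class is Location.AIS else non).append(s)
    return ais, non


def measure_enrichment(scene: Scene, radius_px: int = DESK_ROLLING_BALL_RADIUS_PX) -> float:
    ais, non = quantify_scene(scene, radius_px)
    return enrichment_ratio(ais, non).enrichment_ratio


def enrichment_recovery(true_ratio: float, seed: int,
                        nonais_density: float = 10.0) -> tuple[float, float]:
    """One replicate of the ratio-recovery experiment.

    Plants AIS density ``true_ratio x nonais_density`` with equal size
    distributions, runs the full pipeline, and returns (measured ratio,
    planted ratio).
    """
    cfg = desk_config(
        ais_puncta_density_per_100um2=true_ratio * nonais_density,
        nonais_puncta_density_per_100um2=nonais_density,
        seed=seed,
    )
    return measure_enrichment(generate_scene(cfg)), true_ratio


def density_size_recovery(seed: int, noise: bool, ais_density: float = 30.0,
                          nonais_density: float = 10.0) -> dict[str, float]:
    """Recovery of planted per-ROI density and mean punctum size.

    ``noise=False`` is the noise-light regime (no shot/read noise, flat
    background, no residual blur); ``noise=True`` uses the full rendering
    model.  Errors are percentages relative to the planted (realised) truth,
    pooled over AIS ROIs for density and size and over non-AIS ROIs for the
    field density.
    """
    kw = {} if noise else dict(poisson_noise=False, gaussian_read_sd=0.0,
                               background_gradient_amplitude=0.0, psf_sigma_um=0.0)
    cfg = desk_config(ais_puncta_density_per_100um2=ais_density,
                      nonais_puncta_density_per_100um2=nonais_density,
                      seed=seed, **kw)
    scene = generate_scene(cfg)
    ais, non = quantify_scene(scene)
    tt = scene.truth.roi_truth
    t_ais = tt[tt.location_class == "AIS"]
    t_non = tt[tt.location_class == "NON_AIS"]

    def pct_err(measured, truth):
        return float(abs(measured - truth) / truth * 100.0)

    return {
        "ais_density_err_pct": pct_err(np.mean([s.density for s in ais]),
                                       t_ais.density_per_100um2.mean()),
        "nonais_density_err_pct": pct_err(np.mean([s.density for s in non]),
                                          t_non.density_per_100um2.mean()),
        "size_err_pct": pct_err(np.nanmean([s.mean_size_um2 for s in ais]),
                                t_ais.mean_size_um2.mean()),
    }


def ko_experiment(seed: int, residual_fraction: float = 0.05) -> dict[str, float]:
    """Knockout scenario: thin one subunit channel, leave its sibling alone.

    Returns the percent change of measured AIS density in the thinned channel
    and in the untouched bystander channel, each relative to the control
    scene at the same seed.
    """
    cfg = desk_config(channels=("alpha2", "alpha3"), seed=seed)
    control = generate_scene(cfg)
    ko = generate_ko_scene(cfg, "alpha2", residual_fraction)

    def ais_density(scene, label):
        ais, _ = quantify_scene(scene, channel=label)
        return float(np.mean([s.density for s in ais]))

    ctrl_a, ctrl_b = ais_density(control, "alpha2"), ais_density(control, "alpha3")
    ko_a, ko_b = ais_density(ko, "alpha2"), ais_density(ko, "alpha3")
    return {
        "ko_change_pct": (ko_a - ctrl_a) / ctrl_a * 100.0,
        "bystander_change_pct": (ko_b - ctrl_b) / ctrl_b * 100.0,
    }


def coloc_m1_curve(fractions, seeds, image_size_px=(256, 256)) -> dict[float, float]:
    """Mean binary M1 (subunit vs partner) as a function of the planted
    per-punctum colocalization probability."""
    from .coloc import manders_binary

    out = {}
    for frac in fractions:
        vals = []
        for seed in seeds:
            cfg = SceneConfig(
                image_size_px=image_size_px, pixel_size_nm=128.0, n_ais=2,
                ais_length_um=12.0, ais_width_um=1.6, ais_wiggle_um=0.5,
                ais_puncta_density_per_100um2=30.0,
                nonais_puncta_density_per_100um2=10.0,
                channels=("alpha2", "Geph"), coloc_fraction_geph=frac, seed=seed,
            )
            scene = generate_scene(cfg)
            thr_a = triangle_threshold(
                rolling_ball_subtract(scene.channels["alpha2"], DESK_ROLLING_BALL_RADIUS_PX))
            thr_b = triangle_threshold(
                rolling_ball_subtract(scene.channels["Geph"], DESK_ROLLING_BALL_RADIUS_PX))
            for roi in scene.rois:
                m1, _ = manders_binary(thr_a.mask, thr_b.mask, roi)
                if np.isfinite(m1):
                    vals.append(m1)
        out[frac] = float(np.mean(vals))
    return out
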