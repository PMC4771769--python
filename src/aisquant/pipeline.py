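"""Orchestration: configured end-to-end runs producing tabular outputs.

A run is driven by a YAML config (or an equivalent dict).  All tabular output
is CSV (UTF-8, '.' decimal, header row) with fixed ``%.6g`` float formatting,
so reruns of the same manifest are byte-identical.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coloc import manders_binary, pearson_roi
from .enrichment import enrichment_ratio, per_roi_enrichment
from .imaging import CalibratedImage, Location, Roi, RoiPair, load_roi_set, read_image
from .particles import DEFAULT_AREA_GATE_UM2, DEFAULT_CIRC_GATE, quantify_roi
from .preprocess import costes_auto_threshold, rolling_ball_subtract, triangle_threshold
from .stats import bonferroni_planned, bonferroni_t_tests, one_way_anova, tukey_kramer, two_way_anova
from .synthetic import read_scene

__all__ = ["DEFAULTS", "load_config", "run_quantify", "run_coloc", "run_stats"]

log = logging.getLogger("aisquant")

DEFAULTS: dict = {
    "pixel_size_nm": 64.0,
    "channels": None,  # None -> every non-structural, non-partner channel
    "preprocess": {
        "rolling_ball_radius_px": 50,
        "threshold_method": "triangle",  # triangle | fixed
        "fixed_threshold": None,
    },
    "particles": {
        "connectivity": 8,
        "area_gate_um2": list(DEFAULT_AREA_GATE_UM2),
        "circ_gate": list(DEFAULT_CIRC_GATE),
        "density_per_area_um2": 100.0,
    },
    "coloc": {
        "channel_a": None,
        "channel_b": None,
        "pearson_thresholds": "costes",  # costes | none | [ta, tb]
    },
    "alpha": 0.05,
    "out_dir": None,
    "seed": 0,
}

_AUX_CHANNELS = {"AnkG", "Geph", "vGAT"}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            out[k] = _merge(base[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path) -> dict:
    """Read a YAML run config and merge it over the documented defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(DEFAULTS, user)


def _load_inputs(config: dict) -> tuple[dict[str, CalibratedImage], list[Roi], list[RoiPair]]:
    if config.get("scene_dir"):
        channels, rois, pairs, _ = read_scene(config["scene_dir"])
        return channels, rois, pairs
    images = config.get("images")
    if not images:
        raise ValueError("config needs either scene_dir or an images mapping")
    px = float(config["pixel_size_nm"])
    channels = {lab: read_image(p, px, lab) for lab, p in images.items()}
    rois, pairs = load_roi_set(config["roi_mask"], config["roi_sidecar"])
    return channels, rois, pairs


def _binarize(img: CalibratedImage, config: dict):
    pp = config["preprocess"]
    sub = rolling_ball_subtract(img, int(pp["rolling_ball_radius_px"]))
    if pp["threshold_method"] == "fixed":
        from .imaging import BinaryMask
        from .preprocess import ThresholdMethod, ThresholdResult

        thr = float(pp["fixed_threshold"])
        return sub, ThresholdResult(
            thr, ThresholdMethod.FIXED,
            BinaryMask(sub.pixels.astype(np.float64) > thr, {"method": "FIXED"}),
        )
    return sub, triangle_threshold(sub)


def _write_tables(tables: dict[str, pd.DataFrame], config: dict) -> None:
    out_dir = config.get("out_dir")
    if not out_dir:
        return
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False, float_format="%.6g")
    manifest = {"config": {k: v for k, v in config.items() if k != "out_dir"},
                "version": __version__, "seed": config.get("seed", 0)}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


def run_quantify(config: dict) -> dict[str, pd.DataFrame]:
    """Puncta quantification end to end: per-ROI stats, enrichment, ANOVA tables.

    Returns (and, with ``out_dir`` set, writes) the tables:
    ``roi_stats``, ``enrichment``, ``anova_density``, ``anova_size``, and the
    location comparisons per brain area (Bonferroni planned).
    """
    config = _merge(DEFAULTS, config)
    channels, rois, pairs = _load_inputs(config)
    labels = config["channels"] or [c for c in channels if c not in _AUX_CHANNELS]
    missing = [c for c in labels if c not in channels]
    if missing:
        raise KeyError(f"channels {missing} not present in input")
    if not rois:
        warnings.warn("no ROIs: output tables are empty", stacklevel=2)
    part = config["particles"]
    px = next(iter(channels.values())).pixel_size_nm if channels else config["pixel_size_nm"]

    stat_rows = []
    stats_by = {}
    for lab in labels:
        _, thr = _binarize(channels[lab], config)
        for roi in rois:
            s = quantify_roi(
                thr.mask, roi, px,
                connectivity=int(part["connectivity"]),
                area_gate_um2=tuple(part["area_gate_um2"]),
                circ_gate=tuple(part["circ_gate"]),
                per_area_um2=float(part["density_per_area_um2"]),
            )
            stats_by[(lab, roi.label)] = s
            stat_rows.append(
                dict(channel=lab, roi_label=roi.label,
                     location_class=roi.location_class.value,
                     brain_area=roi.brain_area, pair_id=roi.pair_id,
                     n_clusters=s.n_clusters, density_per_100um2=s.density,
                     mean_size_um2=s.mean_size_um2, percent_area=s.percent_area)
        )
    roi_stats = pd.DataFrame(stat_rows, columns=["channel", "roi_label", "location_class",
                                                 "brain_area", "pair_id", "n_clusters",
                                                 "density_per_100um2", "mean_size_um2",
                                                 "percent_area"])

    enr_rows, pair_rows = [], []
    for lab in labels:
        sub = roi_stats[roi_stats.channel == lab]
        for area in sorted(sub.brain_area.unique()):
            ais = [stats_by[(lab, r)] for r in sub[(sub.brain_area == area)
                   & (sub.location_class == "AIS")].roi_label]
            non = [stats_by[(lab, r)] for r in sub[(sub.brain_area == area)
                   & (sub.location_class == "NON_AIS")].roi_label]
            if not ais or not non:
                continue
            res = enrichment_ratio(ais, non, area)
            enr_rows.append(
                dict(channel=lab, brain_area=area,
                     n_ais_rois=res.n_ais_rois, n_nonais_rois=res.n_non_ais_rois,
                     mean_pct_area_ais=res.mean_percent_area_ais,
                     mean_pct_area_nonais=res.mean_percent_area_non_ais,
                     enrichment_ratio=res.enrichment_ratio)
            )
        for p in pairs:
            a, n = stats_by.get((lab, p.ais.label)), stats_by.get((lab, p.non_ais.label))
            if a is None or n is None:
                continue
            ratio = per_roi_enrichment([(a, n)])[0]
            pair_rows.append(dict(channel=lab, pair_id=p.ais.pair_id,
                                  brain_area=p.ais.brain_area, pair_ratio=ratio))
    enrichment = pd.DataFrame(enr_rows, columns=["channel", "brain_area", "n_ais_rois",
                                                 "n_nonais_rois", "mean_pct_area_ais",
                                                 "mean_pct_area_nonais", "enrichment_ratio"])
    pair_ratios = pd.DataFrame(pair_rows, columns=["channel", "pair_id", "brain_area",
                                                   "pair_ratio"])

    tables = {"roi_stats": roi_stats, "enrichment": enrichment, "pair_ratios": pair_ratios}
    tables.update(_quantify_stats(roi_stats, pair_ratios, config))
    _write_tables(tables, config)
    return tables


def _anova_df_rows(tab: pd.DataFrame, channel: str, response: str) -> list[dict]:
    return [dict(channel=channel, response=response, effect=e, **row)
            for e, row in tab.to_dict("index").items()]


def _quantify_stats(roi_stats: pd.DataFrame, pair_ratios: pd.DataFrame,
                    config: dict) -> dict[str, pd.DataFrame]:
    """ANOVA stack over the per-ROI table.

    With >= 2 brain areas: two-way (location x area) ANOVA on density and mean
    size, Bonferroni planned AIS vs non-AIS comparisons per area, and one-way
    ANOVA + Tukey-Kramer on the per-pair enrichment ratios across areas.
    With one area the location effect is tested by one-way ANOVA.
    """
    anova_rows = {"density_per_100um2": [], "mean_size_um2": []}
    cmp_rows = []
    for lab in sorted(roi_stats.channel.unique()) if len(roi_stats) else []:
        sub = roi_stats[roi_stats.channel == lab]
        n_areas = sub.brain_area.nunique()
        for response in anova_rows:
            try:
                if n_areas >= 2:
                    tab = two_way_anova(sub[response], sub.location_class, sub.brain_area)
                else:
                    tab = one_way_anova(sub[response], sub.location_class)
            except ValueError as err:
                log.warning("ANOVA on %s/%s skipped: %s", lab, response, err)
                continue
            anova_rows[response].extend(
                _anova_df_rows(tab.reset_index().set_index("effect"), lab, response))
        # planned AIS vs non-AIS comparisons within each area
        for response in ("density_per_100um2", "mean_size_um2"):
            areas = sorted(sub.brain_area.unique())
            ps, ests = [], []
            for area in areas:
                a = sub[(sub.brain_area == area) & (sub.location_class == "AIS")][response].dropna()
                n = sub[(sub.brain_area == area) & (sub.location_class == "NON_AIS")][response].dropna()
                if len(a) < 2 or len(n) < 2:
                    ps.append(np.nan); ests.append(np.nan)
                    continue
                from scipy import stats as sps
                t = sps.ttest_ind(a, n, equal_var=True)
                ps.append(float(t.pvalue)); ests.append(float(a.mean() - n.mean()))
            adj = bonferroni_planned([p for p in ps if np.isfinite(p)], len(areas))
            it = iter(adj)
            for area, p, est in zip(areas, ps, ests):
                cmp_rows.append(dict(channel=lab, response=response, brain_area=area,
                                     estimate=est, p_raw=p,
                                     p_adjusted=next(it) if np.isfinite(p) else np.nan,
                                     method="BONFERRONI"))
    out = {
        "anova_density": pd.DataFrame(anova_rows["density_per_100um2"]),
        "anova_size": pd.DataFrame(anova_rows["mean_size_um2"]),
        "location_comparisons": pd.DataFrame(cmp_rows),
    }
    # across-area ANOVA on per-pair enrichment ratios
    enr_anova, enr_cmp = [], []
    for lab in sorted(pair_ratios.channel.unique()) if len(pair_ratios) else []:
        sub = pair_ratios[pair_ratios.channel == lab].dropna(subset=["pair_ratio"])
        if sub.brain_area.nunique() >= 2:
            tab = one_way_anova(sub.pair_ratio, sub.brain_area)
            enr_anova.extend(_anova_df_rows(tab, lab, "pair_ratio"))
            groups = {a: g.pair_ratio.to_numpy() for a, g in sub.groupby("brain_area")}
            if all(len(v) >= 2 for v in groups.values()):
                for c in tukey_kramer(groups):
                    enr_cmp.append(dict(channel=lab, group_a=c.pair[0], group_b=c.pair[1],
                                        estimate=c.estimate, p_adjusted=c.p_adjusted,
                                        method=c.method))
    out["enrichment_anova"] = pd.DataFrame(enr_anova)
    out["enrichment_comparisons"] = pd.DataFrame(enr_cmp)
    return out


def run_coloc(config: dict) -> dict[str, pd.DataFrame]:
    """Two-channel ROI colocalization: Pearson + binary Manders per ROI, and
    AIS vs non-AIS Bonferroni-corrected t-tests over the coefficient family."""
    config = _merge(DEFAULTS, config)
    channels, rois, pairs = _load_inputs(config)
    cc = config["coloc"]
    lab_a, lab_b = cc["channel_a"], cc["channel_b"]
    for lab in (lab_a, lab_b):
        if lab not in channels:
            raise KeyError(f"channel {lab!r} not present in input")
    img_a, thr_a = _binarize(channels[lab_a], config)
    img_b, thr_b = _binarize(channels[lab_b], config)

    rows = []
    for roi in rois:
        mode = cc["pearson_thresholds"]
        r = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                if mode == "costes":
                    ta, tb = costes_auto_threshold(img_a, img_b, roi)
                    r = pearson_roi(img_a, img_b, roi, (ta.threshold, tb.threshold))
                elif mode == "none" or mode is None:
                    r = pearson_roi(img_a, img_b, roi)
                else:
                    r = pearson_roi(img_a, img_b, roi, (float(mode[0]), float(mode[1])))
            except ValueError:
                r = pearson_roi(img_a, img_b, roi)
        m1, m2 = manders_binary(thr_a.mask, thr_b.mask, roi)
        rows.append(dict(roi_label=roi.label, location_class=roi.location_class.value,
                         brain_area=roi.brain_area, pair_id=roi.pair_id,
                         pearson_r=r, m1=m1, m2=m2, n_pixels=roi.n_pixels))
    coloc = pd.DataFrame(rows, columns=["roi_label", "location_class", "brain_area",
                                        "pair_id", "pearson_r", "m1", "m2", "n_pixels"])

    cmp_rows = []
    if len(coloc):
        metrics = {}
        for metric in ("pearson_r", "m1", "m2"):
            a = coloc[coloc.location_class == "AIS"][metric].to_numpy()
            n = coloc[coloc.location_class == "NON_AIS"][metric].to_numpy()
            if np.isfinite(a).sum() >= 2 and np.isfinite(n).sum() >= 2:
                metrics[metric] = (a, n)
        for c in bonferroni_t_tests(metrics):
            cmp_rows.append(dict(metric=c.pair[0].split(":")[0], estimate=c.estimate,
                                 p_raw=c.p_raw, p_adjusted=c.p_adjusted, method=c.method))
    tables = {"coloc": coloc,
              "coloc_comparisons": pd.DataFrame(cmp_rows, columns=["metric", "estimate",
                                                                   "p_raw", "p_adjusted",
                                                                   "method"])}
    _write_tables(tables, config)
    return tables


def run_stats(roi_stats_path: str | Path, config: dict | None = None) -> dict[str, pd.DataFrame]:
    """Re-run the ANOVA stack on an existing per-ROI stats table."""
    config = _merge(DEFAULTS, config or {})
    roi_stats = pd.read_csv(roi_stats_path)
    pair_rows = []
    for (lab, pid, area), g in roi_stats.groupby(["channel", "pair_id", "brain_area"]):
        if pid < 0:
            continue
        a = g[g.location_class == "AIS"].percent_area
        n = g[g.location_class == "NON_AIS"].percent_area
        if len(a) == 1 and len(n) == 1:
            ratio = a.iloc[0] / n.iloc[0] if n.iloc[0] > 0 else np.nan
            pair_rows.append(dict(channel=lab, pair_id=pid, brain_area=area, pair_ratio=ratio))
    tables = _quantify_stats(roi_stats, pd.DataFrame(pair_rows, columns=["channel", "pair_id",
                                                                         "brain_area",
                                                                         "pair_ratio"]), config)
    _write_tables(tables, config)
    return tables
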