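"""Pearson and Manders colocalization within ROIs; AnkG-overlap validation."""

import math

import numpy as np
import pytest

from aisquant.coloc import manders_binary, pearson_roi, validate_ais_roi
from aisquant.imaging import BinaryMask, CalibratedImage, Location, Roi


def _img(arr, px=64.0):
    return CalibratedImage(np.asarray(arr, dtype=np.float64), px)


def _full_roi(shape):
    return Roi(np.ones(shape, dtype=bool), 1, Location.AIS)


class TestPearson:
    def test_identical_channels_give_r_one(self, rng):
        arr = rng.uniform(0, 200, (40, 40))
        r = pearson_roi(_img(arr), _img(arr.copy()), _full_roi(arr.shape))
        assert abs(r - 1.0) < 1e-12

    def test_inverted_channel_gives_r_minus_one(self, rng):
        arr = rng.uniform(0, 200, (40, 40))
        r = pearson_roi(_img(arr), _img(250.0 - arr), _full_roi(arr.shape))
        assert abs(r + 1.0) < 1e-12

    def test_affine_rescaling_invariance(self, rng):
        a = rng.uniform(0, 200, (30, 30))
        b = rng.uniform(0, 200, (30, 30))
        roi = _full_roi(a.shape)
        r1 = pearson_roi(_img(a), _img(b), roi)
        r2 = pearson_roi(_img(3.7 * a + 11.0), _img(b), roi)
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_zero_variance_is_missing_with_warning(self):
        a = np.full((10, 10), 5.0)
        b = np.arange(100, dtype=float).reshape(10, 10)
        with pytest.warns(UserWarning, match="zero variance"):
            r = pearson_roi(_img(a), _img(b), _full_roi(a.shape))
        assert math.isnan(r)

    def test_thresholds_restrict_evaluation_set(self, rng):
        a = rng.uniform(0, 100, (20, 20))
        b = a + rng.normal(0, 1, (20, 20)).clip(-a)
        roi = _full_roi(a.shape)
        r_all = pearson_roi(_img(a), _img(np.abs(b)), roi)
        r_thr = pearson_roi(_img(a), _img(np.abs(b)), roi, thresholds=(50.0, 50.0))
        assert -1.0 <= r_thr <= 1.0 and r_thr != r_all

    def test_shared_fraction_monotonicity(self):
        """Mean r rises monotonically with the fraction of shared puncta."""
        levels = [0.0, 0.25, 0.5, 0.75, 1.0]
        n_pts, shape = 40, (128, 128)
        means = []
        for f in levels:
            rs = []
            for seed in range(30):
                r = np.random.default_rng(seed + 1000)
                pos = r.integers(5, 123, (n_pts, 2))
                n_shared = int(round(f * n_pts))
                pos_b = np.vstack([pos[:n_shared], r.integers(5, 123, (n_pts - n_shared, 2))])
                a = np.zeros(shape)
                b = np.zeros(shape)
                for p, img in ((pos, a), (pos_b, b)):
                    for rr, cc in p:
                        img[rr - 2 : rr + 3, cc - 2 : cc + 3] += 100.0
                a += r.normal(0, 5, shape) ** 2
                b += r.normal(0, 5, shape) ** 2
                rs.append(pearson_roi(_img(a), _img(b), _full_roi(shape)))
            means.append(np.mean(rs))
        assert all(m2 > m1 for m1, m2 in zip(means, means[1:]))
        assert means[0] < means[2] < means[-1]


class TestManders:
    def test_identical_masks_give_unity(self):
        m = np.zeros((20, 20), dtype=bool)
        m[5:10, 5:10] = True
        m1, m2 = manders_binary(BinaryMask(m), BinaryMask(m.copy()), _full_roi(m.shape))
        assert m1 == 1.0 and m2 == 1.0

    def test_disjoint_masks_give_zero(self):
        a = np.zeros((20, 20), dtype=bool)
        b = np.zeros((20, 20), dtype=bool)
        a[2:6, 2:6] = True
        b[10:14, 10:14] = True
        assert manders_binary(BinaryMask(a), BinaryMask(b), _full_roi(a.shape)) == (0.0, 0.0)

    def test_nested_masks_set_arithmetic(self):
        b = np.zeros((20, 20), dtype=bool)
        b[0:10, 0:10] = True  # 100 px
        a = np.zeros((20, 20), dtype=bool)
        a[0:5, 0:8] = True  # 40 px, subset of b
        m1, m2 = manders_binary(BinaryMask(a), BinaryMask(b), _full_roi(a.shape))
        assert m1 == 1.0 and m2 == pytest.approx(0.4)

    def test_empty_reference_is_missing(self):
        a = np.zeros((10, 10), dtype=bool)
        b = np.ones((10, 10), dtype=bool)
        m1, m2 = manders_binary(BinaryMask(a), BinaryMask(b), _full_roi(a.shape))
        assert math.isnan(m1) and m2 == 0.0

    def test_random_pairs_match_set_arithmetic(self, rng):
        roi = _full_roi((32, 32))
        for _ in range(30):
            a = rng.random((32, 32)) < 0.3
            b = rng.random((32, 32)) < 0.3
            if not a.any() or not b.any():
                continue
            m1, m2 = manders_binary(BinaryMask(a), BinaryMask(b), roi)
            inter = (a & b).sum()
            assert m1 == inter / a.sum()
            assert m2 == inter / b.sum()

    def test_swap_symmetry(self, rng):
        roi = _full_roi((32, 32))
        a = rng.random((32, 32)) < 0.4
        b = rng.random((32, 32)) < 0.4
        m1_ab, m2_ab = manders_binary(BinaryMask(a), BinaryMask(b), roi)
        m1_ba, m2_ba = manders_binary(BinaryMask(b), BinaryMask(a), roi)
        assert m1_ab == m2_ba and m2_ab == m1_ba


class TestValidateAisRoi:
    def test_full_overlap_validates_at_any_threshold(self):
        sub = np.zeros((20, 20), dtype=bool)
        sub[5:8, 5:8] = True
        ankg = np.zeros((20, 20), dtype=bool)
        ankg[4:9, 4:9] = True
        roi = _full_roi((20, 20))
        for thr in (0.1, 0.5, 1.0):
            assert validate_ais_roi(BinaryMask(sub), BinaryMask(ankg), roi, thr)

    def test_zero_overlap_fails(self):
        sub = np.zeros((20, 20), dtype=bool)
        sub[2:5, 2:5] = True
        ankg = np.zeros((20, 20), dtype=bool)
        ankg[10:15, 10:15] = True
        assert not validate_ais_roi(BinaryMask(sub), BinaryMask(ankg),
                                    _full_roi((20, 20)), 0.1)

    def test_empty_subunit_signal_warns_and_fails(self):
        empty = BinaryMask(np.zeros((10, 10), dtype=bool))
        full = BinaryMask(np.ones((10, 10), dtype=bool))
        with pytest.warns(UserWarning, match="cannot validate"):
            assert not validate_ais_roi(empty, full, _full_roi((10, 10)))

    def test_candidate_mix_validation_rate(self):
        """With 90% of candidate ROIs on true AIS trajectories, the validation
        rate lands within 10 percentage points of 90%."""
        from aisquant.preprocess import rolling_ball_subtract, triangle_threshold
        from aisquant.protocols import DESK_ROLLING_BALL_RADIUS_PX, desk_config
        from aisquant.synthetic import generate_scene

        cfg = desk_config(n_ais=36, channels=("alpha2", "AnkG"), seed=9)
        scene = generate_scene(cfg)
        sub_mask = triangle_threshold(
            rolling_ball_subtract(scene.channels["alpha2"], DESK_ROLLING_BALL_RADIUS_PX)).mask
        ankg_mask = triangle_threshold(
            rolling_ball_subtract(scene.channels["AnkG"], DESK_ROLLING_BALL_RADIUS_PX)).mask
        ais_rois = [r for r in scene.rois if r.location_class is Location.AIS]
        decoys = [r for r in scene.rois if r.location_class is Location.NON_AIS][:4]
        candidates = ais_rois + decoys  # 36 true + 4 decoys = 90% planted true
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # signal-free decoys warn
            rate = np.mean([validate_ais_roi(sub_mask, ankg_mask, r, 0.5)
                            for r in candidates])
        assert abs(rate - 0.9) <= 0.10
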