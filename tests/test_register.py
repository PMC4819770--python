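"""Fiducial matching, LWM transform recovery, residual bookkeeping."""

import numpy as np
import pytest

from nanofish.core import FrameGeometry
from nanofish.register import (FiducialPair, InsufficientFiducialsError,
                               apply_transform, build_lwm_transform,
                               load_model, match_fiducials, residual_error,
                               save_model)
from nanofish.synthetic import ChannelWarp


@pytest.fixture
def reg_frame():
    return FrameGeometry(128, 128, 200.0)


def _pairs_from_warp(warp, positions):
    return [FiducialPair(tuple(p), tuple(q))
            for p, q in zip(positions, warp.apply(positions))]


def _scatter(rng, frame, n, margin=1200.0):
    return rng.uniform(margin, frame.width_nm - margin, size=(n, 2))


class TestMatchFiducials:
    def test_identical_lists_all_matched_at_zero(self, reg_frame):
        rng = np.random.default_rng(0)
        pos = _scatter(rng, reg_frame, 20)
        pairs = match_fiducials(pos, pos)
        assert len(pairs) == 20
        for p in pairs:
            assert p.position_a == p.position_b

    def test_extra_bead_left_unmatched(self, reg_frame):
        rng = np.random.default_rng(1)
        pos = _scatter(rng, reg_frame, 20)
        extra = np.vstack([pos, [[900.0, 900.0]]])
        pairs = match_fiducials(extra, pos)
        assert len(pairs) == 20

    def test_matches_ground_truth_correspondence(self, reg_frame):
        rng = np.random.default_rng(2)
        warp = ChannelWarp.random_quadratic(reg_frame, 40.0, rng)
        pos = _scatter(rng, reg_frame, 30)
        pairs = match_fiducials(pos, warp.apply(pos))
        assert len(pairs) == 30
        for p in pairs:
            expected = warp.apply(np.array(p.position_a))[0]
            np.testing.assert_allclose(p.position_b, expected, atol=1e-9)

    def test_too_few_pairs_raises(self, reg_frame):
        rng = np.random.default_rng(3)
        pos = _scatter(rng, reg_frame, 5)
        with pytest.raises(InsufficientFiducialsError):
            match_fiducials(pos, pos)


class TestLwmTransform:
    def test_identity_reproduced(self, reg_frame):
        rng = np.random.default_rng(4)
        pos = _scatter(rng, reg_frame, 30)
        model = build_lwm_transform(_pairs_from_warp(ChannelWarp.identity(), pos))
        q = _scatter(rng, reg_frame, 40, margin=1500.0)
        np.testing.assert_allclose(apply_transform(model, q), q, atol=0.5)

    def test_translation_reproduced_exactly(self, reg_frame):
        rng = np.random.default_rng(5)
        warp = ChannelWarp.translation(50.0, 0.0)
        pos = _scatter(rng, reg_frame, 30)
        model = build_lwm_transform(_pairs_from_warp(warp, pos))
        q = _scatter(rng, reg_frame, 40, margin=1500.0)
        corrected = apply_transform(model, warp.apply(q))
        np.testing.assert_allclose(corrected, q, atol=0.5)

    def test_quadratic_warp_recovered(self, reg_frame):
        rng = np.random.default_rng(6)
        warp = ChannelWarp.random_quadratic(reg_frame, 50.0, rng)
        pos = _scatter(rng, reg_frame, 40)
        model = build_lwm_transform(_pairs_from_warp(warp, pos))
        holdout = _pairs_from_warp(warp, _scatter(rng, reg_frame, 30, 1500.0))
        assert residual_error(model, holdout) < 2.0

    def test_requires_twelve_pairs(self, reg_frame):
        rng = np.random.default_rng(7)
        pairs = _pairs_from_warp(ChannelWarp.identity(),
                                 _scatter(rng, reg_frame, 11))
        with pytest.raises(InsufficientFiducialsError):
            build_lwm_transform(pairs)

    def test_determinism(self, reg_frame):
        rng = np.random.default_rng(8)
        warp = ChannelWarp.random_quadratic(reg_frame, 30.0, rng)
        pos = _scatter(rng, reg_frame, 30)
        pairs = _pairs_from_warp(warp, pos)
        q = _scatter(rng, reg_frame, 25, 1500.0)
        out1 = apply_transform(build_lwm_transform(pairs), q)
        out2 = apply_transform(build_lwm_transform(pairs), q)
        np.testing.assert_array_equal(out1, out2)

    def test_grid_agrees_with_direct_evaluation(self, reg_frame):
        rng = np.random.default_rng(9)
        warp = ChannelWarp.random_quadratic(reg_frame, 50.0, rng)
        pos = _scatter(rng, reg_frame, 40)
        pairs = _pairs_from_warp(warp, pos)
        q = _scatter(rng, reg_frame, 50, 1500.0)
        grid = apply_transform(build_lwm_transform(pairs, method="grid"), q)
        direct = apply_transform(build_lwm_transform(pairs, method="direct"), q)
        assert np.abs(grid - direct).max() < 1.0

    def test_roundtrip_serialization(self, reg_frame, tmp_path):
        rng = np.random.default_rng(10)
        warp = ChannelWarp.random_quadratic(reg_frame, 30.0, rng)
        pairs = _pairs_from_warp(warp, _scatter(rng, reg_frame, 30))
        model = build_lwm_transform(pairs)
        residual_error(model, _pairs_from_warp(warp, _scatter(rng, reg_frame, 15, 1500.0)))
        path = tmp_path / "model.tsv"
        save_model(model, path)
        loaded = load_model(path)
        assert loaded.residual_nm == pytest.approx(model.residual_nm)
        q = _scatter(rng, reg_frame, 20, 1500.0)
        np.testing.assert_allclose(loaded.transform(q), model.transform(q),
                                   atol=1e-6)


class TestResidualError:
    def test_noiseless_holdout_near_zero(self, reg_frame):
        rng = np.random.default_rng(11)
        pos = _scatter(rng, reg_frame, 30)
        model = build_lwm_transform(_pairs_from_warp(ChannelWarp.identity(), pos))
        ho = _pairs_from_warp(ChannelWarp.identity(),
                              _scatter(rng, reg_frame, 20, 1500.0))
        r = residual_error(model, ho)
        assert 0.0 <= r < 0.5
        assert model.residual_nm == r

    def test_tracks_localization_noise_floor(self, reg_frame):
        """With 15-nm (2D RMS) per-channel bead localization noise and a
        perfectly recoverable warp, r approaches sqrt(15^2 + 15^2) ~ 21 nm."""
        rng = np.random.default_rng(12)
        warp = ChannelWarp.random_quadratic(reg_frame, 50.0, rng)
        sig_axis = 15.0 / np.sqrt(2.0)
        ratios = []
        for _ in range(6):
            true = _scatter(rng, reg_frame, 60)
            obs_a = true + rng.normal(0, sig_axis, true.shape)
            obs_b = warp.apply(true) + rng.normal(0, sig_axis, true.shape)
            model = build_lwm_transform(
                [FiducialPair(tuple(a), tuple(b)) for a, b in zip(obs_a, obs_b)])
            ht = _scatter(rng, reg_frame, 150, 1500.0)
            ho = [FiducialPair(tuple(a), tuple(b)) for a, b in zip(
                ht + rng.normal(0, sig_axis, ht.shape),
                warp.apply(ht) + rng.normal(0, sig_axis, ht.shape))]
            ratios.append(residual_error(model, ho) / np.hypot(15.0, 15.0))
        mean_ratio = float(np.mean(ratios))
        assert 0.8 <= mean_ratio <= 1.2

    def test_empty_holdout_rejected(self, reg_frame):
        rng = np.random.default_rng(13)
        model = build_lwm_transform(
            _pairs_from_warp(ChannelWarp.identity(), _scatter(rng, reg_frame, 20)))
        with pytest.raises(ValueError):
            residual_error(model, [])

    def test_r_shrinks_with_bead_brightness(self, reg_frame):
        """More photons per bead (lower localization noise) lowers r."""
        rng = np.random.default_rng(14)
        warp = ChannelWarp.random_quadratic(reg_frame, 40.0, rng)
        rs = []
        for noise_nm in (20.0, 10.0, 5.0, 2.0):
            trial = []
            for _ in range(4):
                true = _scatter(rng, reg_frame, 50)
                oa = true + rng.normal(0, noise_nm, true.shape)
                ob = warp.apply(true) + rng.normal(0, noise_nm, true.shape)
                model = build_lwm_transform(
                    [FiducialPair(tuple(a), tuple(b)) for a, b in zip(oa, ob)])
                ht = _scatter(rng, reg_frame, 80, 1500.0)
                ho = [FiducialPair(tuple(a), tuple(b)) for a, b in zip(
                    ht + rng.normal(0, noise_nm, ht.shape),
                    warp.apply(ht) + rng.normal(0, noise_nm, ht.shape))]
                trial.append(residual_error(model, ho))
            rs.append(np.mean(trial))
        assert all(b < a for a, b in zip(rs, rs[1:]))
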