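import numpy as np
import pandas as pd
import pytest

from smstoich.benchmark import brightness_linearity, detection_performance
from smstoich.camera import TIRF_EMCCD
from smstoich.detect import (
    LOC_COLUMNS,
    SpotDetector,
    detect_spots,
    filter_localizations,
    fit_spot,
    net_gradient,
)


class TestDetectSpots:
    def test_constant_frame_has_no_candidates(self):
        assert len(detect_spots(np.full((64, 64), 170.0))) == 0

    def test_non_2d_input_rejected(self):
        with pytest.raises(ValueError):
            detect_spots(np.zeros((3, 64, 64)))
        with pytest.raises(ValueError):
            detect_spots(np.zeros((4, 4)), dog_sigmas_nm=(240.0, 120.0))

    def test_background_only_frames_mostly_empty(self):
        # offset + read noise at the default threshold: no candidates in >=95%
        n_empty = 0
        for s in range(40):
            rng = np.random.default_rng(1000 + s)
            frame = np.clip(np.rint(170 + rng.normal(0, 10, (128, 128))), 0, None)
            if len(detect_spots(frame)) == 0:
                n_empty += 1
        assert n_empty >= 38

    def test_single_emitter_found_within_one_pixel(self, single_emitter_factory):
        stack, scene = single_emitter_factory(k=2, n_frames=1, noise=True)
        cands = detect_spots(stack.frames[0])
        assert len(cands) == 1
        px = TIRF_EMCCD.pixel_size_nm
        truth = np.array([scene.emitters.y_nm[0] / px, scene.emitters.x_nm[0] / px])
        assert np.linalg.norm(cands[0] + 0.5 - truth) <= 1.0


class TestFitSpot:
    def test_noiseless_round_trip_recovers_volume_and_width(
        self, single_emitter_factory
    ):
        stack, scene = single_emitter_factory(k=3, noise=False)
        px = TIRF_EMCCD.pixel_size_nm
        cand = (int(scene.emitters.y_nm[0] / px), int(scene.emitters.x_nm[0] / px))
        loc = fit_spot(stack.frames[0], cand, photometry_sigma_nm=None)
        assert loc["fit_ok"]
        assert loc["brightness_photons"] == pytest.approx(750.0, rel=0.01)
        assert loc["sigma_nm"] == pytest.approx(150.0, rel=0.01)

    def test_flat_background_candidate_never_a_bright_spot(self):
        frame = np.full((32, 32), 170.0)
        loc = fit_spot(frame, (16, 16))
        assert (not loc["fit_ok"]) or loc["brightness_photons"] <= 1.0

    def test_roi_touching_border_is_fit_failed(self):
        frame = np.full((32, 32), 170.0)
        loc = fit_spot(frame, (2, 16))
        assert not loc["fit_ok"]
        assert loc["reject_reason"] == "fit_failed"

    def test_localization_error_below_cr_bound_scale(self):
        # 1000-photon emitter on 20 photons/px background, 500 repetitions
        from smstoich.synth import SceneConfig, generate_scene, render_movie

        cfg = SceneConfig(
            field_size_nm=(3200.0, 3200.0),
            n_emitters=1,
            order_distribution={1: 1.0},
            labeling_p=1.0,
            min_separation_nm=0.0,
            border_nm=1400.0,
        )
        scene = generate_scene(cfg, seed=21)
        stack, _ = render_movie(
            scene,
            photons_per_fluorophore=1000.0,
            n_frames=500,
            seed=22,
            background_photons=20.0,
            brightness_cv=0.0,
        )
        px = TIRF_EMCCD.pixel_size_nm
        tx, ty = scene.emitters.x_nm[0] / px, scene.emitters.y_nm[0] / px
        cand = (int(ty), int(tx))
        err2 = []
        for f in range(500):
            loc = fit_spot(stack.frames[f], cand)
            if loc["fit_ok"]:
                err2.append((loc["x_px"] - tx) ** 2 + (loc["y_px"] - ty) ** 2)
        assert len(err2) > 450
        assert np.sqrt(np.mean(err2)) < 0.3


class TestFilterLocalizations:
    @staticmethod
    def loc_row(frame=0, x=10.0, y=10.0, sigma=150.0, reason="none", fit_ok=True):
        return {
            "frame": frame,
            "x_px": x,
            "y_px": y,
            "x_nm": x * 100,
            "y_nm": y * 100,
            "brightness_photons": 300.0,
            "sigma_nm": sigma,
            "background_photons": 1.0,
            "fit_ok": fit_ok,
            "reject_reason": reason,
        }

    def test_close_pair_both_rejected(self):
        locs = pd.DataFrame([self.loc_row(x=10.0), self.loc_row(x=16.0)])
        out = filter_localizations(locs, min_roi_distance_px=7.0)
        assert (out["reject_reason"] == "overlap").all()

    def test_pair_at_min_distance_kept(self):
        locs = pd.DataFrame([self.loc_row(x=10.0), self.loc_row(x=17.5)])
        out = filter_localizations(locs, min_roi_distance_px=7.0)
        assert (out["reject_reason"] == "none").all()

    def test_pair_in_different_frames_not_overlapping(self):
        locs = pd.DataFrame(
            [self.loc_row(frame=0, x=10.0), self.loc_row(frame=1, x=11.0)]
        )
        out = filter_localizations(locs, min_roi_distance_px=7.0)
        assert (out["reject_reason"] == "none").all()

    @pytest.mark.parametrize(
        "sigma,expected", [(150.0, "none"), (200.0, "none"), (201.0, "sigma_too_large")]
    )
    def test_maximum_sigma_boundary(self, sigma, expected):
        out = filter_localizations(pd.DataFrame([self.loc_row(sigma=sigma)]))
        assert out["reject_reason"].iloc[0] == expected

    def test_empty_input_gives_empty_output(self):
        out = filter_localizations(pd.DataFrame(columns=LOC_COLUMNS))
        assert len(out) == 0

    def test_filtering_is_idempotent(self):
        rng = np.random.default_rng(5)
        rows = [
            self.loc_row(x=float(x), y=float(y), sigma=float(s))
            for x, y, s in zip(
                rng.uniform(6, 60, 30), rng.uniform(6, 60, 30), rng.uniform(100, 260, 30)
            )
        ]
        once = filter_localizations(pd.DataFrame(rows))
        twice = filter_localizations(once)
        pd.testing.assert_frame_equal(once, twice)


class TestNetGradient:
    def test_flat_image_scores_zero(self):
        assert np.abs(net_gradient(np.full((31, 31), 7.0))).max() == 0.0

    def test_even_box_rejected(self):
        with pytest.raises(ValueError):
            net_gradient(np.zeros((16, 16)), box=6)

    def test_spot_scores_positive_and_peaks_at_center(self, single_emitter_factory):
        stack, scene = single_emitter_factory(k=2, noise=False)
        frame = stack.frames[0]
        ng = net_gradient(frame)
        px = TIRF_EMCCD.pixel_size_nm
        r, c = int(scene.emitters.y_nm[0] / px), int(scene.emitters.x_nm[0] / px)
        center = ng[r - 1 : r + 2, c - 1 : c + 2].max()
        far = ng[r - 8 : r + 9, c - 8 : c + 9].copy()
        far[3:-3, 3:-3] = -np.inf  # ring at >= ~3 px from the centre
        assert center > 0
        assert center > far.max()

    def test_inverted_spot_scores_negative(self, single_emitter_factory):
        stack, _ = single_emitter_factory(k=2, noise=False)
        frame = stack.frames[0]
        inverted = 2 * frame.mean() - frame
        assert net_gradient(inverted).min() < 0
        np.testing.assert_allclose(
            net_gradient(inverted), -net_gradient(frame - 2 * frame.mean()), atol=1e-6
        )


class TestDetectorPerformance:
    def test_brightness_linear_in_label_count(self):
        res = brightness_linearity(seed=31)
        assert res["slope_error"] < 0.02
        # every k individually unbiased on noiseless renders
        for k, b in res["brightness_by_k"].items():
            assert b == pytest.approx(250.0 * k, rel=0.02)

    def test_recall_and_precision_on_dim_isolated_emitters(self):
        res = detection_performance(seed=32)
        assert res["recall"] >= 0.95
        assert res["precision"] >= 0.95

    def test_conversion_round_trip_with_forward_model(self, single_emitter_factory):
        # inversion of the simulator's mean model at high photon count
        stack, scene = single_emitter_factory(
            k=1, noise=False, photons_per_fluorophore=5000.0
        )
        det = SpotDetector()
        locs = SpotDetector.accepted(det.locate(stack.frames[0]))
        assert len(locs) == 1
        assert locs["brightness_photons"].iloc[0] == pytest.approx(5000.0, rel=0.01)
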