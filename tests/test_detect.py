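"""LoG detection: filter properties, thresholds, localization, SNR."""

import numpy as np
import pandas as pd
import pytest

from synmap import (
    ChannelConfig,
    DetectionParams,
    Micrograph,
    SynthConfig,
    compute_snr,
    detect_puncta,
    evaluate_detection,
    generate_field,
    log_response,
    measure_intensity,
)
from synmap.synthgen import GroundTruth, render_ground_truth


def render_single_punctum(x_um, y_um, amplitude=400.0, sigma_um=0.09,
                          background=100.0, field_um=10.0):
    cfg = SynthConfig(
        field_size_um=(field_um, field_um),
        channels=[ChannelConfig("A", density_per_100um2=0.0)],
        background_level=background,
        read_noise_sd=0.0,
        shot_noise=False,
    )
    truth = GroundTruth(
        channels={
            "A": pd.DataFrame(
                {
                    "x_um": [x_um], "y_um": [y_um],
                    "amplitude": [amplitude], "sigma_um": [sigma_um],
                    "pair_id": [-1], "mode": [""],
                }
            )
        },
        pairs=pd.DataFrame(
            columns=["pair_id", "channel_a", "channel_b", "index_a", "index_b", "mode"]
        ),
    )
    return render_ground_truth(cfg, truth)[0]


class TestLogResponse:
    def test_constant_image_gives_zero_response(self):
        img = Micrograph(np.full((64, 64), 300.0))
        resp = log_response(img, 0.15)
        np.testing.assert_allclose(resp, 0.0, atol=1e-8)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        img = Micrograph(rng.uniform(50, 500, size=(48, 48)))
        scaled = Micrograph(0.5 * img.pixels)
        np.testing.assert_allclose(
            log_response(scaled, 0.15), 0.5 * log_response(img, 0.15), atol=1e-9
        )

    def test_peak_at_matched_punctum_within_one_pixel(self):
        sigma = 0.09
        img = render_single_punctum(5.03, 4.77, sigma_um=sigma)
        resp = log_response(img, sigma * np.sqrt(2.0))
        i, j = np.unravel_index(resp.argmax(), resp.shape)
        s = img.pixel_size_um
        assert abs((j + 0.5) * s - 5.03) <= s
        assert abs((i + 0.5) * s - 4.77) <= s

    def test_radius_below_one_pixel_raises(self):
        img = Micrograph(np.zeros((32, 32)))
        with pytest.raises(ValueError, match="minimum"):
            log_response(img, 0.01)


class TestDetectPuncta:
    def test_blank_noisy_image_yields_no_puncta(self):
        cfg = SynthConfig(
            field_size_um=(20.0, 20.0),
            channels=[ChannelConfig("A", density_per_100um2=0.0)],
        )
        images, _ = generate_field(cfg, seed=9)
        ps = detect_puncta(images[0], DetectionParams(quality_threshold=45.0))
        assert len(ps) == 0

    def test_recall_and_precision_on_synthetic_field(self, medium_field,
                                                     default_params):
        _, image, truth = medium_field
        ps = detect_puncta(image, default_params)
        score = evaluate_detection(ps.positions, truth.positions("SV2A"), 0.3)
        assert score.n_truth >= 40
        assert score.recall >= 0.95
        assert score.precision >= 0.95

    def test_detection_is_deterministic(self, medium_field, default_params):
        _, image, _ = medium_field
        ps1 = detect_puncta(image, default_params)
        ps2 = detect_puncta(image.copy(), default_params)
        pd.testing.assert_frame_equal(ps1.puncta, ps2.puncta)

    def test_output_ordered_by_descending_quality(self, medium_field,
                                                  default_params):
        _, image, _ = medium_field
        q = detect_puncta(image, default_params).puncta["quality"]
        assert (q.diff().dropna() <= 0).all()

    @pytest.mark.parametrize("knob", ["quality_threshold", "intensity_threshold"])
    def test_count_monotone_in_thresholds(self, medium_field, knob):
        _, image, _ = medium_field
        grids = {
            "quality_threshold": [10.0, 45.0, 120.0, 250.0],
            "intensity_threshold": [0.0, 110.0, 150.0, 300.0],
        }
        counts = []
        for thr in grids[knob]:
            params = DetectionParams(quality_threshold=30.0, exclude_border=False)
            setattr(params, knob, thr)
            counts.append(len(detect_puncta(image, params)))
        assert counts == sorted(counts, reverse=True)

    def test_auto_quality_threshold_uses_mean_candidate_quality(self, medium_field):
        _, image, _ = medium_field
        auto = detect_puncta(
            image, DetectionParams(quality_threshold="auto", exclude_border=False)
        )
        # auto mode keeps only candidates at or above the mean quality, so it
        # must be stricter than an effectively-zero absolute threshold
        loose = detect_puncta(
            image, DetectionParams(quality_threshold=1e-9, exclude_border=False)
        )
        assert 0 < len(auto) < len(loose)

    def test_subpixel_refinement_reduces_rmse(self, medium_field):
        _, image, truth = medium_field
        xy_true = truth.positions("SV2A")
        rmse = {}
        for subpixel in (True, False):
            ps = detect_puncta(
                image,
                DetectionParams(quality_threshold=45.0, subpixel=subpixel,
                                exclude_border=False),
            )
            rmse[subpixel] = evaluate_detection(ps.positions, xy_true, 0.3).rmse_um
        assert rmse[True] < rmse[False]

    def test_roi_mask_restricts_detections_and_area(self, medium_field,
                                                    default_params):
        _, image, _ = medium_field
        mask = np.zeros(image.pixels.shape, dtype=bool)
        mask[: mask.shape[0] // 2] = True
        ps = detect_puncta(image, default_params, roi_mask=mask)
        s = image.pixel_size_um
        assert ps.roi_area_um2 == pytest.approx(mask.sum() * s**2)
        assert (ps.puncta["y_um"] <= mask.shape[0] // 2 * s + 1e-9).all()

    def test_empty_roi_flagged(self, medium_field, default_params):
        _, image, _ = medium_field
        with pytest.warns(UserWarning, match="empty ROI"):
            ps = detect_puncta(
                image, default_params, roi_mask=np.zeros(image.pixels.shape, bool)
            )
        assert len(ps) == 0 and ps.roi_area_um2 == 0.0

    def test_detection_on_montage_matches_tiles_away_from_seams(self):
        from synmap import stitch_tiles, tile_montage
        from synmap._matching import match_points

        cfg = SynthConfig(
            field_size_um=(39.168, 39.168),  # 576 px at 68 nm: splits into 2x2
            channels=[ChannelConfig("A", density_per_100um2=8.0)],
            seed=21,
        )
        images, _ = generate_field(cfg)
        image = images[0]
        params = DetectionParams(quality_threshold=45.0, exclude_border=False)
        whole = detect_puncta(image, params).positions
        grid = tile_montage(image, (288, 288))
        s = image.pixel_size_um
        tiled = []
        for (r, c), tile in grid.tiles.items():
            ps = detect_puncta(tile, params)
            xy = ps.positions
            xy[:, 0] += c * 288 * s
            xy[:, 1] += r * 288 * s
            tiled.append(xy)
        tiled = np.vstack(tiled)
        seam_um = 288 * s
        band = 2 * params.punctum_radius_um
        def away(xy):
            return xy[
                (np.abs(xy[:, 0] - seam_um) > band) & (np.abs(xy[:, 1] - seam_um) > band)
            ]
        whole_away, tiled_away = away(whole), away(tiled)
        assert len(whole_away) == len(tiled_away)
        assert len(match_points(whole_away, tiled_away, 0.05)) == len(whole_away)


class TestMeasureIntensity:
    def test_constant_field(self):
        img = Micrograph(np.full((40, 40), 300.0))
        assert measure_intensity(img, (1.0, 1.0), 0.2) == 300.0

    def test_step_edge_through_centre_averages_to_midpoint(self):
        px = np.full((40, 40), 100.0)
        px[:, 20:] = 200.0
        img = Micrograph(px)
        s = img.pixel_size_um
        val = measure_intensity(img, (20 * s, 20 * s), 0.3)
        assert val == pytest.approx(150.0, abs=5.0)

    def test_matches_brute_force_pixel_enumeration(self):
        img = render_single_punctum(3.1, 2.9, amplitude=350.0, sigma_um=0.1)
        s = img.pixel_size_um
        centroid, radius = (3.1, 2.9), 0.15
        vals = []
        for i in range(img.pixels.shape[0]):
            for j in range(img.pixels.shape[1]):
                cx, cy = (j + 0.5) * s, (i + 0.5) * s
                if (cx - centroid[0]) ** 2 + (cy - centroid[1]) ** 2 <= radius**2:
                    vals.append(img.pixels[i, j])
        assert measure_intensity(img, centroid, radius) == pytest.approx(
            np.mean(vals), rel=1e-12
        )

    def test_disc_outside_image_raises(self):
        img = Micrograph(np.zeros((10, 10)))
        with pytest.raises(ValueError, match="outside"):
            measure_intensity(img, (50.0, 50.0), 0.2)


class TestSnr:
    def _puncta_set(self, img, xy):
        from synmap.detect import PUNCTA_COLUMNS, PunctaSet

        df = pd.DataFrame(
            {
                "x_um": [p[0] for p in xy],
                "y_um": [p[1] for p in xy],
                "quality": 1.0,
                "mean_intensity": 1.0,
                "radius_um": 0.12,
            },
            columns=PUNCTA_COLUMNS,
        )
        area = img.pixels.size * img.pixel_size_um**2
        return PunctaSet(marker="A", puncta=df, roi_area_um2=area)

    def test_formula_arithmetic(self):
        # background {8, 8, 12, 12, 10}: mean 10, sd (ddof=1) exactly 2
        px = np.full((1, 8), 10.0)
        px[0, :5] = [8.0, 8.0, 12.0, 12.0, 10.0]
        px[0, 6] = 30.0
        img = Micrograph(px)
        mask = np.zeros_like(px, bool)
        mask[0, :5] = True
        s = img.pixel_size_um
        ps = self._puncta_set(img, [((6 + 0.5) * s, 0.5 * s)])
        assert compute_snr(img, ps, mask) == pytest.approx(10.0)

    def test_empty_puncta_set_is_nan_with_warning(self):
        rng = np.random.default_rng(0)
        img = Micrograph(rng.uniform(90, 110, size=(20, 20)))
        ps = self._puncta_set(img, [])
        with pytest.warns(UserWarning, match="empty"):
            assert np.isnan(compute_snr(img, ps))

    def test_zero_background_variance_raises(self):
        img = Micrograph(np.full((10, 10), 100.0))
        s = img.pixel_size_um
        ps = self._puncta_set(img, [(5 * s, 5 * s)])
        with pytest.raises(ValueError, match="variance"):
            compute_snr(img, ps, np.ones((10, 10), bool))

    def test_recovers_amplitude_over_read_noise(self):
        # no shot noise: SNR ~= A / read_noise_sd within 10% over seeds
        amplitude, read_sd = 300.0, 10.0
        snrs = []
        for seed in range(20):
            cfg = SynthConfig(
                field_size_um=(25.0, 25.0),
                channels=[ChannelConfig("A", density_per_100um2=3.0,
                                        amplitude_mean=amplitude, amplitude_sd=0.0,
                                        sigma_jitter=0.0)],
                shot_noise=False,
                read_noise_sd=read_sd,
                seed=seed,
            )
            images, truth = generate_field(cfg)
            img = images[0]
            xy = truth.positions("A")
            if len(xy) < 3:
                continue
            # honest background: pixels far from every punctum
            s = img.pixel_size_um
            yy, xx = np.mgrid[: img.pixels.shape[0], : img.pixels.shape[1]]
            cx, cy = (xx + 0.5) * s, (yy + 0.5) * s
            mask = np.ones(img.pixels.shape, bool)
            for x, y in xy:
                mask &= (cx - x) ** 2 + (cy - y) ** 2 > 0.5**2
            snrs.append(compute_snr(img, self._puncta_set(img, xy), mask))
        assert len(snrs) >= 15
        assert np.mean(snrs) == pytest.approx(amplitude / read_sd, rel=0.10)
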