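"""Vision core: color mapping, digit recognition, calibration, transition scan."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from trimsight import (
    AxisCalibrationError,
    ProfileSpec,
    RenderStyle,
    VisionParams,
    build_color_map,
    calibrate_x_axis,
    classify_patch,
    locate_threshold_row,
    pixel_to_position,
    recognize_number,
    render_plot,
    scan_transition,
    simulate_profile,
)
from trimsight._font import render_text_mask
from trimsight.plot_vision import REFERENCE_PALETTE, ColorMap

PARAMS = VisionParams()


def uniform_image(rgb, shape=(40, 40)):
    return np.tile(np.array(rgb, np.uint8), (*shape, 1))


class TestColorMap:
    def test_uniform_yellow_image(self):
        cm = build_color_map(uniform_image((255, 255, 0)), PARAMS)
        assert cm.labels == {"yellow"}

    def test_fixture_palette_coverage(self, rendered):
        image, _ = rendered
        labels = build_color_map(image, PARAMS).labels
        assert {"yellow", "red", "green", "orange", "white"} <= labels

    def test_image_smaller_than_patch_raises(self):
        with pytest.raises(ValueError, match="too small"):
            build_color_map(uniform_image((0, 0, 0), (5, 5)), PARAMS)

    @pytest.mark.parametrize(
        "rgb,expected", [((255, 255, 0), "yellow"), ((255, 0, 0), "red"),
                         ((0, 0, 255), "blue"), ((255, 255, 255), "white")]
    )
    def test_pure_colors(self, rgb, expected):
        cm = ColorMap(centroids=REFERENCE_PALETTE)
        assert classify_patch(uniform_image(rgb, (10, 10)), cm) == expected

    def test_agrees_with_exhaustive_nearest_centroid(self):
        """classify_patch == brute-force nearest-centroid over random patches."""
        cm = ColorMap(centroids=REFERENCE_PALETTE)
        rng = np.random.default_rng(42)
        for _ in range(1000):
            rgb = rng.integers(0, 256, 3)
            patch = uniform_image(tuple(rgb), (4, 4))
            best, best_d = None, np.inf
            for c, lab in cm.centroids:  # independent exhaustive search
                d = sum((float(a) - float(b)) ** 2 for a, b in zip(c, rgb))
                if d < best_d:
                    best, best_d = lab, d
            assert classify_patch(patch, cm) == best

    @given(st.integers(0, 255), st.integers(0, 255), st.integers(0, 255))
    def test_every_patch_gets_exactly_one_known_label(self, r, g, b):
        cm = ColorMap(centroids=REFERENCE_PALETTE)
        assert classify_patch(uniform_image((r, g, b), (3, 3)), cm) in {
            lab for _, lab in REFERENCE_PALETTE
        }


class TestRecognizeNumber:
    @pytest.mark.parametrize("value", [0, 1, 7, 20, 42, 100, 150, 251, 300])
    def test_atlas_glyphs_read_exactly(self, value):
        mask = render_text_mask(str(value))
        img = np.where(mask[..., None], 0, 255).astype(np.uint8).repeat(3, axis=2)
        assert recognize_number(img, (0, 0, img.shape[1], img.shape[0])) == value

    def test_uniform_background_returns_none(self):
        img = uniform_image((255, 255, 255), (20, 80))
        assert recognize_number(img, (0, 0, 80, 20)) is None

    def test_range_label_resolves_to_upper_bound(self):
        mask = render_text_mask("35-251")
        img = np.where(mask[..., None], 0, 255).astype(np.uint8).repeat(3, axis=2)
        assert recognize_number(img, (0, 0, img.shape[1], img.shape[0])) == 251


class TestAxisCalibration:
    def test_threshold_row_matches_sidecar(self, rendered):
        image, sidecar = rendered
        geo = locate_threshold_row(image, PARAMS)
        assert geo.threshold_row == pytest.approx(sidecar.threshold_row_q20, abs=1)

    def test_offgrid_threshold_interpolates_between_flanking_ticks(self, rendered):
        image, sidecar = rendered
        geo = locate_threshold_row(image, VisionParams(quality_threshold=21))
        mid = (sidecar.y_tick_rows[20.0] + sidecar.y_tick_rows[22.0]) / 2
        assert geo.threshold_row == pytest.approx(mid, abs=1)

    def test_y_ticks_decrease_in_row_as_score_increases(self, rendered):
        image, _ = rendered
        geo = locate_threshold_row(image, PARAMS)
        rows = [r for _, r in sorted(geo.y_ticks)]
        assert all(a > b for a, b in zip(rows, rows[1:]))

    def test_blank_image_fails_calibration(self):
        with pytest.raises(AxisCalibrationError):
            locate_threshold_row(uniform_image((255, 255, 255), (200, 200)), PARAMS)

    def test_x_ticks_match_sidecar(self, rendered):
        image, sidecar = rendered
        geo = calibrate_x_axis(image, PARAMS, locate_threshold_row(image, PARAMS))
        recovered = dict(geo.x_ticks)
        assert set(recovered) == set(sidecar.x_tick_cols)
        for pos, col in sidecar.x_tick_cols.items():
            assert recovered[pos] == pytest.approx(col, abs=2)

    def test_erased_x_labels_fail_calibration(self, rendered):
        image, sidecar = rendered
        img = image.copy()
        img[sidecar.plot_box[3] + 1 :, :] = 255
        with pytest.raises(AxisCalibrationError):
            calibrate_x_axis(img, PARAMS, locate_threshold_row(img, PARAMS))

    def test_range_labeled_ticks_calibrate_too(self, noiseless_profile):
        """Binned "A-B" x labels resolve to B and still anchor the axis."""
        image, sidecar = render_plot(
            noiseless_profile, RenderStyle(range_x_labels=True)
        )
        geo = calibrate_x_axis(image, PARAMS, locate_threshold_row(image, PARAMS))
        recovered = dict(geo.x_ticks)
        for pos, col in sidecar.x_tick_cols.items():
            assert recovered[pos] == pytest.approx(col, abs=2)


class TestPixelToPosition:
    @pytest.fixture(scope="class")
    @staticmethod
    def geometry(rendered):
        image, _ = rendered
        return calibrate_x_axis(image, PARAMS, locate_threshold_row(image, PARAMS))

    def test_tick_columns_are_anchors(self, rendered, geometry):
        _, sidecar = rendered
        for pos, col in sidecar.x_tick_cols.items():
            assert pixel_to_position(col, geometry) == pos

    def test_midpoint_between_ticks(self, rendered, geometry):
        _, sidecar = rendered
        mid = (sidecar.x_tick_cols[50] + sidecar.x_tick_cols[100]) / 2
        assert pixel_to_position(mid, geometry) == pytest.approx(75, abs=1)

    def test_column_outside_plot_box_raises(self, geometry):
        with pytest.raises(ValueError):
            pixel_to_position(geometry.plot_box[0] - 20, geometry)


class TestScanTransition:
    @staticmethod
    def predict_position(profile, threshold=20.0):
        image, sidecar = render_plot(profile, RenderStyle())
        params = VisionParams(quality_threshold=threshold)
        cm = build_color_map(image, params)
        geo = calibrate_x_axis(image, params, locate_threshold_row(image, params))
        res = scan_transition(image, geo, cm, params)
        return res, geo, sidecar

    def test_crossing_recovered_within_one_bin(self, noiseless_profile):
        res, geo, sidecar = self.predict_position(noiseless_profile)
        assert res.status == "found"
        pos = pixel_to_position(res.transition_column, geo)
        assert abs(pos - sidecar.ground_truth_truncation) <= 5

    def test_flat_high_quality_never_below(self):
        profile = simulate_profile(
            ProfileSpec(read_length=250, plateau_q=39, decay_start=250,
                        decay_rate=0.0, noise_sd=0.0, seed=3)
        )
        res, _, _ = self.predict_position(profile)
        assert res.status == "never_below"

    def test_flat_low_quality_always_below(self):
        profile = simulate_profile(
            ProfileSpec(read_length=250, plateau_q=8, decay_start=250,
                        decay_rate=0.0, noise_sd=0.0, iqr_half_width=2, seed=3)
        )
        res, _, _ = self.predict_position(profile)
        assert res.status == "always_below"

    def test_found_transition_inside_plot_box(self, noiseless_profile):
        res, geo, _ = self.predict_position(noiseless_profile)
        left, _, right, _ = geo.plot_box
        assert left <= res.transition_column <= right

    def test_lowering_threshold_never_trims_more(self, noiseless_profile):
        """Lower quality bar -> keep at least as many bases."""
        positions = []
        for t in (30, 25, 20, 15):
            res, geo, _ = self.predict_position(noiseless_profile, threshold=t)
            assert res.status == "found"
            positions.append(pixel_to_position(res.transition_column, geo))
        assert positions == sorted(positions)
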