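"""Signal-extraction chain: Otsu, illumination, zones, detection."""
import numpy as np
import pytest

from lfaquant import (Box, SimulationConfig, StripImage, correct_illumination,
                      detect_zones, green_plane, otsu_threshold, quantify_zone,
                      render_strip, strip_signals)
from lfaquant.errors import (CorrectionError, DegenerateInputError,
                             DetectionError, FormatError, NoSpotError)
from lfaquant.quantify import ChannelSignal, StripResult, ZoneQuant


def brute_force_otsu(hist):
    """Independent oracle: exhaustive between-class-variance scan."""
    hist = np.asarray(hist, dtype=float)
    total = hist.sum()
    levels = np.arange(256)
    best_t, best_v = None, -np.inf
    for t in range(1, 256):
        w0 = hist[:t].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[:t] * levels[:t]).sum() / w0
        mu1 = (hist[t:] * levels[t:]).sum() / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v:  # strict: keeps the lowest tied level
            best_t, best_v = t, v
    return best_t


class TestOtsu:
    def test_perfect_bimodal_tie_breaks_low(self):
        hist = np.zeros(256)
        hist[10] = 50
        hist[200] = 50
        assert otsu_threshold(hist) == 11

    def test_matches_exhaustive_scan_on_random_histograms(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            hist = rng.integers(0, 50, size=256)
            hist[rng.random(256) < 0.7] = 0
            if np.count_nonzero(hist) < 2:
                continue
            assert otsu_threshold(hist) == brute_force_otsu(hist)

    def test_single_level_histogram_is_degenerate(self):
        hist = np.zeros(256)
        hist[42] = 100
        with pytest.raises(DegenerateInputError):
            otsu_threshold(hist)

    def test_bad_histograms_rejected(self):
        with pytest.raises(FormatError):
            otsu_threshold(np.zeros(100))
        h = np.zeros(256)
        h[0], h[1] = 1, -1
        with pytest.raises(FormatError):
            otsu_threshold(h)


class TestGreenPlane:
    def test_extracts_green_component(self):
        px = np.zeros((2, 2, 3), dtype=np.uint8)
        px[0, 0] = (10, 200, 30)
        assert green_plane(StripImage(px))[0, 0] == 200.0

    def test_all_green_image_is_identity(self):
        px = np.zeros((4, 5, 3), dtype=np.uint8)
        px[:, :, 1] = np.arange(20).reshape(4, 5)
        np.testing.assert_array_equal(green_plane(px), px[:, :, 1])

    def test_grayscale_rejected(self):
        with pytest.raises(FormatError):
            green_plane(np.zeros((4, 5), dtype=np.uint8))


class TestIlluminationCorrection:
    points = [(5, 5), (5, 55), (35, 5), (35, 55), (20, 30)]

    def test_flat_field_unchanged(self):
        plane = np.full((40, 60), 180.0)
        out = correct_illumination(plane, self.points)
        np.testing.assert_allclose(out, plane, rtol=1e-12)

    def test_removes_injected_linear_gradient(self):
        cc, rr = np.meshgrid(np.arange(60), np.arange(40))
        gradient = 1.0 + 0.002 * cc + 0.001 * rr
        plane = 180.0 * gradient
        out = correct_illumination(plane, self.points)
        residual_slope = np.abs(np.diff(out, axis=1)).max()
        injected_slope = 180.0 * 0.002
        assert residual_slope < 0.01 * injected_slope

    def test_idempotent_on_own_output(self):
        cc, rr = np.meshgrid(np.arange(60), np.arange(40))
        plane = 150.0 * (1.0 + 0.003 * cc - 0.001 * rr)
        once = correct_illumination(plane, self.points)
        twice = correct_illumination(once, self.points)
        np.testing.assert_allclose(twice, once, rtol=1e-9)

    def test_too_few_or_collinear_points_rejected(self):
        plane = np.full((40, 60), 100.0)
        with pytest.raises(CorrectionError):
            correct_illumination(plane, [(5, 5), (10, 10)])
        with pytest.raises(CorrectionError):
            correct_illumination(plane, [(5, 5), (5, 20), (5, 40)])


class TestQuantifyZone:
    def _plane(self, bg=150.0, spot=100.0):
        plane = np.full((30, 80), bg)
        rr, cc = np.mgrid[0:30, 0:80]
        plane[np.hypot(rr - 15, cc - 55) <= 8] = spot
        return plane

    def test_exact_signal_on_synthetic_zone(self):
        plane = self._plane()
        zq = quantify_zone(plane, Box(0, 40, 30, 70), Box(0, 0, 30, 30))
        assert zq.signal == pytest.approx(50.0)
        assert zq.spot_mean == pytest.approx(100.0)
        assert zq.reference_mean == pytest.approx(150.0)

    def test_invariant_under_constant_offset(self):
        plane = self._plane()
        zq0 = quantify_zone(plane, Box(0, 40, 30, 70), Box(0, 0, 30, 30))
        zq1 = quantify_zone(plane + 30.0, Box(0, 40, 30, 70), Box(0, 0, 30, 30))
        assert zq1.signal == pytest.approx(zq0.signal)
        assert zq1.n_spot_pixels == zq0.n_spot_pixels

    def test_blank_zone_raises_or_flags(self):
        plane = np.full((30, 80), 150.0)
        with pytest.raises(NoSpotError):
            quantify_zone(plane, Box(0, 40, 30, 70), Box(0, 0, 30, 30))
        zq = quantify_zone(plane, Box(0, 40, 30, 70), Box(0, 0, 30, 30),
                           on_blank="zero")
        assert zq.signal == 0.0 and zq.negative_flag


class TestDetectZones:
    def test_zero_offset_recovers_layout(self, exact_records, layout):
        img, _ = exact_records[0]
        zones, offset = detect_zones(img, layout)
        assert offset == (0, 0)
        assert zones == layout.zones

    def test_known_translation_recovered(self, layout):
        cfg = SimulationConfig(noise_sd=1.0, seed=2)
        img, _ = render_strip(cfg, layout, 10.0)
        shifted = np.roll(img.pixels, (5, -3), axis=(0, 1))
        _, offset = detect_zones(StripImage(shifted), layout)
        assert offset == (5, -3)

    def test_masked_fiducials_raise(self, layout, exact_records):
        img, _ = exact_records[0]
        px = img.pixels.copy()
        px[layout.fiducial_mask()] = 210  # paint barriers over
        with pytest.raises(DetectionError):
            detect_zones(StripImage(px), layout)


class TestStripSignals:
    def test_identical_channels_have_zero_sd(self, exact_records, layout):
        img, _ = exact_records[0]
        res = strip_signals(img, layout)
        assert len(res.channels) == 4
        assert res.sd_ratio == pytest.approx(0.0, abs=1e-4)

    def test_mean_of_ratios_is_arithmetic(self):
        def chan(i, ratio):
            t = ZoneQuant(i, "test", 100.0, 150.0, 50.0 * ratio, 10, 120)
            c = ZoneQuant(i, "control", 100.0, 150.0, 50.0, 10, 120)
            return ChannelSignal(i, t, c)
        res = StripResult("s", [chan(i, r) for i, r in
                                enumerate([1.0, 1.0, 1.0, 0.8])])
        assert res.mean_ratio == pytest.approx(0.95)

    def test_noise_free_pipeline_reproduces_ground_truth(self, exact_records,
                                                         layout):
        """Idealized renders: signals match the sidecar to < 0.5 units."""
        for img, truth in exact_records:
            res = strip_signals(img, layout, strip_id=truth["strip_id"])
            for ch, cs in zip(truth["channels"], res.channels):
                assert cs.test_signal == pytest.approx(ch["test_signal"],
                                                       abs=0.5)
                assert cs.control_signal == pytest.approx(
                    ch["control_signal"], abs=0.5)

    def test_soft_edge_render_nearly_preserves_ratio(self, layout):
        """Soft spot edges bias absolute signals by a few percent, but the
        test/control ratio only at the 0.2% level (edge pixels enter both
        spots alike)."""
        cfg = SimulationConfig(noise_sd=0.0, edge_sigma=1.2)
        img, truth = render_strip(cfg, layout, 30.0)
        res = strip_signals(img, layout)
        truth_ratio = truth["channels"][0]["ratio"]
        assert res.mean_ratio == pytest.approx(truth_ratio, abs=2e-3)
        # the absolute test signal is biased far more than the ratio
        signal_bias = abs(res.channels[0].test_signal
                          - truth["channels"][0]["test_signal"])
        ratio_bias = abs(res.mean_ratio - truth_ratio) / truth_ratio
        assert ratio_bias < signal_bias / truth["channels"][0]["test_signal"]

    def test_noisy_strip_mean_near_truth(self, layout):
        cfg = SimulationConfig(noise_sd=2.0, seed=8)
        ratios = []
        truth_ratio = None
        for seed in range(10):
            cfg.seed = seed
            img, truth = render_strip(cfg, layout, 100.0)
            ratios.append(strip_signals(img, layout).mean_ratio)
            truth_ratio = truth["channels"][0]["ratio"]
        se = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
        assert np.mean(ratios) == pytest.approx(truth_ratio,
                                                abs=max(3 * se, 2e-3))
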