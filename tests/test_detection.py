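"""Detector tests: brute-force oracles on tiny images, localisation
accuracy, sensitivity monotonicity, and serialization."""

import numpy as np
import pytest
from scipy import ndimage

from ishprofiler import (
    AUTO,
    Detection,
    DetectionParams,
    Palette,
    SyntheticSpec,
    detect_circles,
    edge_map,
    read_detections,
    render_core,
    write_detections,
)
from ishprofiler.detection import SENSITIVITY_DEFAULTS
from tests.conftest import match_detections

PALETTE = Palette()


def draw_disc(image, x, y, radius, colour):
    """Hard-edged disc, used as a simple ground-truth stimulus."""
    h, w = image.shape[:2]
    yy, xx = np.mgrid[:h, :w]
    image[(xx - x) ** 2 + (yy - y) ** 2 <= radius ** 2] = colour
    return image


def blank(side=64):
    out = np.empty((side, side, 3), dtype=np.uint8)
    out[:] = PALETTE.background
    return out


class TestEdgeMap:
    def test_constant_image_has_no_edges(self):
        assert not edge_map(blank()).any()

    def test_otsu_matches_brute_force_threshold(self):
        """AUTO mode must equal an exhaustive inter-class-variance search
        over the same 256-bin histogram of gradient magnitudes."""
        image = blank(48)
        draw_disc(image, 20, 24, 4, PALETTE.pten)
        draw_disc(image, 36, 12, 3, PALETTE.cep10)

        lum = (0.299 * image[..., 0] + 0.587 * image[..., 1]
               + 0.114 * image[..., 2]).astype(float)
        gy = ndimage.sobel(lum, axis=0)
        gx = ndimage.sobel(lum, axis=1)
        grad = np.hypot(gx, gy)

        counts, edges_ = np.histogram(grad.ravel(), bins=256)
        mids = (edges_[:-1] + edges_[1:]) / 2
        best_var, best_thr = -1.0, mids[0]
        for k in range(1, 256):
            w0, w1 = counts[:k].sum(), counts[k:].sum()
            if w0 == 0 or w1 == 0:
                continue
            m0 = (counts[:k] * mids[:k]).sum() / w0
            m1 = (counts[k:] * mids[k:]).sum() / w1
            var = w0 * w1 * (m0 - m1) ** 2
            if var > best_var:
                best_var, best_thr = var, mids[k - 1]
        assert np.array_equal(edge_map(image), grad > best_thr)

    def test_explicit_threshold_is_strict(self):
        image = blank(32)
        draw_disc(image, 16, 16, 4, PALETTE.pten)
        zero_thr = edge_map(image, edge_threshold=0.0)
        high_thr = edge_map(image, edge_threshold=1e9)
        assert zero_thr.sum() > 0
        assert high_thr.sum() == 0

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            edge_map(blank(), edge_threshold="fancy")


class TestDetectCircles:
    def test_blank_image_yields_nothing(self):
        assert detect_circles(blank()) == []

    @pytest.mark.parametrize("radius", [2, 4, 7])
    def test_single_disc_found_accurately(self, radius):
        image = blank(64)
        draw_disc(image, 30, 33, radius, PALETTE.pten)
        dets = detect_circles(image)
        assert len(dets) == 1
        d = dets[0]
        assert abs(d.x - 30) <= 1.0 and abs(d.y - 33) <= 1.0
        assert abs(d.radius - radius) <= 1.0

    def test_matched_filter_oracle_on_tiny_image(self):
        """On a 64 px image with well-separated hard discs, the detector
        must agree with a brute-force normalised matched filter: one
        detection within 1.5 px of each template-correlation optimum."""
        truth = [(14, 14, 3), (45, 18, 5), (22, 46, 2)]
        image = blank(64)
        for x, y, r in truth:
            draw_disc(image, x, y, r, PALETTE.pten)
        lum = (0.299 * image[..., 0] + 0.587 * image[..., 1]
               + 0.114 * image[..., 2]).astype(float)
        inv = 255.0 - lum

        oracle = []
        for x0, y0, r in truth:
            yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
            template = (xx ** 2 + yy ** 2 <= r ** 2).astype(float)
            template -= template.mean()
            best, best_xy = -np.inf, None
            for y in range(r, 64 - r):
                for x in range(r, 64 - r):
                    if abs(x - x0) > 3 or abs(y - y0) > 3:
                        continue
                    win = inv[y - r:y + r + 1, x - r:x + r + 1]
                    score = float((win * template).sum())
                    if score > best:
                        best, best_xy = score, (x, y)
            oracle.append(best_xy)

        dets = detect_circles(image)
        assert len(dets) == len(truth)
        tp, recall, precision = match_detections(
            oracle, [(d.x, d.y) for d in dets], tol=1.5)
        assert recall == 1.0 and precision == 1.0

    def test_translation_equivariance(self):
        """Shifting the stimulus by whole pixels shifts the detection by
        the same amount to within 0.5 px."""
        base = blank(96)
        draw_disc(base, 30, 40, 4, PALETTE.pten)
        shifted = blank(96)
        draw_disc(shifted, 30 + 17, 40 + 9, 4, PALETTE.pten)
        (d0,) = detect_circles(base)
        (d1,) = detect_circles(shifted)
        assert abs((d1.x - d0.x) - 17) <= 0.5
        assert abs((d1.y - d0.y) - 9) <= 0.5

    def test_both_colours_detected_in_one_pass(self):
        image = blank(96)
        draw_disc(image, 25, 25, 4, PALETTE.pten)
        draw_disc(image, 70, 60, 4, PALETTE.cep10)
        dets = detect_circles(image)
        assert len(dets) == 2

    def test_sensitivity_monotone_in_detection_count(self):
        image, _ = render_core(
            SyntheticSpec(image_side=512, n_pten=20, n_cep10=40, seed=3))
        counts = [
            len(detect_circles(image, DetectionParams(sensitivity=s)))
            for s in (0.5, 0.85, 0.95)
        ]
        assert counts[0] <= counts[1] <= counts[2]

    def test_profile_defaults_match_explicit_sensitivity(self):
        from ishprofiler import CoreImage
        image, _ = render_core(
            SyntheticSpec(image_side=256, n_pten=5, n_cep10=10, seed=8))
        for profile, s in SENSITIVITY_DEFAULTS.items():
            implicit = detect_circles(CoreImage(image, scanner_profile=profile))
            explicit = detect_circles(image, DetectionParams(sensitivity=s))
            assert implicit == explicit

    def test_image_smaller_than_diameter_rejected(self):
        with pytest.raises(ValueError, match="radius_max"):
            detect_circles(np.zeros((10, 64, 3), dtype=np.uint8))

    def test_near_border_flagged(self):
        image = blank(64)
        draw_disc(image, 5, 32, 3, PALETTE.pten)
        draw_disc(image, 32, 32, 3, PALETTE.pten)
        dets = {round(d.x): d for d in detect_circles(image)}
        assert dets[5].near_border
        assert not dets[32].near_border

    def test_min_centre_distance_suppresses_close_pair(self):
        image = blank(64)
        draw_disc(image, 30, 30, 2, PALETTE.pten)
        draw_disc(image, 34, 30, 2, PALETTE.pten)
        wide = detect_circles(image, DetectionParams(min_centre_distance=10.0))
        assert len(wide) == 1

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            DetectionParams(radius_min=0)
        with pytest.raises(ValueError):
            DetectionParams(radius_min=5, radius_max=3)
        with pytest.raises(ValueError):
            DetectionParams(sensitivity=1.5)
        with pytest.raises(ValueError):
            DetectionParams(min_centre_distance=0.0)


class TestOnSyntheticCore:
    def test_recall_and_precision_on_small_core(self, small_core):
        image, truth = small_core
        dets = detect_circles(image)
        _, recall, precision = match_detections(
            [(s.x, s.y) for s in truth.signals],
            [(d.x, d.y) for d in dets], tol=2.0)
        assert recall >= 0.9
        assert precision >= 0.9

    def test_radius_estimates_close_to_truth(self, small_core):
        image, truth = small_core
        dets = detect_circles(image)
        from scipy.spatial import cKDTree
        truth_xy = np.array([(s.x, s.y) for s in truth.signals])
        tree = cKDTree(truth_xy)
        errs = []
        for d in dets:
            dist, idx = tree.query([d.x, d.y])
            if dist <= 2.0:
                errs.append(abs(d.radius - truth.signals[idx].radius))
        assert np.mean(errs) <= 1.0


class TestDetectionIO:
    def test_round_trip(self, tmp_path):
        dets = [
            Detection(1.25, 2.5, 3.0, 0.9, False),
            Detection(10.0, 20.0, 1.5, 0.4, True),
        ]
        path = tmp_path / "dets.tsv"
        write_detections(dets, path)
        back = read_detections(path)
        assert back == dets
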