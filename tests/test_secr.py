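"""Detector construction, capture histories, and the SECR likelihood."""

import math

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, Polygon

from scatcap.secr import (
    CaptureHistory,
    DetectorArray,
    HabitatMask,
    assign_detections,
    build_mask,
    fit_secr,
    halfnormal_detect,
    secr_loglik,
    segment_transects,
)


class TestSegmentation:
    def test_straight_km_line_five_detectors(self):
        line = LineString([(0, 0), (1000, 0)])
        det = segment_transects([line], 200.0)
        assert len(det) == 5
        assert np.allclose(det.coords[:, 0], [100, 300, 500, 700, 900])

    def test_short_remainder_merges_into_previous(self):
        line = LineString([(0, 0), (500, 0)])
        det = segment_transects([line], 200.0)
        # 200 + 200 + 100 -> the 100 m remainder merges: midpoints 100, 350
        assert np.allclose(det.coords[:, 0], [100, 350])

    def test_long_remainder_kept(self):
        line = LineString([(0, 0), (550, 0)])
        det = segment_transects([line], 200.0)
        assert np.allclose(det.coords[:, 0], [100, 300, 475])

    def test_zero_length_polyline_skipped(self):
        good = LineString([(0, 0), (400, 0)])
        degenerate = LineString([(5, 5), (5, 5)])
        with pytest.warns(UserWarning, match="zero length"):
            det = segment_transects([degenerate, good], 200.0)
        assert len(det) == 2

    def test_polyline_measured_along_path(self):
        # an L-shaped 400 m path: detectors at path distance 100 and 300
        line = LineString([(0, 0), (200, 0), (200, 200)])
        det = segment_transects([line], 200.0)
        assert np.allclose(det.coords, [[100, 0], [200, 100]])


def _toy_detectors():
    return segment_transects([LineString([(0, 0), (1000, 0)])], 200.0)


class TestAssignment:
    def test_nearest_detector_wins(self):
        det = _toy_detectors()
        d = pd.DataFrame({"scat_id": ["a"], "x": [110.0], "y": [10.0], "occasion": [1]})
        hist = assign_detections(d, det, {"a": "I1"})
        assert hist.omega[0, 0, 0] == 1
        assert hist.omega.sum() == 1

    def test_binary_collapse_same_cell(self):
        det = _toy_detectors()
        d = pd.DataFrame(
            {
                "scat_id": ["a", "b"],
                "x": [100.0, 105.0],
                "y": [0.0, 5.0],
                "occasion": [1, 1],
            }
        )
        hist = assign_detections(d, det, {"a": "I1", "b": "I1"})
        assert hist.omega.sum() == 1

    def test_equidistant_goes_to_lowest_id(self):
        det = _toy_detectors()
        d = pd.DataFrame({"scat_id": ["a"], "x": [200.0], "y": [0.0], "occasion": [1]})
        hist = assign_detections(d, det, {"a": "I1"})
        assert hist.omega[0, 0, 0] == 1  # detector 0 at x=100, not 1 at x=300

    def test_far_scat_dropped_with_warning(self):
        det = _toy_detectors()
        d = pd.DataFrame(
            {"scat_id": ["a", "b"], "x": [100.0, 100.0], "y": [0.0, 5000.0],
             "occasion": [1, 1]}
        )
        with pytest.warns(UserWarning, match="dropped"):
            hist = assign_detections(d, det, {"a": "I1", "b": "I2"})
        assert hist.n == 1


class TestHalfNormal:
    def test_at_zero_distance(self):
        assert halfnormal_detect(0.0, 0.3, 500.0) == pytest.approx(0.3)

    def test_at_one_sigma(self):
        assert halfnormal_detect(500.0, 0.3, 500.0) == pytest.approx(
            0.3 * math.exp(-0.5)
        )

    def test_strictly_decreasing(self):
        d = np.linspace(0, 3000, 50)
        p = halfnormal_detect(d, 0.3, 500.0)
        assert np.all(np.diff(p) < 0)

    @pytest.mark.parametrize("bad", [(-1.0, 0.3, 500.0), (0.0, 0.3, -5.0), (0.0, 1.5, 500.0)])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            halfnormal_detect(*bad)


def _brute_force_3cell(D, g0, sigma, cell_area, mask_pts, det_xy, omega, K):
    """Independent arithmetic for one detector, one individual."""
    total_pdot = 0.0
    esa_terms = []
    for (mx, my) in mask_pts:
        d = math.hypot(mx - det_xy[0], my - det_xy[1])
        p = g0 * math.exp(-d * d / (2 * sigma * sigma))
        pdot = 1.0 - (1.0 - p) ** K
        total_pdot += pdot
        pr = 1.0
        for k in range(K):
            pr *= p if omega[k] else (1.0 - p)
        esa_terms.append(pr)
    term1 = -D * cell_area * total_pdot
    term2 = math.log(D * cell_area * sum(esa_terms))
    return term1 + term2


class TestLikelihood:
    def test_three_cell_brute_force(self):
        mask_pts = [(0.0, 0.0), (250.0, 0.0), (500.0, 0.0)]
        det_xy = (100.0, 0.0)
        K = 1
        omega = [1]
        mask = HabitatMask(points=np.array(mask_pts), cell_area_ha=6.25)
        detectors = DetectorArray(
            ids=[0], coords=np.array([det_xy]), transect_index=np.array([0]),
            section_length=200.0,
        )
        hist = CaptureHistory(["I1"], np.array([[[1]]], dtype=np.int8), n_occasions=1)
        params = (0.004, 0.3, 300.0)
        expected = _brute_force_3cell(*params, 6.25, mask_pts, det_xy, omega, K)
        got = secr_loglik(params, hist, detectors, mask)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_detector_relabeling_invariance(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 1000, size=(6, 2))
        mask = HabitatMask(points=rng.uniform(-500, 1500, size=(40, 2)), cell_area_ha=4.0)
        omega = (rng.random((3, 6, 2)) < 0.3).astype(np.int8)
        hist = CaptureHistory(["a", "b", "c"], omega, 2)
        base = DetectorArray(list(range(6)), coords, np.zeros(6, int), 200.0)
        perm = rng.permutation(6)
        permuted = DetectorArray(list(range(6)), coords[perm], np.zeros(6, int), 200.0)
        hist_perm = CaptureHistory(["a", "b", "c"], omega[:, perm, :], 2)
        p = (0.01, 0.2, 400.0)
        assert secr_loglik(p, hist, base, mask) == pytest.approx(
            secr_loglik(p, hist_perm, permuted, mask), rel=1e-12
        )

    def test_mesh_refinement_stability(self):
        # halving the cell size over the same region barely moves log L
        # at survey-scale sigma
        habitat = Polygon([(0, 0), (4000, 0), (4000, 4000), (0, 4000)])
        detectors = segment_transects(
            [LineString([(1000, 2000), (3000, 2000)])], 200.0
        )
        omega = np.zeros((2, len(detectors), 2), dtype=np.int8)
        omega[0, 2, 0] = omega[0, 3, 1] = 1
        omega[1, 7, 0] = 1
        hist = CaptureHistory(["a", "b"], omega, 2)
        p = (0.002, 0.2, 772.9)
        lls = []
        for res in (500.0, 250.0):
            mask = build_mask(habitat, detectors, resolution=res)
            lls.append(secr_loglik(p, hist, detectors, mask))
        assert abs(lls[0] - lls[1]) < 0.01


@pytest.fixture(scope="module")
def sim_fit():
    from scatcap.simulate import (
        default_geometry,
        draw_activity_centers,
        simulate_survey,
    )

    geom = default_geometry()
    detectors = segment_transects(geom.transects, 200.0)
    mask = build_mask(geom.habitat, detectors, resolution=500.0)
    rng = np.random.default_rng(42)
    centers = draw_activity_centers(9, geom.habitat, rng)
    det, truth = simulate_survey(
        centers, [f"I{i}" for i in range(9)], detectors, 0.16, 700.0, 2, rng
    )
    hist = assign_detections(det, detectors, truth, n_occasions=2)
    fit = fit_secr(hist, detectors, mask)
    return hist, detectors, mask, fit


class TestFit:
    def test_abundance_at_least_observed(self, sim_fit):
        hist, _, _, fit = sim_fit
        assert fit.n_hat >= hist.n

    def test_mle_dominates_random_parameters(self, sim_fit):
        hist, detectors, mask, fit = sim_fit
        rng = np.random.default_rng(7)
        for _ in range(100):
            cand = (
                float(rng.uniform(1e-4, 0.05)),
                float(rng.uniform(0.01, 0.9)),
                float(rng.uniform(100, 3000)),
            )
            assert fit.loglik >= secr_loglik(cand, hist, detectors, mask) - 1e-6

    def test_buffer_extension_stability(self, sim_fit):
        # activity centers beyond ~4 sigma are effectively undetectable,
        # so enlarging the buffer must leave the density MLE unchanged
        hist, detectors, _, fit = sim_fit
        m1 = build_mask(None, detectors, resolution=500.0, buffer=4 * 700.0)
        m2 = build_mask(None, detectors, resolution=500.0, buffer=8 * 700.0)
        f1 = fit_secr(hist, detectors, m1)
        f2 = fit_secr(hist, detectors, m2)
        assert f2.density == pytest.approx(f1.density, rel=0.02)
        assert f2.sigma == pytest.approx(f1.sigma, rel=0.02)

    def test_reasonable_estimates(self, sim_fit):
        _, _, _, fit = sim_fit
        assert fit.converged
        assert 0 < fit.g0 < 1
        assert 100 < fit.sigma < 3000
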