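"""Evaluation statistics: closed forms, brute-force oracles, invariances."""

import numpy as np
import pytest

from leukoseg.metrics import (
    EvalReport,
    aggregate,
    boundary_points,
    detection_ratios,
    dice,
    evaluate_masks,
    hausdorff,
    match_detections,
    pixel_rates,
    rde,
)


def mask_from_points(points, shape=(20, 20)):
    m = np.zeros(shape, dtype=bool)
    for r, c in points:
        m[r, c] = True
    return m


def brute_hausdorff(a_pts, b_pts):
    d = np.linalg.norm(a_pts[:, None, :] - b_pts[None, :, :], axis=2)
    return max(d.min(axis=1).max(), d.min(axis=0).max())


def brute_rde(a_pts, b_pts, squared=True):
    d = np.linalg.norm(a_pts[:, None, :] - b_pts[None, :, :], axis=2)
    de, dt = d.min(axis=1), d.min(axis=0)
    if squared:
        de, dt = de**2, dt**2
    return 0.5 * (de.mean() + dt.mean())


def random_blob_pair(rng, shape=(30, 30)):
    while True:
        a = np.zeros(shape, dtype=bool)
        b = np.zeros(shape, dtype=bool)
        for m in (a, b):
            r, c = rng.integers(5, 25, size=2)
            rad = rng.integers(2, 6)
            yy, xx = np.ogrid[: shape[0], : shape[1]]
            m |= (yy - r) ** 2 + (xx - c) ** 2 <= rad**2
        if a.any() and b.any():
            return a, b


class TestBoundary:
    def test_boundary_of_solid_square(self):
        m = np.zeros((10, 10), dtype=bool)
        m[3:7, 3:7] = True
        pts = {tuple(p) for p in boundary_points(m)}
        interior = {(r, c) for r in (4, 5) for c in (4, 5)}
        full = {(r, c) for r in range(3, 7) for c in range(3, 7)}
        assert pts == full - interior

    def test_single_pixel_is_its_own_boundary(self):
        m = mask_from_points([(4, 4)])
        assert [tuple(p) for p in boundary_points(m)] == [(4, 4)]

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            boundary_points(np.zeros((5, 5), dtype=bool))


class TestHausdorff:
    def test_identical_masks_zero(self, rng):
        a, _ = random_blob_pair(rng)
        assert hausdorff(a, a) == 0.0

    def test_single_pixel_pair_is_euclidean(self):
        assert hausdorff(mask_from_points([(0, 0)]), mask_from_points([(3, 4)])) == 5.0

    def test_matches_brute_force(self, rng):
        for _ in range(25):
            a, b = random_blob_pair(rng)
            expect = brute_hausdorff(
                boundary_points(a).astype(float), boundary_points(b).astype(float)
            )
            assert hausdorff(a, b) == pytest.approx(expect, abs=1e-12)

    def test_symmetric(self, rng):
        a, b = random_blob_pair(rng)
        assert hausdorff(a, b) == hausdorff(b, a)

    def test_translation_invariant(self):
        a = mask_from_points([(2, 2), (2, 3), (3, 2)])
        b = mask_from_points([(5, 6), (6, 5)])
        a2 = mask_from_points([(7, 9), (7, 10), (8, 9)])
        b2 = mask_from_points([(10, 13), (11, 12)])
        assert hausdorff(a, b) == pytest.approx(hausdorff(a2, b2))

    def test_empty_mask_rejected(self, rng):
        a, _ = random_blob_pair(rng)
        with pytest.raises(ValueError):
            hausdorff(a, np.zeros_like(a))


class TestRde:
    def test_identical_masks_zero(self, rng):
        a, _ = random_blob_pair(rng)
        assert rde(a, a) == 0.0

    def test_single_pixel_pair_squared(self):
        a, b = mask_from_points([(0, 0)]), mask_from_points([(3, 4)])
        assert rde(a, b) == 25.0
        assert rde(a, b, squared=False) == 5.0

    def test_matches_brute_force(self, rng):
        for _ in range(25):
            a, b = random_blob_pair(rng)
            pa = boundary_points(a).astype(float)
            pb = boundary_points(b).astype(float)
            assert rde(a, b) == pytest.approx(brute_rde(pa, pb), abs=1e-10)
            assert rde(a, b, squared=False) == pytest.approx(
                brute_rde(pa, pb, squared=False), abs=1e-10
            )

    def test_symmetric_and_nonnegative(self, rng):
        a, b = random_blob_pair(rng)
        assert rde(a, b) == rde(b, a)
        assert rde(a, b) >= 0.0
        assert (rde(a, b) == 0.0) == np.array_equal(
            sorted(map(tuple, boundary_points(a))), sorted(map(tuple, boundary_points(b)))
        )


class TestPixelRates:
    def test_identical_masks(self, rng):
        a, _ = random_blob_pair(rng)
        assert pixel_rates(a, a) == (0.0, 0.0, 0.0)

    def test_pure_over_segmentation(self):
        truth = np.zeros((20, 20), dtype=bool)
        truth[0:10, 0:10] = True  # 100 px
        pred = truth.copy()
        pred[10, 0:10] = True  # +10 px
        over, under, err = pixel_rates(pred, truth)
        assert (over, under, err) == (0.10, 0.0, 0.10)

    def test_empty_prediction(self):
        truth = np.zeros((8, 8), dtype=bool)
        truth[2:4, 2:4] = True
        assert pixel_rates(np.zeros_like(truth), truth) == (0.0, 1.0, 1.0)

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            pixel_rates(np.ones((4, 4), bool), np.zeros((4, 4), bool))

    def test_asymmetric(self):
        truth = np.zeros((10, 10), dtype=bool)
        truth[0:5] = True
        pred = np.zeros_like(truth)
        pred[0:6] = True
        assert pixel_rates(pred, truth) != pixel_rates(truth, pred)


class TestDetection:
    def test_perfect_match(self, rng):
        a, _ = random_blob_pair(rng)
        assert match_detections(a, a) == (1, 1, 1)

    def test_extra_speck_counts_as_false_detection(self):
        truth = np.zeros((40, 40), dtype=bool)
        truth[5:15, 5:15] = True
        truth[25:35, 25:35] = True
        pred = truth.copy()
        pred[0, 39] = True
        assert match_detections(pred, truth) == (3, 2, 2)

    def test_one_to_one_matching(self):
        truth = np.zeros((30, 30), dtype=bool)
        truth[5:25, 5:25] = True
        pred = np.zeros_like(truth)
        pred[5:25, 5:14] = True   # two predicted pieces over one truth cell
        pred[5:25, 16:25] = True
        n_det, n_cor, n_tru = match_detections(pred, truth, iou_min=0.2)
        assert (n_det, n_tru) == (2, 1)
        assert n_cor <= 1

    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((20, 19, 21), (0.95, 20 / 21)),
            ((5, 5, 5), (1.0, 1.0)),
            ((0, 0, 5), (0.0, 0.0)),
            ((0, 0, 0), (1.0, 1.0)),
        ],
    )
    def test_detection_ratios(self, counts, expected):
        a1, a2, e1, e2 = detection_ratios(*counts)
        assert (a1, a2) == pytest.approx(expected)
        assert e1 == 1 - a1 and e2 == 1 - a2


class TestReportsAndAggregation:
    def test_single_report_aggregates_to_itself(self, rng):
        a, b = random_blob_pair(rng)
        rep = evaluate_masks(a, b)
        agg = aggregate([rep])
        assert agg.to_dict() == pytest.approx(rep.to_dict())

    def test_pooled_ratios_not_averaged(self):
        r1 = EvalReport(1, 1, 0, 0, 1.0, 0, 0, 0, 0.0, 2, 2, 2)
        r2 = EvalReport(0, 1, 1, 0, 1.0, 0, 0, 0, 0.0, 1, 0, 1)
        agg = aggregate([r1, r2])
        assert agg.A1 == pytest.approx(2 / 3)  # pooled 2/3, not mean(1, 0) = 0.5
        assert agg.n_detected == 3 and agg.n_correct == 2 and agg.n_truth == 3

    def test_distance_metrics_averaged(self):
        r1 = EvalReport(1, 1, 0, 0, 2.0, 0.1, 0.1, 0.2, 4.0, 1, 1, 1)
        r2 = EvalReport(1, 1, 0, 0, 4.0, 0.3, 0.1, 0.4, 8.0, 1, 1, 1)
        agg = aggregate([r1, r2])
        assert agg.D == 3.0 and agg.RDE == 6.0
        assert agg.ER == pytest.approx(0.3)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            aggregate([])

    def test_evaluate_masks_consistent_fields(self, rng):
        a, b = random_blob_pair(rng)
        rep = evaluate_masks(a, b)
        assert rep.E1 == 1 - rep.A1 and rep.E2 == 1 - rep.A2
        assert rep.ER == pytest.approx(rep.OR + rep.UR)


class TestDice:
    def test_anchors(self):
        m = np.zeros((6, 6), dtype=bool)
        m[1:4, 1:4] = True
        assert dice(m, m) == 1.0
        assert dice(m, np.zeros_like(m)) == 0.0
        assert dice(np.zeros_like(m), np.zeros_like(m)) == 1.0

    def test_half_overlap(self):
        a = np.zeros((4, 4), dtype=bool)
        b = np.zeros((4, 4), dtype=bool)
        a[0, :2] = True
        b[0, 1:3] = True
        assert dice(a, b) == pytest.approx(0.5)
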