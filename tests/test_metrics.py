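"""Metric correctness against O(n^2) brute-force oracles, closed-form hand
examples and the DSC/IoU identity; spacing covariance; empty-set flags."""

import numpy as np
import pytest

from esegnet.metrics import (asd, dsc, evaluate_case, extract_surface,
                             hausdorff, hd95, iou, aggregate_reports)


# -- independent O(n^2) oracles -------------------------------------------

def brute_directed(sx, sy):
    d = np.sqrt(((sx[:, None, :] - sy[None, :, :]) ** 2).sum(-1))
    return d.min(axis=1)


def brute_asd(sx, sy):
    dxy = brute_directed(sx, sy)
    dyx = brute_directed(sy, sx)
    return (dxy.sum() + dyx.sum()) / (len(dxy) + len(dyx))


def brute_hd95(sx, sy):
    dxy = brute_directed(sx, sy)
    dyx = brute_directed(sy, sx)
    return max(np.percentile(dxy, 95), np.percentile(dyx, 95))


def brute_surface(mask, cls, spacing):
    m = np.asarray(mask) == cls
    pts = []
    for idx in np.argwhere(m):
        for axis in range(m.ndim):
            for step in (-1, 1):
                nb = idx.copy()
                nb[axis] += step
                if (nb < 0).any() or (nb >= np.array(m.shape)).any() \
                        or not m[tuple(nb)]:
                    pts.append(idx * np.asarray(spacing))
                    break
            else:
                continue
            break
    return np.array(pts) if pts else np.empty((0, m.ndim))


def random_mask_pair(rng, shape, n_classes=3):
    a = rng.integers(0, n_classes, size=shape)
    b = a.copy()
    flip = rng.uniform(size=shape) < 0.2
    b[flip] = rng.integers(0, n_classes, size=int(flip.sum()))
    return a, b


# -- overlap metrics -------------------------------------------------------

class TestOverlap:
    def test_identical_masks(self):
        m = np.array([[0, 1], [1, 2]])
        assert dsc(m, m, 1) == 1.0
        assert iou(m, m, 2) == 1.0

    def test_hand_enumerated_half_overlap(self):
        pred = np.zeros((2, 2), int)
        gt = np.zeros((2, 2), int)
        pred[0, 0] = pred[0, 1] = 1           # X = {(0,0),(0,1)}
        gt[0, 1] = gt[1, 1] = 1               # Y = {(0,1),(1,1)}
        assert dsc(pred, gt, 1) == pytest.approx(0.5)
        assert iou(pred, gt, 1) == pytest.approx(1 / 3)

    def test_disjoint_sets(self):
        pred = np.array([[1, 0], [0, 0]])
        gt = np.array([[0, 0], [0, 1]])
        assert dsc(pred, gt, 1) == 0.0
        assert iou(pred, gt, 1) == 0.0

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            dsc(np.zeros((2, 2)), np.zeros((3, 3)), 1)

    def test_dsc_iou_identity_on_random_masks(self, rng):
        for _ in range(50):
            a, b = random_mask_pair(rng, (12, 12))
            for cls in (1, 2):
                j = iou(a, b, cls)
                assert dsc(a, b, cls) == pytest.approx(2 * j / (1 + j),
                                                       abs=1e-12)

    def test_symmetry(self, rng):
        a, b = random_mask_pair(rng, (10, 10))
        assert dsc(a, b, 1) == dsc(b, a, 1)
        assert iou(a, b, 1) == iou(b, a, 1)


# -- surfaces --------------------------------------------------------------

class TestSurface:
    def test_solid_square_boundary_is_ring(self):
        m = np.zeros((5, 5), int)
        m[1:4, 1:4] = 1
        pts = extract_surface(m, 1)
        assert len(pts) == 8  # all but the center
        assert [2, 2] not in pts.tolist()

    def test_single_pixel_is_its_own_boundary(self):
        m = np.zeros((3, 3), int)
        m[1, 1] = 1
        np.testing.assert_array_equal(extract_surface(m, 1), [[1, 1]])

    def test_full_grid_boundary_is_border_ring(self):
        m = np.ones((4, 6), int)
        pts = extract_surface(m, 1)
        expect = brute_surface(m, 1, (1, 1))
        assert sorted(map(tuple, pts)) == sorted(map(tuple, expect))

    def test_absent_class_gives_empty_set(self):
        assert extract_surface(np.zeros((4, 4), int), 1).size == 0

    def test_matches_brute_force_with_spacing(self, rng):
        spacing = (0.7, 1.9)
        for _ in range(10):
            a, _ = random_mask_pair(rng, (9, 9))
            pts = extract_surface(a, 1, spacing)
            expect = brute_surface(a, 1, spacing)
            assert sorted(map(tuple, np.round(pts, 9))) == \
                sorted(map(tuple, np.round(expect, 9)))


# -- surface distances -----------------------------------------------------

class TestSurfaceDistances:
    def test_identical_sets_are_zero(self, rng):
        s = rng.uniform(size=(20, 2))
        assert asd(s, s) == 0.0
        assert hd95(s, s) == 0.0

    def test_1d_hand_example(self):
        assert asd(np.array([[0.0]]), np.array([[3.0]])) == pytest.approx(3.0)

    def test_asd_matches_brute_force(self, rng):
        sx = rng.uniform(0, 10, size=(50, 3))
        sy = rng.uniform(0, 10, size=(40, 3))
        assert asd(sx, sy) == pytest.approx(brute_asd(sx, sy), abs=1e-9)

    def test_hd95_matches_brute_force(self, rng):
        sx = rng.uniform(0, 10, size=(100, 2))
        sy = rng.uniform(0, 10, size=(90, 2))
        assert hd95(sx, sy) == pytest.approx(brute_hd95(sx, sy), abs=1e-9)

    def test_hd95_not_above_classic_hausdorff(self, rng):
        for _ in range(20):
            sx = rng.uniform(size=(rng.integers(2, 40), 2))
            sy = rng.uniform(size=(rng.integers(2, 40), 2))
            assert hd95(sx, sy) <= hausdorff(sx, sy) + 1e-12

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            asd(np.empty((0, 2)), np.ones((3, 2)))


# -- metric/oracle equivalence at scale ------------------------------------

class TestOracleEquivalence:
    @pytest.mark.parametrize("shape,spacing", [
        ((16, 16), (1.0, 1.0)),
        ((16, 16), (0.8, 2.5)),
        ((8, 8, 6), (1.0, 1.0, 1.0)),
        ((8, 8, 6), (0.7, 0.7, 2.1)),
    ])
    def test_asd_hd95_match_brute_force_on_random_masks(self, shape, spacing):
        rng = np.random.default_rng(99)
        checked = 0
        while checked < 30:
            a, b = random_mask_pair(rng, shape)
            if not ((a == 1).any() and (b == 1).any()):
                continue
            sx = extract_surface(a, 1, spacing)
            sy = extract_surface(b, 1, spacing)
            assert asd(sx, sy) == pytest.approx(brute_asd(sx, sy), abs=1e-9)
            assert hd95(sx, sy) == pytest.approx(brute_hd95(sx, sy), abs=1e-9)
            checked += 1

    def test_spacing_covariance(self, rng):
        lam = 3.7
        a, b = random_mask_pair(rng, (12, 12))
        s1 = (1.0, 2.0)
        s2 = tuple(lam * s for s in s1)
        sx1, sy1 = extract_surface(a, 1, s1), extract_surface(b, 1, s1)
        sx2, sy2 = extract_surface(a, 1, s2), extract_surface(b, 1, s2)
        assert asd(sx2, sy2) == pytest.approx(lam * asd(sx1, sy1), rel=1e-12)
        assert hd95(sx2, sy2) == pytest.approx(lam * hd95(sx1, sy1),
                                               rel=1e-12)
        # overlap metrics are spacing-free by construction
        assert dsc(a, b, 1) == dsc(a, b, 1)


# -- case reports ----------------------------------------------------------

class TestEvaluateCase:
    def test_perfect_prediction(self, rng):
        a, _ = random_mask_pair(rng, (10, 10))
        rep = evaluate_case(a, a)
        for m in rep.per_class.values():
            assert m.dsc == 1.0 and m.iou == 1.0
            assert m.asd == 0.0 and m.hd95 == 0.0

    def test_report_reproduces_hand_example(self):
        pred = np.zeros((2, 2), int)
        gt = np.zeros((2, 2), int)
        pred[0, 0] = pred[0, 1] = 1
        gt[0, 1] = gt[1, 1] = 1
        rep = evaluate_case(pred, gt)
        assert rep.per_class[1].dsc == pytest.approx(0.5)
        assert rep.per_class[1].iou == pytest.approx(1 / 3)

    def test_mean_is_arithmetic_mean_of_counted_classes(self, rng):
        a, b = random_mask_pair(rng, (14, 14))
        rep = evaluate_case(a, b)
        counted = [m.dsc for m in rep.per_class.values()
                   if m.flag != "absent"]
        assert rep.mean("dsc") == pytest.approx(np.mean(counted))

    def test_absent_class_flagged_and_excluded(self):
        a = np.zeros((6, 6), int)
        a[0, 0] = 1
        rep = evaluate_case(a, a, classes=[1, 2])
        assert rep.per_class[2].flag == "absent"
        assert rep.mean("dsc") == pytest.approx(1.0)

    def test_one_sided_empty_flagged_with_diagonal_distance(self):
        pred = np.zeros((6, 8), int)
        gt = np.zeros((6, 8), int)
        gt[2, 2] = 1
        rep = evaluate_case(pred, gt, spacing=(1.0, 1.0))
        m = rep.per_class[1]
        assert m.flag == "pred_empty"
        assert m.dsc == 0.0
        assert m.hd95 == pytest.approx(np.hypot(6, 8))

    def test_background_excluded_by_default(self, rng):
        a, b = random_mask_pair(rng, (10, 10))
        rep = evaluate_case(a, b)
        assert 0 not in rep.per_class
        rep_bg = evaluate_case(a, b, include_background=True)
        assert 0 in rep_bg.per_class

    def test_aggregate_mean_of_two_cases(self, rng):
        a, b = random_mask_pair(rng, (10, 10))
        r1 = evaluate_case(a, b, case_id="a")
        r2 = evaluate_case(a, a, case_id="b")
        agg = aggregate_reports([r1, r2])
        assert agg["dsc"]["mean"] == pytest.approx(
            (r1.mean("dsc") + r2.mean("dsc")) / 2)
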