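"""Metrics, detection matching, tracking, and the five-class error taxonomy."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

import delicate as d
from delicate.evaluation import (ErrorReport, classify_errors, link_tracks,
                                 match_detections, mse, prf, snr)
from delicate.lineage import COLUMNS, LineageTable


def table(rows):
    """rows: (time, cell, parent, x, y, z) with radius 1, factor 1."""
    recs = [(t, c, p, x, y, z, 1.0, 1.0) for t, c, p, x, y, z in rows]
    return LineageTable(pd.DataFrame(recs, columns=COLUMNS))


class TestMSE:
    def test_identical_images(self):
        img = np.arange(12.0).reshape(3, 4)
        assert mse(img, img) == 0.0

    def test_hand_computed(self):
        a = np.array([[1, 2], [3, 4]], float)
        b = np.array([[1, 2], [3, 5]], float)
        assert mse(b, a) == pytest.approx(0.25)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 10, (6, 7))
        b = rng.uniform(0, 10, (6, 7))
        acc = 0.0
        for i in range(6):
            for j in range(7):
                acc += (a[i, j] - b[i, j]) ** 2
        assert mse(b, a) == pytest.approx(acc / 42, abs=1e-9)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            mse(np.zeros((2, 2)), np.zeros((3, 3)))


class TestSNR:
    def test_simple_ratio(self):
        img = np.array([[50, 50], [20, 5]], float)
        mask = np.array([[1, 1], [0, 0]], bool)
        assert snr(img, mask) == pytest.approx(4.0)

    def test_zero_outside_is_infinite(self):
        img = np.array([[5, 5], [0, 0]], float)
        mask = np.array([[1, 1], [0, 0]], bool)
        assert snr(img, mask) == np.inf

    def test_invariant_to_zero_border(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(1, 9, (5, 5))
        mask = rng.random((5, 5)) > 0.5
        base = snr(img, mask)
        pad_img = np.pad(img, 2)
        pad_mask = np.pad(mask, 2)
        assert snr(pad_img, pad_mask) == pytest.approx(base)
        # MSE under padding: the padded mean form rescales by area
        m1 = mse(img, np.zeros_like(img)) * img.size
        m2 = mse(pad_img, np.zeros_like(pad_img)) * pad_img.size
        assert m1 == pytest.approx(m2)


class TestMatchDetections:
    def test_exact_hit(self):
        tp, fp, fn, m = match_detections([[0, 0, 0]], [[0, 0, 0]],
                                         tolerance=1.0)
        assert (tp, fp, fn) == (1, 0, 0) and m == [(0, 0)]

    def test_miss_beyond_tolerance(self):
        tp, fp, fn, _ = match_detections([[0, 0, 4.0]], [[0, 0, 0]],
                                         tolerance=2.0)
        assert (tp, fp, fn) == (0, 1, 1)

    def test_one_to_one_when_two_preds_near_one_gt(self):
        tp, fp, fn, _ = match_detections([[0, 0, 0.1], [0, 0, -0.1]],
                                         [[0, 0, 0]], tolerance=1.0)
        assert (tp, fp, fn) == (1, 1, 0)

    def test_default_radius_tolerance(self):
        tp, _, _, _ = match_detections([[0, 0, 2.5]], [[0, 0, 0]],
                                       gt_radii=np.array([3.0]))
        assert tp == 1
        tp, _, _, _ = match_detections([[0, 0, 2.5]], [[0, 0, 0]],
                                       gt_radii=np.array([2.0]))
        assert tp == 0

    def test_close_to_optimal_assignment(self):
        # greedy matching must agree with the Hungarian optimum on all
        # but <1% of matches over many random instances
        rng = np.random.default_rng(42)
        greedy_total, optimal_total = 0, 0
        for _ in range(200):
            n, m = rng.integers(1, 10, size=2)
            pred = rng.uniform(0, 10, (n, 3))
            gt = rng.uniform(0, 10, (m, 3))
            tol = 2.0
            tp, _, _, _ = match_detections(pred, gt, tolerance=tol)
            cost = np.linalg.norm(pred[:, None] - gt[None], axis=2)
            big = 1e6
            cost = np.where(cost <= tol, cost, big)
            ri, ci = linear_sum_assignment(cost)
            opt = int(np.sum(cost[ri, ci] < big))
            greedy_total += tp
            optimal_total += opt
        assert optimal_total - greedy_total <= 0.01 * max(1, optimal_total)

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            match_detections([[0, 0, 0]], [[0, 0, 0]], tolerance=-1)


class TestPRF:
    def test_formulas(self):
        assert prf(8, 2, 0) == pytest.approx((0.8, 1.0, 0.8))

    def test_zero_conventions(self):
        assert prf(0, 0, 5) == (0.0, 0.0, 0.0)
        assert prf(0, 0, 0) == (0.0, 0.0, 0.0)

    def test_matches_direct_formula_on_random_triples(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            tp, fp, fn = (int(x) for x in rng.integers(0, 20, 3))
            p, r, a = prf(tp, fp, fn)
            assert p == pytest.approx(tp / (tp + fp) if tp + fp else 0.0)
            assert r == pytest.approx(tp / (tp + fn) if tp + fn else 0.0)
            assert a == pytest.approx(
                tp / (tp + fp + fn) if tp + fp + fn else 0.0)

    def test_accuracy_bounded_by_precision_and_recall(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            tp, fp, fn = (int(x) for x in rng.integers(0, 15, 3))
            p, r, a = prf(tp, fp, fn)
            assert a <= p + 1e-12 and a <= r + 1e-12


class TestLinkTracks:
    def test_stationary_nuclei_continue(self):
        dets = {0: np.array([[0, 0, 0], [0, 0, 5.0]]),
                1: np.array([[0, 0, 0], [0, 0, 5.0]])}
        traced = link_tracks(dets, max_step=1.0)
        assert len(traced.divisions()) == 0
        for cell in traced.df["cell"].unique():
            assert traced.lifespan(cell) == (0, 1)

    def test_two_equidistant_detections_become_a_division(self):
        dets = {0: np.array([[0, 0, 0.0]]),
                1: np.array([[0, 0, 2.0], [0, 0, -2.0]])}
        traced = link_tracks(dets, max_step=1.0, division_radius=3.0)
        divs = traced.divisions()
        assert len(divs) == 1
        assert traced.cell_count(1) == 2

    def test_recovers_ground_truth_topology(self):
        # one true division; detections are the exact GT positions
        networkx = pytest.importorskip("networkx")
        cfg = d.SimConfig(grid_shape=(20, 48, 48), spacing=(0.72, 0.36, 0.36),
                          n_timepoints=6, n_founders=2, n_debris=0,
                          cycle_length_mean=3.0, cycle_length_sd=0.0,
                          motion_sd=0.1, seed=3)
        lin = d.generate_lineage(cfg)
        dets = {t: lin.positions(t) for t in range(cfg.n_timepoints)}
        traced = link_tracks(dets, max_step=1.5, division_radius=4.0)

        def tree_of(tab):
            g = networkx.DiGraph()
            for cell in tab.df["cell"].unique():
                g.add_node(cell)
                p = tab.parent_of(cell)
                if p:
                    g.add_edge(p, cell)
            return g

        gt_tree, tr_tree = tree_of(lin), tree_of(traced)
        assert networkx.is_isomorphic(gt_tree, tr_tree)

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        dets = {t: rng.uniform(0, 20, (6, 3)) for t in range(4)}
        a = link_tracks(dets)
        b = link_tracks(dets)
        assert a.df.equals(b.df)


def straight_track(cell, t0, t1, pos, parent=""):
    rows = []
    for t in range(t0, t1 + 1):
        rows.append((t, cell, parent if t == t0 else "", *pos))
    return rows


class TestClassifyErrors:
    def test_identical_lineages_give_zero_errors(self):
        gt = table(straight_track("A", 0, 5, (5, 5, 5))
                   + straight_track("B", 0, 5, (15, 15, 15)))
        report = classify_errors(gt, gt)
        assert report.total() == 0

    def test_planted_class_I_oversegmentation(self):
        # GT: one cell persists; trace splits it into a false sister pair
        gt = table(straight_track("A", 0, 6, (5, 5, 5)))
        traced = table(straight_track("T1", 0, 2, (5, 5, 5))
                       + straight_track("T1a", 3, 6, (5, 5, 5.4), parent="T1")
                       + straight_track("T1p", 3, 6, (5, 5, 4.6), parent="T1"))
        report = classify_errors(traced, gt)
        assert report.class_totals() == {"I": 1, "II": 0, "III": 0,
                                         "IV": 0, "V": 0}

    def test_planted_class_II_movement_division(self):
        # two non-sisters approach; the tracker claims B's detection as a
        # new sister of A
        gt = table(straight_track("A", 0, 6, (5, 5, 5))
                   + [(t, "B", "" if t else "", 5, 5, 8.0 - 0.4 * t)
                      for t in range(7)])
        traced = table(
            straight_track("T1", 0, 3, (5, 5, 5))
            + straight_track("T1a", 4, 6, (5, 5, 5), parent="T1")
            + [(t, "T1p", "T1" if t == 4 else "", 5, 5, 8.0 - 0.4 * t)
               for t in range(4, 7)]
            + [(t, "T2", "", 5, 5, 8.0 - 0.4 * t) for t in range(0, 4)])
        report = classify_errors(traced, gt)
        assert report.class_totals() == {"I": 0, "II": 1, "III": 0,
                                         "IV": 0, "V": 0}

    def test_planted_class_III_noise_track(self):
        gt = table(straight_track("A", 0, 6, (5, 5, 5)))
        traced = table(straight_track("T1", 0, 6, (5, 5, 5))
                       + straight_track("T9", 2, 5, (15, 15, 15)))
        report = classify_errors(traced, gt)
        assert report.class_totals() == {"I": 0, "II": 0, "III": 1,
                                         "IV": 0, "V": 0}

    def test_planted_class_IV_missing_division(self):
        gt = table(straight_track("A", 0, 3, (5, 5, 5))
                   + straight_track("Aa", 4, 6, (5, 5, 6.2), parent="A")
                   + straight_track("Ap", 4, 6, (5, 5, 3.8), parent="A"))
        traced = table(straight_track("T1", 0, 3, (5, 5, 5))
                       + straight_track("T1", 4, 6, (5, 5, 6.2)))
        report = classify_errors(traced, gt)
        assert report.class_totals() == {"I": 0, "II": 0, "III": 0,
                                         "IV": 1, "V": 0}

    def test_planted_class_V_false_death(self):
        gt = table(straight_track("A", 0, 8, (5, 5, 5))
                   + straight_track("B", 0, 8, (15, 15, 15)))
        traced = table(straight_track("T1", 0, 8, (5, 5, 5))
                       + straight_track("T2", 0, 4, (15, 15, 15)))
        report = classify_errors(traced, gt)
        assert report.class_totals() == {"I": 0, "II": 0, "III": 0,
                                         "IV": 0, "V": 1}

    def test_exclusivity_total_is_sum_of_classes(self):
        gt = table(straight_track("A", 0, 6, (5, 5, 5))
                   + straight_track("B", 0, 6, (15, 15, 15)))
        traced = table(straight_track("T1", 0, 2, (5, 5, 5))
                       + straight_track("T1a", 3, 6, (5, 5, 5.4), parent="T1")
                       + straight_track("T1p", 3, 6, (5, 5, 4.6), parent="T1")
                       + straight_track("T2", 0, 2, (15, 15, 15))
                       + straight_track("T9", 1, 4, (25, 25, 25)))
        report = classify_errors(traced, gt)
        assert report.total() == sum(report.class_totals().values())
        assert len(report.records) == report.total()

    def test_stage_binning_uses_gt_cell_count(self):
        gt = table(straight_track("A", 0, 6, (5, 5, 5)))
        traced = table(straight_track("T1", 0, 6, (5, 5, 5))
                       + straight_track("T9", 2, 5, (15, 15, 15)))
        report = classify_errors(traced, gt)
        assert report.counts["0-160"]["III"] == 1

    def test_empty_tables_rejected(self):
        gt = table(straight_track("A", 0, 3, (5, 5, 5)))
        with pytest.raises(ValueError):
            classify_errors(LineageTable(), gt)


def test_error_report_json_round_trip(tmp_path):
    rep = ErrorReport()
    rep.add("I", 4, ("a", "b"), "0-160")
    rep.add("V", 9, ("c",), "160-360")
    path = tmp_path / "errors.json"
    rep.to_json(path)
    import json
    data = json.loads(path.read_text())
    assert data["counts"]["0-160"]["I"] == 1
    assert len(data["records"]) == 2
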