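import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from edgeunet.metrics import (MetricsReport, boundary_f1, bootstrap_ci,
                              confusion_metrics, correlate, dice, evaluate_run,
                              hd95, image_quality, iou, morphometry,
                              paired_compare, tabulate_ablation,
                              to_markdown_table)

from conftest import random_mask
from oracles import brute_hd95


class TestOverlap:
    def test_identical_and_disjoint_masks(self):
        a = np.zeros((5, 5), np.uint8)
        a[1:3, 1:3] = 1
        b = np.zeros((5, 5), np.uint8)
        b[3:5, 3:5] = 1
        assert dice(a, a) == iou(a, a) == 1.0
        assert dice(a, b) == iou(a, b) == 0.0

    def test_hand_counted_overlap(self):
        y = np.array([[1, 1, 1, 1, 0, 0, 0, 0]], np.uint8)
        p = np.array([[1, 1, 0, 0, 1, 1, 0, 0]], np.uint8)
        assert dice(y, p) == pytest.approx(0.5)
        assert iou(y, p) == pytest.approx(1 / 3)

    def test_both_empty_convention(self):
        z = np.zeros((4, 4), np.uint8)
        assert dice(z, z) == 1.0 and iou(z, z) == 1.0

    def test_iou_dice_algebraic_identity(self, rng):
        for _ in range(200):
            y = random_mask(rng, (10, 10))
            p = random_mask(rng, (10, 10))
            d, j = dice(y, p), iou(y, p)
            assert abs(j - d / (2 - d)) < 1e-12

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            dice(np.full((3, 3), 0.5), np.zeros((3, 3)))


class TestHD95:
    def test_identical_masks_give_zero(self, rng):
        m = random_mask(rng, (12, 12))
        assert hd95(m, m) == 0.0

    def test_two_single_pixels_three_columns_apart(self):
        a = np.zeros((7, 7), np.uint8); a[3, 1] = 1
        b = np.zeros((7, 7), np.uint8); b[3, 4] = 1
        assert hd95(a, b) == pytest.approx(3.0)

    def test_matches_all_pairs_oracle_on_random_masks(self, rng):
        for _ in range(50):
            y = random_mask(rng, (16, 16))
            p = random_mask(rng, (16, 16))
            assert hd95(y, p) == pytest.approx(brute_hd95(y, p), abs=1e-9)

    def test_symmetric_and_spacing_linear(self, rng):
        y, p = random_mask(rng, (14, 14)), random_mask(rng, (14, 14))
        assert hd95(y, p) == pytest.approx(hd95(p, y), abs=1e-12)
        assert hd95(y, p, spacing=2.5) == pytest.approx(2.5 * hd95(y, p))

    def test_one_empty_mask_gives_diagonal_sentinel(self):
        y = np.zeros((10, 10), np.uint8)
        p = np.zeros((10, 10), np.uint8); p[4, 4] = 1
        assert hd95(y, p) == pytest.approx(np.hypot(10, 10))
        assert hd95(y, y) == 0.0


class TestBoundaryF1:
    def test_identical_masks_are_perfect(self, rng):
        m = np.zeros((10, 10), np.uint8)
        m[3:7, 3:7] = 1
        assert boundary_f1(m, m) == 1.0

    def test_one_pixel_shift_within_tolerance(self):
        y = np.zeros((12, 12), np.uint8); y[3:8, 3:8] = 1
        p = np.zeros((12, 12), np.uint8); p[4:9, 3:8] = 1
        assert boundary_f1(y, p, tolerance=2.0) == 1.0

    def test_empty_prediction_scores_zero(self):
        y = np.zeros((8, 8), np.uint8); y[2:5, 2:5] = 1
        assert boundary_f1(y, np.zeros_like(y)) == 0.0


class TestConfusion:
    def test_identical_masks_all_ones(self):
        m = np.zeros((6, 6), np.uint8); m[1:4, 1:4] = 1
        out = confusion_metrics(m, m)
        assert all(v == 1.0 for v in out.values())

    def test_hand_counted_confusion(self):
        y = np.zeros((3, 3), np.uint8); y.flat[:4] = 1     # |Y| = 4
        p = np.zeros((3, 3), np.uint8); p.flat[2:6] = 1    # |P| = 4, TP = 2
        out = confusion_metrics(y, p)
        assert out["precision"] == pytest.approx(0.5)
        assert out["recall"] == pytest.approx(0.5)
        assert out["specificity"] == pytest.approx(3 / 5)
        assert out["vol_sim"] == 1.0  # equal volumes regardless of overlap


class TestImageQuality:
    def test_identical_arrays(self, rng):
        x = rng.random((16, 16))
        out = image_quality(x, x)
        assert out["mae"] == 0.0 and out["rmse"] == 0.0
        assert out["psnr"] == 100.0 and out["ssim"] == pytest.approx(1.0)

    def test_known_mse_gives_twenty_db(self):
        y = np.zeros((10, 10))
        p = np.full((10, 10), 0.1)  # MSE = 0.01
        assert image_quality(y, p)["psnr"] == pytest.approx(20.0)

    def test_constant_zero_vs_one(self):
        out = image_quality(np.zeros((8, 8)), np.ones((8, 8)))
        assert out["mae"] == 1.0 and out["rmse"] == 1.0


class TestBootstrap:
    def test_constant_vector_degenerate_ci(self):
        assert bootstrap_ci([3.0, 3.0, 3.0, 3.0]) == (3.0, 3.0)

    def test_seeded_repeatability(self, rng):
        vals = rng.random(40)
        assert bootstrap_ci(vals, seed=9) == bootstrap_ci(vals, seed=9)

    def test_n3_matches_exhaustive_enumeration(self):
        vals = np.array([1.0, 4.0, 10.0])
        means = [np.mean(c) for c in itertools.product(vals, repeat=3)]
        lo, hi = np.percentile(means, [2.5, 97.5])
        assert bootstrap_ci(vals) == (pytest.approx(lo), pytest.approx(hi))

    def test_contains_sample_mean_for_symmetric_data(self, rng):
        vals = rng.normal(5.0, 1.0, 60)
        lo, hi = bootstrap_ci(vals, seed=0)
        assert lo <= vals.mean() <= hi

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci([1.0])


class TestPairedCompare:
    def test_identical_samples_degenerate_convention(self):
        c = paired_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert c.cohens_d == 0.0 and c.p_value == 1.0

    def test_differences_one_two_three_closed_form(self):
        c = paired_compare([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert c.cohens_d == pytest.approx(2.0)
        t = 2.0 / (1.0 / np.sqrt(3.0))
        assert t == pytest.approx(3.4641, abs=1e-4)
        assert c.p_value == pytest.approx(2 * stats.t.sf(t, df=2), abs=1e-10)
        assert c.p_value == pytest.approx(0.0742, abs=5e-4)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            paired_compare([1.0], [2.0])


class TestMorphometry:
    def test_foreground_fraction(self):
        m = np.zeros((10, 10), np.uint8)
        m[:5, :5] = 1
        _, frac = morphometry(m)
        assert frac == pytest.approx(0.25)

    def test_two_disjoint_squares(self):
        m = np.zeros((12, 12), np.uint8)
        m[1:4, 1:4] = 1
        m[7:10, 7:10] = 1
        areas, _ = morphometry(m)
        assert sorted(areas) == [9.0, 9.0]

    def test_diagonal_touch_is_one_component(self):
        m = np.zeros((4, 4), np.uint8)
        m[0, 0] = m[1, 1] = 1  # 8-connectivity joins diagonals
        areas, _ = morphometry(m)
        assert list(areas) == [2.0]

    def test_pearson_affine_invariance(self, rng):
        x = rng.random(20)
        assert correlate(x, 2 * x + 1) == pytest.approx(1.0)


class TestReporting:
    def test_single_perfect_prediction_is_ideal_row(self):
        y = np.zeros((16, 16), np.uint8)
        y[4:10, 4:10] = 1
        rep = evaluate_run([y, y], [y.astype(float), y.astype(float)])
        row = rep.per_image.iloc[0]
        assert row["dice"] == row["iou"] == row["boundary_f1"] == 1.0
        assert row["hd95"] == 0.0 and row["ssim"] == pytest.approx(1.0)

    def test_aggregates_equal_hand_computation(self, rng):
        truths = [random_mask(rng, (16, 16)) for _ in range(5)]
        probs = [rng.random((16, 16)) for _ in range(5)]
        rep = evaluate_run(truths, probs, ci_seed=0)
        col = rep.per_image["dice"].to_numpy()
        assert rep.aggregates.loc["dice", "mean"] == pytest.approx(col.mean())
        assert rep.aggregates.loc["dice", "sd"] == pytest.approx(
            col.std(ddof=1))

    def test_misaligned_counts_rejected(self):
        with pytest.raises(ValueError):
            evaluate_run([np.zeros((4, 4), np.uint8)], [])

    def test_ablation_table_has_row_per_configuration(self, rng):
        df = pd.DataFrame({"dice": rng.random(4), "iou": rng.random(4),
                           "hd95": rng.random(4)})
        table = tabulate_ablation({f"{k}: variant": df for k in "ABCD"})
        assert len(table) == 4
        assert list(table.columns) == ["dice", "iou", "hd95"]

    def test_markdown_table_renders(self):
        df = pd.DataFrame({"x": [1.0]}, index=pd.Index(["a"], name="row"))
        md = to_markdown_table(df)
        assert md.splitlines()[0].startswith("| row")

    def test_summary_mentions_every_metric(self, rng):
        truths = [random_mask(rng, (12, 12)) for _ in range(3)]
        probs = [rng.random((12, 12)) for _ in range(3)]
        text = evaluate_run(truths, probs).summary()
        for metric in ("dice", "iou", "hd95", "ssim"):
            assert metric in text
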