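"""Confusion metrics, volume quantification, overlays, group statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tongueseg import (
    compare_groups,
    compare_paired,
    confusion,
    evaluate_subject,
    metrics,
    overlay_slice,
    summary_table,
    tongue_volume,
)
from tongueseg.evaluation import ConfusionCounts


class TestConfusion:
    def test_perfect_prediction(self, rng):
        t = rng.integers(0, 2, (6, 6, 6))
        c = confusion(t, t)
        assert c.fp == c.fn == 0
        assert c.tp == t.sum()
        assert c.total == t.size

    def test_complement_prediction_has_no_true_voxels(self, rng):
        t = rng.integers(0, 2, (5, 5, 5))
        c = confusion(1 - t, t)
        assert c.tp == 0 and c.tn == 0

    def test_counts_match_brute_force_loop(self, rng):
        p = rng.integers(0, 2, (10, 10, 10))
        t = rng.integers(0, 2, (10, 10, 10))
        c = confusion(p, t)
        tp = fp = fn = tn = 0
        for i in range(10):
            for j in range(10):
                for k in range(10):
                    if p[i, j, k] and t[i, j, k]:
                        tp += 1
                    elif p[i, j, k]:
                        fp += 1
                    elif t[i, j, k]:
                        fn += 1
                    else:
                        tn += 1
        assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)

    def test_nonbinary_input_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.full((2, 2), 2), np.zeros((2, 2)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.zeros((2, 2)), np.zeros((3, 3)))


class TestMetrics:
    def test_forced_arithmetic(self):
        m = metrics(ConfusionCounts(tp=3, tn=0, fp=1, fn=1))
        assert m.precision == m.recall == m.dice == 0.75

    def test_empty_masks_are_undefined_not_zero(self):
        m = metrics(ConfusionCounts(tp=0, tn=10, fp=0, fn=0))
        assert m.precision is None and m.recall is None and m.dice is None

    def test_dice_is_harmonic_mean_of_precision_recall(self):
        m = metrics(ConfusionCounts(tp=2, tn=0, fp=4, fn=1))
        assert m.precision == pytest.approx(1 / 3)
        assert m.recall == pytest.approx(2 / 3)
        assert m.dice == pytest.approx(4 / 9)
        harmonic = 2 * m.precision * m.recall / (m.precision + m.recall)
        assert m.dice == pytest.approx(harmonic, abs=1e-12)

    def test_dice_iou_identity(self, rng):
        for _ in range(10):
            c = ConfusionCounts(*(int(v) for v in rng.integers(1, 500, 4)))
            m = metrics(c)
            assert m.dice == pytest.approx(
                2 * m.foreground_iou / (1 + m.foreground_iou), abs=1e-12
            )


class TestTongueVolume:
    def test_eight_voxels_at_half_mm(self):
        mask = np.zeros((4, 4, 4), dtype=np.uint8)
        mask[:2, :2, :2] = 1
        assert tongue_volume(mask, 0.5) == pytest.approx(0.001)

    def test_empty_mask(self):
        assert tongue_volume(np.zeros((3, 3, 3)), 1.0) == 0.0

    def test_cohort_scale_sanity(self):
        # 763,800 voxels at 0.5 mm isotropic = 95.5 cm^3 (healthy tongue scale)
        mask = np.zeros(763_800 + 10, dtype=np.uint8)
        mask[:763_800] = 1
        assert tongue_volume(mask.reshape(-1, 1, 1), 0.5) == pytest.approx(95.475)

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError):
            tongue_volume(np.full((2, 2), 3), 1.0)


class TestOverlay:
    def test_perfect_prediction_has_no_error_colors(self, rng):
        t = rng.integers(0, 2, (8, 8))
        img = overlay_slice(t, t, rng.random((8, 8)))
        blue = (img[..., 2] > 0.5) & (img[..., 0] < 0.3) & (img[..., 1] < 0.3)
        yellow = (img[..., 0] > 0.5) & (img[..., 1] > 0.5) & (img[..., 2] < 0.3)
        assert not blue.any() and not yellow.any()

    def test_missed_truth_is_yellow_only(self):
        t = np.zeros((6, 6), dtype=int)
        t[2:4, 2:4] = 1
        img = overlay_slice(np.zeros_like(t), t, np.zeros((6, 6)))
        fn_px = img[t == 1]
        assert np.allclose(fn_px[:, 0], fn_px[:, 1])  # R == G (yellow)
        assert np.all(fn_px[:, 2] < fn_px[:, 0])

    def test_colored_pixel_counts_equal_confusion_counts(self, rng):
        p = rng.integers(0, 2, (12, 12))
        t = rng.integers(0, 2, (12, 12))
        img = overlay_slice(p, t, np.zeros((12, 12)), alpha=1.0)
        c = confusion(p, t)
        magenta = np.all(img == [1, 0, 1], axis=-1).sum()
        blue = np.all(img == [0, 0, 1], axis=-1).sum()
        yellow = np.all(img == [1, 1, 0], axis=-1).sum()
        assert (magenta, blue, yellow) == (c.tp, c.fp, c.fn)


class TestComparePaired:
    def test_identical_lists_report_no_difference(self):
        res = compare_paired([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.degenerate
        assert res.p_value == 1.0

    def test_constant_shift_is_degenerate(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = compare_paired([x + 0.5 for x in a], a)
        assert res.degenerate and res.p_value is None

    def test_matches_closed_form_paired_t(self, rng):
        a = rng.normal(100, 8, 20)
        b = a + rng.normal(1.0, 2.0, 20)
        res = compare_paired(list(a), list(b))
        d = a - b
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p = 2 * sps.t.sf(abs(t), len(d) - 1)
        if res.test_name == "paired t":
            assert res.statistic == pytest.approx(t, abs=1e-8)
            assert res.p_value == pytest.approx(p, abs=1e-8)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_paired([1, 2, 3], [1, 2])


class TestCompareGroups:
    def test_identical_groups_not_significant(self, rng):
        a = list(rng.normal(10, 1, 12))
        res = compare_groups(a, list(a))
        assert res.p_value > 0.9

    def test_heavy_tailed_group_triggers_mann_whitney(self, rng):
        a = list(rng.standard_cauchy(30) * 10)
        b = list(rng.normal(0, 1, 30))
        res = compare_groups(a, b)
        assert res.test_name == "Mann-Whitney U"
        assert res.normality_p[0] < 0.05

    def test_large_shift_detected_by_unpaired_t(self, rng):
        # two normal samples at the group-study size (n=19) and a large
        # standardized difference
        a = list(rng.normal(106, 8, 19))
        b = list(rng.normal(80, 8, 19))
        res = compare_groups(a, b)
        assert res.test_name == "unpaired t"
        assert res.p_value < 0.005

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0, 2.0, 3.0])


class TestSummaryTable:
    def _rows(self, subjects, strategies, dice=lambda s, st: 0.9):
        rows = []
        for s in subjects:
            for st_ in strategies:
                rows.append(
                    dict(subject=s, strategy=st_, tp=10, tn=100, fp=2, fn=3,
                         precision=0.8, recall=0.7, dice=dice(s, st_))
                )
        return pd.DataFrame(rows)

    def test_single_subject_has_zero_sd(self):
        out = summary_table(self._rows(["s0"], ["softmax"]))
        assert out.loc[0, "dice_sd"] == 0.0

    def test_mean_of_dice_differs_from_pooled_dice(self):
        # two subjects constructed so the two aggregations disagree
        df = pd.DataFrame(
            [
                dict(subject="a", strategy="softmax", tp=1, tn=0, fp=0, fn=9,
                     precision=1.0, recall=0.1, dice=2 * 1 / (2 * 1 + 0 + 9)),
                dict(subject="b", strategy="softmax", tp=90, tn=0, fp=0, fn=0,
                     precision=1.0, recall=1.0, dice=1.0),
            ]
        )
        out = summary_table(df)
        mean_dice = out.loc[0, "dice_mean"]
        pooled = 2 * 91 / (2 * 91 + 0 + 9)
        assert abs(mean_dice - pooled) > 0.05

    def test_inconsistent_subject_sets_rejected(self):
        df = pd.concat(
            [self._rows(["a", "b"], ["softmax"]), self._rows(["a"], ["union"])]
        )
        with pytest.raises(ValueError):
            summary_table(df)


class TestEvaluateSubject:
    def test_counts_sum_to_grid_size(self, rng):
        p = rng.integers(0, 2, (16, 16, 16))
        t = rng.integers(0, 2, (16, 16, 16))
        c, m = evaluate_subject(p, t, 2.0)
        assert c.total == 16**3
        assert m.volume_cm3 == pytest.approx(p.sum() * 8.0 / 1000.0)
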