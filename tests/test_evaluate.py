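"""Dice metrics, pectoral detection outcomes and group statistics."""

import numpy as np
import pytest

from mamseg.evaluate import (EvaluationReport, anova_tukey, compare_groups,
                             dice_per_class, overall_dice, pectoral_detection,
                             score_image)
from mamseg.image_io import LabelGrid


def set_dice(pred, truth, c):
    """Independent oracle: dice via python sets of pixel coordinates."""
    p = {tuple(ix) for ix in np.argwhere(np.asarray(pred) == c)}
    t = {tuple(ix) for ix in np.argwhere(np.asarray(truth) == c)}
    if not t:
        return None
    return 2 * len(p & t) / (len(p) + len(t))


class TestDice:
    def test_identical_masks(self, rng):
        m = rng.integers(0, 3, size=(16, 16))
        for c in np.unique(m):
            assert dice_per_class(m, m, int(c)) == 1.0

    def test_disjoint_masks(self):
        pred = np.zeros((10, 10), dtype=int)
        pred[:5] = 1
        truth = np.zeros((10, 10), dtype=int)
        truth[5:] = 1
        assert dice_per_class(pred, truth, 1) == 0.0

    def test_nested_regions_counting(self):
        # truth 100 px, prediction 50 px fully inside: 2*50/150
        truth = np.zeros((20, 20), dtype=int)
        truth[:10, :10] = 1
        pred = np.zeros((20, 20), dtype=int)
        pred[:5, :10] = 1
        assert dice_per_class(pred, truth, 1) == pytest.approx(2 * 50 / 150)

    def test_undefined_when_truth_lacks_class(self):
        truth = np.zeros((8, 8), dtype=int)
        pred = np.full((8, 8), 2, dtype=int)
        assert dice_per_class(pred, truth, 2) is None

    def test_symmetry_and_set_oracle(self, rng):
        for _ in range(25):
            a = rng.integers(0, 3, size=(16, 16))
            b = rng.integers(0, 3, size=(16, 16))
            for c in (1, 2):
                expected = set_dice(a, b, c)
                got = dice_per_class(a, b, c)
                if expected is None:
                    assert got is None
                else:
                    assert abs(got - expected) < 1e-12
                    if set_dice(b, a, c) is not None:
                        assert dice_per_class(b, a, c) == pytest.approx(
                            dice_per_class(a, b, c) if (a == c).any() else got)

    def test_accepts_label_grids(self, rng):
        m = LabelGrid(rng.integers(0, 3, size=(8, 8)).astype(np.uint8))
        assert dice_per_class(m, m, 1) == 1.0


class TestOverallDice:
    def _masks(self):
        # truth: 900 breast px with dice 0.9, 100 pectoral px with dice 0.5
        truth = np.zeros((40, 40), dtype=int)
        truth[:30, :30] = 1           # 900 breast
        truth[30:35, :20] = 2         # 100 pectoral
        pred = np.zeros_like(truth)
        # breast: pred 900 px, overlap 810 -> dice 2*810/1800 = 0.9
        pred[:27, :30] = 1            # 810 inside
        pred[35:38, :30] = 1          # 90 outside
        # pectoral: pred 100 px, overlap 50 -> dice 2*50/200 = 0.5
        pred[30:35, :10] = 2          # 50 inside
        pred[38:40, 15:40] = 2        # 50 outside
        return pred, truth

    def test_pixel_weighted_combination(self):
        pred, truth = self._masks()
        assert dice_per_class(pred, truth, 1) == pytest.approx(0.9)
        assert dice_per_class(pred, truth, 2) == pytest.approx(0.5)
        assert overall_dice(pred, truth) == pytest.approx(
            (900 * 0.9 + 100 * 0.5) / 1000)
        assert overall_dice(pred, truth) == pytest.approx(0.86)

    def test_equals_breast_dice_without_pectoral(self, rng):
        truth = (rng.uniform(size=(16, 16)) < 0.4).astype(int)
        pred = (rng.uniform(size=(16, 16)) < 0.4).astype(int)
        if not truth.any():
            truth[0, 0] = 1
        assert overall_dice(pred, truth) == dice_per_class(pred, truth, 1)

    def test_perfect_prediction(self, rng):
        truth = rng.integers(0, 3, size=(12, 12))
        truth[0, 0] = 1
        assert overall_dice(truth, truth) == 1.0

    def test_bounded_by_class_dices(self, rng):
        for _ in range(20):
            pred = rng.integers(0, 3, size=(16, 16))
            truth = rng.integers(0, 3, size=(16, 16))
            if not (truth == 1).any() or not (truth == 2).any():
                continue
            d1 = dice_per_class(pred, truth, 1)
            d2 = dice_per_class(pred, truth, 2)
            ov = overall_dice(pred, truth)
            assert min(d1, d2) - 1e-12 <= ov <= max(d1, d2) + 1e-12

    def test_no_breast_truth_rejected(self):
        with pytest.raises(ValueError):
            overall_dice(np.zeros((4, 4), dtype=int), np.zeros((4, 4), dtype=int))


class TestDetection:
    def test_true_negative(self):
        truth = np.ones((10, 10), dtype=int)
        pred = np.ones((10, 10), dtype=int)
        assert pectoral_detection(pred, truth).outcome == "TN"

    def test_any_pixel_false_positive(self):
        truth = np.ones((10, 10), dtype=int)
        pred = truth.copy()
        pred[0, 0] = 2
        out = pectoral_detection(pred, truth)
        assert out.outcome == "FP"

    def test_fp_area_threshold(self):
        # breast area 1000 px, 5 predicted pectoral px: below the 1% bound
        truth = np.zeros((40, 40), dtype=int)
        truth.flat[:1000] = 1
        pred = truth.copy()
        pred.flat[:5] = 2
        out = pectoral_detection(pred, truth, area_fraction_threshold=0.01)
        assert out.outcome == "FP"
        assert out.fp_breast_fraction == pytest.approx(0.005)
        assert out.fp_exceeds_threshold is False

    def test_false_negative_and_true_positive(self):
        truth = np.ones((6, 6), dtype=int)
        truth[0, :] = 2
        assert pectoral_detection(np.ones_like(truth), truth).outcome == "FN"
        assert pectoral_detection(truth, truth).outcome == "TP"

    def test_outcomes_partition(self, rng):
        seen = set()
        for _ in range(50):
            pred = rng.integers(0, 3, size=(8, 8))
            truth = rng.integers(0, 3, size=(8, 8))
            out = pectoral_detection(pred, truth)
            assert out.outcome in {"TP", "FP", "FN", "TN"}
            seen.add(out.outcome)
        assert "TP" in seen   # random 3-label masks almost surely contain 2s


class TestReport:
    def test_single_perfect_prediction(self, rng):
        truth = rng.integers(0, 3, size=(16, 16))
        truth[0, 0] = 1
        report = EvaluationReport(scores=[score_image(truth, truth, view="MLO")])
        row = report.summarize(by=["view"]).iloc[0]
        assert row["overall_dice_mean"] == 1.0
        assert row["n_TP"] + row["n_TN"] == 1

    def test_mean_and_sample_sd(self):
        # two images scored 0.8 and 1.0: mean 0.9, sample sd sqrt(0.02)
        truth = np.zeros((10, 10), dtype=int)
        truth[:5] = 1                   # 50 breast px
        pred_08 = np.zeros_like(truth)
        pred_08[:5, :5] = 1             # nested 25 px -> dice 2*25/75 != 0.8
        pred_08[5:, :2] = 1             # calibrated below
        # simplest: craft dice 0.8 = 2*i/(p+t): p=t=50, i=40
        pred_08 = np.zeros_like(truth)
        pred_08[:4] = 1                 # rows 0-3 inside truth: 40 px
        pred_08[5, :] = 1               # 10 px outside
        report = EvaluationReport(scores=[
            score_image(pred_08, truth), score_image(truth, truth)])
        summary = report.summarize().iloc[0]
        assert report.scores[0].overall_dice == pytest.approx(0.8)
        assert summary["overall_dice_mean"] == pytest.approx(0.9)
        assert summary["overall_dice_sd"] == pytest.approx(np.sqrt(0.02))

    def test_stratum_counts_partition(self, rng):
        truth = np.ones((8, 8), dtype=int)
        scores = [score_image(truth, truth, view=v)
                  for v in ["MLO"] * 7 + ["CC"] * 5]
        summary = EvaluationReport(scores=scores).summarize(by=["view"])
        assert summary["n"].sum() == 12


class TestGroupComparisons:
    def test_self_comparison_paired(self, rng):
        a = rng.normal(size=30)
        res = compare_groups(a, a, mode="paired_t")
        assert res.statistic == 0.0 and not res.significant

    def test_bonferroni_threshold(self, rng):
        res = compare_groups(rng.normal(size=10), rng.normal(size=10),
                             alpha=0.05, n_comparisons=8)
        assert res.alpha_adjusted == pytest.approx(0.00625)

    def test_shifted_gaussians_significant(self, rng):
        a = rng.normal(0.0, 1.0, 50)
        b = rng.normal(2.0, 1.0, 50)
        res = compare_groups(a, b, mode="unpaired_t")
        assert res.significant and res.p_value < 1e-6

    def test_against_statsmodels(self, rng):
        from statsmodels.stats.weightstats import DescrStatsW, ttest_ind

        a = rng.normal(0.0, 1.0, 40)
        b = rng.normal(0.7, 1.2, 45)
        res = compare_groups(a, b, mode="unpaired_t")
        t_ref, p_ref, _ = ttest_ind(a, b, usevar="pooled")
        assert res.statistic == pytest.approx(t_ref, abs=1e-6)
        assert res.p_value == pytest.approx(p_ref, abs=1e-6)

        c = a + rng.normal(0.3, 0.5, 40)
        res = compare_groups(a, c, mode="paired_t")
        t_ref, p_ref, _ = DescrStatsW(a - c).ttest_mean(0.0)
        assert res.statistic == pytest.approx(t_ref, abs=1e-6)
        assert res.p_value == pytest.approx(p_ref, abs=1e-6)

    def test_paired_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            compare_groups(rng.normal(size=5), rng.normal(size=6), mode="paired_t")


class TestAnovaTukey:
    def test_identical_groups(self):
        g = [0.8, 0.9, 1.0, 0.85]
        res = anova_tukey([g, g, g])
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert not res.significant
        assert not res.pairwise["significant"].any()

    def test_shifted_group_detected(self, rng):
        groups = [rng.normal(0, 1, 40), rng.normal(0, 1, 40), rng.normal(3, 1, 40)]
        res = anova_tukey(groups)
        assert res.significant
        flagged = res.pairwise[res.pairwise["significant"]]
        assert set(map(tuple, flagged[["group_a", "group_b"]].values)) == {(0, 2), (1, 2)}

    def test_pairwise_count(self, rng):
        k = 5
        groups = [rng.normal(size=10) for _ in range(k)]
        res = anova_tukey(groups)
        assert len(res.pairwise) == k * (k - 1) // 2

    def test_against_statsmodels(self, rng):
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        groups = [rng.normal(0, 1, 30), rng.normal(0.5, 1, 30), rng.normal(1.0, 1, 30)]
        res = anova_tukey(groups)
        df = pd.DataFrame({
            "y": np.concatenate(groups),
            "g": np.repeat(["a", "b", "c"], [len(g) for g in groups]),
        })
        table = sm.stats.anova_lm(ols("y ~ C(g)", data=df).fit())
        assert res.f_statistic == pytest.approx(table["F"].iloc[0], abs=1e-6)
        assert res.p_value == pytest.approx(table["PR(>F)"].iloc[0], abs=1e-6)
        ref = pairwise_tukeyhsd(df["y"], df["g"])
        assert np.allclose(sorted(res.pairwise["p_adj"]), sorted(ref.pvalues), atol=1e-6)

    def test_too_few_groups_rejected(self, rng):
        with pytest.raises(ValueError):
            anova_tukey([rng.normal(size=5), rng.normal(size=5)])
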