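"""Segmentation evaluation: dice metrics, detection outcomes, statistics.

Per-class overlap is quantified by the dice coefficient

    DICE(c) = 2 |pred_c ∩ truth_c| / (|pred_c| + |truth_c|),

computed only for classes present in the ground truth (an image without a
pectoral muscle contributes no pectoral dice).  The overall dice of an image
averages the breast and pectoral dice weighted by the ground-truth pixel
count of each class; background is excluded.

Pectoral-muscle presence is additionally scored as a detection problem: a
false positive is any predicted pectoral pixel when the truth has none, a
false negative is an empty pectoral prediction when the truth has some.  The
fraction of the truth breast region covered by a false-positive pectoral
prediction is reported against a configurable threshold (1% by default) to
separate negligible from substantial false positives.

Group comparisons use Student t-tests (unpaired or paired), one-way ANOVA
with Tukey's HSD post hoc, and Bonferroni-adjusted significance levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .image_io import LabelGrid

__all__ = [
    "ImageScore", "EvaluationReport", "TestResult",
    "dice_per_class", "overall_dice", "pectoral_detection",
    "score_image", "evaluate_dataset", "compare_groups", "anova_tukey",
]

BREAST, PECTORAL = 1, 2


def _labels(x) -> np.ndarray:
    return np.asarray(getattr(x, "labels", x))


def dice_per_class(pred, truth, c: int) -> float | None:
    """Dice coefficient for class ``c``; None when truth lacks the class."""
    p, t = _labels(pred), _labels(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    pm, tm = p == c, t == c
    n_truth = int(tm.sum())
    if n_truth == 0:
        return None
    n_pred = int(pm.sum())
    inter = int((pm & tm).sum())
    return 2.0 * inter / (n_pred + n_truth)


def overall_dice(pred, truth) -> float:
    """Breast and pectoral dice averaged with truth-pixel-count weights."""
    t = _labels(truth)
    n_breast = int((t == BREAST).sum())
    n_pect = int((t == PECTORAL).sum())
    if n_breast == 0:
        raise ValueError("truth contains no breast pixels; overall dice undefined")
    d_breast = dice_per_class(pred, truth, BREAST)
    if n_pect == 0:
        return d_breast
    d_pect = dice_per_class(pred, truth, PECTORAL)
    return (n_breast * d_breast + n_pect * d_pect) / (n_breast + n_pect)


@dataclass(frozen=True)
class DetectionOutcome:
    """Pectoral presence detection for one image."""

    outcome: str                      # one of TP / FP / FN / TN
    fp_breast_fraction: float | None  # predicted-pectoral / truth-breast area (FP only)
    fp_exceeds_threshold: bool | None


def pectoral_detection(pred, truth, area_fraction_threshold: float = 0.01) -> DetectionOutcome:
    """Classify the image as pectoral TP/FP/FN/TN (any-pixel rule).

    For false positives the predicted-pectoral area as a fraction of the
    ground-truth breast region (breast + pectoral labels) is compared with
    ``area_fraction_threshold``.
    """
    p, t = _labels(pred), _labels(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    pred_has = bool((p == PECTORAL).any())
    truth_has = bool((t == PECTORAL).any())
    if truth_has:
        return DetectionOutcome("TP" if pred_has else "FN", None, None)
    if not pred_has:
        return DetectionOutcome("TN", None, None)
    breast_area = int((t != 0).sum())
    frac = float((p == PECTORAL).sum()) / breast_area if breast_area else math.inf
    return DetectionOutcome("FP", frac, frac > area_fraction_threshold)


@dataclass
class ImageScore:
    """Per-image dice and detection scores plus stratification metadata."""

    breast_dice: float
    pectoral_dice: float | None
    overall_dice: float
    n_breast: int
    n_pectoral: int
    detection: DetectionOutcome
    view: str = ""
    vendor: str = ""
    kind: str = ""
    image_id: str = ""


def score_image(pred, truth, *, view: str = "", vendor: str = "", kind: str = "",
                image_id: str = "", area_fraction_threshold: float = 0.01) -> ImageScore:
    """All per-image metrics for one prediction/truth pair."""
    t = _labels(truth)
    return ImageScore(
        breast_dice=dice_per_class(pred, truth, BREAST),
        pectoral_dice=dice_per_class(pred, truth, PECTORAL),
        overall_dice=overall_dice(pred, truth),
        n_breast=int((t == BREAST).sum()),
        n_pectoral=int((t == PECTORAL).sum()),
        detection=pectoral_detection(pred, truth, area_fraction_threshold),
        view=view, vendor=vendor, kind=kind, image_id=image_id,
    )


@dataclass
class EvaluationReport:
    """Per-image scores with stratified summaries (mean ± sd)."""

    scores: list[ImageScore]
    sample_sd: bool = True  # n-1 denominator in summaries

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.scores:
            rows.append({
                "image_id": s.image_id, "view": s.view, "vendor": s.vendor,
                "kind": s.kind, "breast_dice": s.breast_dice,
                "pectoral_dice": s.pectoral_dice, "overall_dice": s.overall_dice,
                "n_breast": s.n_breast, "n_pectoral": s.n_pectoral,
                "detection": s.detection.outcome,
                "fp_breast_fraction": s.detection.fp_breast_fraction,
            })
        return pd.DataFrame(rows)

    def summarize(self, by: list[str] | None = None) -> pd.DataFrame:
        """Stratified mean ± sd of the dice metrics plus detection tallies.

        Pectoral dice is averaged only over images whose truth contains the
        pectoral class.
        """
        df = self.to_frame()
        ddof = 1 if self.sample_sd else 0
        group_cols = by or []
        groups = df.groupby(group_cols, dropna=False) if group_cols else [((), df)]
        rows = []
        for key, g in groups:
            if not isinstance(key, tuple):
                key = (key,)
            pect = g["pectoral_dice"].dropna()
            row = dict(zip(group_cols, key))
            row.update({
                "n": len(g),
                "breast_dice_mean": g["breast_dice"].mean(),
                "breast_dice_sd": g["breast_dice"].std(ddof=ddof),
                "pectoral_n": len(pect),
                "pectoral_dice_mean": pect.mean() if len(pect) else np.nan,
                "pectoral_dice_sd": pect.std(ddof=ddof) if len(pect) else np.nan,
                "overall_dice_mean": g["overall_dice"].mean(),
                "overall_dice_sd": g["overall_dice"].std(ddof=ddof),
            })
            for out in ("TP", "FP", "FN", "TN"):
                row[f"n_{out}"] = int((g["detection"] == out).sum())
            rows.append(row)
        return pd.DataFrame(rows)


def evaluate_dataset(model, records, strata: list[str] | None = None,
                     area_fraction_threshold: float = 0.01) -> EvaluationReport:
    """Score a trained model over an iterable of evaluation records.

    Each record needs ``image`` (2-D grid in [0, 1]), ``truth`` (LabelGrid)
    and optional ``view`` / ``vendor`` / ``kind`` / ``image_id`` attributes.
    """
    from .unet import predict_labels

    scores = []
    for rec in records:
        pred = predict_labels(model, rec.image)
        scores.append(score_image(
            pred, rec.truth,
            view=getattr(rec, "view", ""), vendor=getattr(rec, "vendor", ""),
            kind=getattr(rec, "kind", ""), image_id=str(getattr(rec, "image_id", "")),
            area_fraction_threshold=area_fraction_threshold,
        ))
    return EvaluationReport(scores=scores)


@dataclass(frozen=True)
class TestResult:
    """A two-sample (or omnibus) test with its adjusted significance level."""

    statistic: float
    p_value: float
    alpha_adjusted: float
    significant: bool


def compare_groups(a, b, mode: str = "unpaired_t", alpha: float = 0.05,
                   n_comparisons: int = 1, equal_var: bool = True) -> TestResult:
    """Student t-test between two score lists.

    ``mode`` selects unpaired (independent-sample) or paired testing; the
    significance level is Bonferroni-adjusted to alpha / n_comparisons.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    if mode == "unpaired_t":
        res = stats.ttest_ind(a, b, equal_var=equal_var)
    elif mode == "paired_t":
        if a.size != b.size:
            raise ValueError("paired test requires equal-length groups")
        res = stats.ttest_rel(a, b)
    else:
        raise ValueError("mode must be 'unpaired_t' or 'paired_t'")
    stat = float(res.statistic)
    p = float(res.pvalue)
    if math.isnan(stat):  # identical paired samples: zero difference
        stat, p = 0.0, 1.0
    thr = alpha / n_comparisons
    return TestResult(statistic=stat, p_value=p, alpha_adjusted=thr,
                      significant=p < thr)


@dataclass(frozen=True)
class AnovaTukeyResult:
    f_statistic: float
    p_value: float
    significant: bool
    pairwise: pd.DataFrame  # columns: group_a, group_b, statistic, p_adj, significant


def anova_tukey(groups, alpha: float = 0.05) -> AnovaTukeyResult:
    """One-way ANOVA with Tukey HSD pairwise post hoc comparisons."""
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 3:
        raise ValueError("need at least three groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs at least two observations")
    f_stat, p = stats.f_oneway(*groups)
    tukey = stats.tukey_hsd(*groups)
    rows = []
    k = len(groups)
    for i in range(k):
        for j in range(i + 1, k):
            rows.append({
                "group_a": i, "group_b": j,
                "statistic": float(tukey.statistic[i, j]),
                "p_adj": float(tukey.pvalue[i, j]),
                "significant": bool(tukey.pvalue[i, j] < alpha),
            })
    if math.isnan(f_stat):  # all groups identical and constant
        f_stat, p = 0.0, 1.0
    return AnovaTukeyResult(
        f_statistic=float(f_stat), p_value=float(p),
        significant=bool(p < alpha), pairwise=pd.DataFrame(rows),
    )
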