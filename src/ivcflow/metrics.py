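"""Agreement and overlap statistics for automated-vs-manual comparison.

Continuous measurements are compared with Pearson correlation, Bland-Altman
bias and 95% limits of agreement, and a paired location test whose branch
(paired t vs. Wilcoxon signed-rank) is gated by Shapiro-Wilk normality of
the paired differences.  Categorical outputs (dichotomised cIVC, RAP) are
compared with a Pearson chi-square association test and confusion-matrix
summaries; macro accuracy is the unweighted mean of per-class recall, so
every class counts equally regardless of prevalence.  Segmentation overlap
is scored with IoU and Dice.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "AgreementReport",
    "pearson_r",
    "bland_altman",
    "location_test",
    "chi_square_association",
    "confusion_and_macro",
    "overlap_scores",
    "agreement_report",
]

LOA_MULTIPLIER = 1.96
NORMALITY_ALPHA = 0.05


@dataclasses.dataclass
class AgreementReport:
    pearson_r: float
    bias: float
    loa_low: float
    loa_high: float
    location_test_name: str
    location_statistic: float
    location_p: float
    chi_square: Optional[Tuple[float, int, float]] = None  # (stat, dof, p)
    confusion: Optional[np.ndarray] = None
    confusion_normalized: Optional[np.ndarray] = None
    macro_accuracy: Optional[float] = None
    per_class: Optional[Dict[str, Dict[str, float]]] = None

    def to_dict(self) -> dict:
        out = {
            "pearson_r": self.pearson_r,
            "bland_altman": {"bias": self.bias, "loa_low": self.loa_low,
                             "loa_high": self.loa_high},
            "location_test": {"name": self.location_test_name,
                              "statistic": self.location_statistic,
                              "p": self.location_p},
        }
        if self.chi_square is not None:
            s, d, p = self.chi_square
            out["chi_square"] = {"statistic": s, "dof": d, "p": p}
        if self.confusion is not None:
            out["confusion"] = self.confusion.tolist()
            out["confusion_normalized"] = self.confusion_normalized.tolist()
            out["macro_accuracy"] = self.macro_accuracy
            out["per_class"] = self.per_class
        return out


def pearson_r(x, y) -> float:
    """Product-moment correlation; zero-variance input is an error."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def bland_altman(auto, manual):
    """Bias and 95% limits of agreement of auto - manual differences.

    Returns ``(bias, loa_low, loa_high, differences)`` with
    LoA = bias +- 1.96 * SD(differences, ddof=1).
    """
    auto = np.asarray(auto, dtype=float)
    manual = np.asarray(manual, dtype=float)
    if auto.shape != manual.shape:
        raise ValueError("paired series must have equal length")
    if len(auto) < 2:
        raise ValueError("need at least 2 pairs")
    diff = auto - manual
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return bias, bias - LOA_MULTIPLIER * sd, bias + LOA_MULTIPLIER * sd, diff


def location_test(auto, manual, force: Optional[str] = None):
    """Paired two-tailed location comparison with normality gating.

    Shapiro-Wilk on the paired differences (alpha = 0.05) chooses between
    the paired t-test (normal) and the Wilcoxon signed-rank test; ``force``
    overrides the gate with "t", "wilcoxon" or "mannwhitney" (the unpaired
    rank test, provided for completeness).  All-zero differences give the
    degenerate report ("degenerate", 0, 1).
    """
    auto = np.asarray(auto, dtype=float)
    manual = np.asarray(manual, dtype=float)
    if auto.shape != manual.shape or len(auto) < 3:
        raise ValueError("need paired samples with n >= 3")
    diff = auto - manual
    if np.allclose(diff, 0):
        return "degenerate", 0.0, 1.0
    if force is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            normal = stats.shapiro(diff).pvalue > NORMALITY_ALPHA
        force = "t" if normal else "wilcoxon"
    if force == "t":
        res = stats.ttest_rel(auto, manual)
        return "paired-t", float(res.statistic), float(res.pvalue)
    if force == "wilcoxon":
        res = stats.wilcoxon(auto, manual)
        return "wilcoxon", float(res.statistic), float(res.pvalue)
    if force == "mannwhitney":
        res = stats.mannwhitneyu(auto, manual, alternative="two-sided")
        return "mann-whitney", float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {force!r}")


def chi_square_association(table):
    """Pearson chi-square of association, no continuity correction.

    All-zero rows/columns are dropped (with a warning) before computation;
    a table smaller than 2x2 after dropping is an error.
    """
    table = np.asarray(table)
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        table = np.asarray(table, dtype=float)
        if np.any(table < 0) or np.any(table != np.round(table)):
            raise ValueError("contingency table must hold non-negative integers")
    row_ok = table.sum(axis=1) > 0
    col_ok = table.sum(axis=0) > 0
    if not (row_ok.all() and col_ok.all()):
        warnings.warn("dropping all-zero rows/columns from contingency table")
        table = table[row_ok][:, col_ok]
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least a 2x2 table with non-zero margins")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def confusion_and_macro(y_true, y_pred, classes: Sequence):
    """Confusion counts, row-normalised matrix, macro accuracy, per-class PRF.

    Rows are true classes, columns predicted; the normalised matrix divides
    each cell by its row sum (all-zero rows stay zero).  Macro accuracy is
    the unweighted mean of per-class recall; per-class precision/recall/F1
    define 0/0 as 0.
    """
    classes = list(classes)
    lut = {c: i for i, c in enumerate(classes)}
    for lab in list(y_true) + list(y_pred):
        if lab not in lut:
            raise ValueError(f"label {lab!r} not in class order {classes}")
    K = len(classes)
    cm = np.zeros((K, K), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[lut[t], lut[p]] += 1
    row_sums = cm.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(row_sums > 0, cm / np.maximum(row_sums, 1), 0.0)
    per_class: Dict[str, Dict[str, float]] = {}
    recalls = []
    for i, c in enumerate(classes):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        rec = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        per_class[str(c)] = {"precision": float(prec), "recall": float(rec),
                             "f1": float(f1)}
        if cm[i].sum() > 0:
            recalls.append(rec)
    macro = float(np.mean(recalls)) if recalls else 0.0
    return cm, norm, macro, per_class


def overlap_scores(mask_a, mask_b) -> Tuple[float, float]:
    """Intersection-over-union and Dice coefficient of two binary masks.

    Two empty masks score (1, 1) by convention.
    """
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    inter = float(np.logical_and(a, b).sum())
    union = float(np.logical_or(a, b).sum())
    size_sum = float(a.sum() + b.sum())
    if union == 0:
        return 1.0, 1.0
    return inter / union, 2.0 * inter / size_sum


def agreement_report(
    auto, manual,
    auto_labels=None, manual_labels=None, classes=None,
) -> AgreementReport:
    """Full agreement suite for a paired continuous series, optionally with
    categorical labels for the chi-square / confusion part."""
    r = pearson_r(auto, manual)
    bias, lo, hi, _ = bland_altman(auto, manual)
    name, statistic, p = location_test(auto, manual)
    rep = AgreementReport(r, bias, lo, hi, name, statistic, p)
    if auto_labels is not None and manual_labels is not None:
        if classes is None:
            classes = sorted(set(manual_labels) | set(auto_labels))
        cm, norm, macro, per_class = confusion_and_macro(
            manual_labels, auto_labels, classes)
        rep.confusion, rep.confusion_normalized = cm, norm
        rep.macro_accuracy, rep.per_class = macro, per_class
        try:
            rep.chi_square = chi_square_association(cm)
        except ValueError:
            rep.chi_square = None
    return rep
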