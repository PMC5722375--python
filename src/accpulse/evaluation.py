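"""Statistical evaluation of single-feature pulse detectors.

Implements the comparisons used to benchmark CCp against mean arterial
pressure and heart rate: two-sample Student's t, Pearson correlation,
ROC/AUC with sensitivity/specificity/accuracy at a fixed threshold, a paired
Z-test for correlated AUCs (DeLong's covariance estimate, with
Hanley-McNeil as an alternative), and a 2x2 Pearson chi-square for
proportions.  The elementary statistics are computed from their defining
formulas; scipy supplies only the reference distributions for p-values.

PR (perfusing rhythm) is the positive class throughout: sensitivity is the
ability to detect PR, specificity the ability to correctly classify PEA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .detection import ThresholdModel, optimize_threshold
from .exceptions import DegenerateInputError, ShapeError
from .io import FeatureTable

FEATURE_COLUMNS = {"CCp": "ccp", "MAP": "map_mmhg", "HR": "hr_bpm"}


@dataclass
class PerformanceReport:
    """AUC and thresholded confusion metrics for one feature."""

    feature: str
    auc: float
    sensitivity: float
    specificity: float
    accuracy: float
    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float | None = None

    def as_dict(self) -> dict:
        return {
            "feature": self.feature,
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "threshold": self.threshold,
        }

    def formatted(self) -> str:
        return (
            f"{self.feature}: AUC {self.auc:.3f}, sensitivity "
            f"{100 * self.sensitivity:.1f}%, specificity "
            f"{100 * self.specificity:.1f}%, accuracy {100 * self.accuracy:.1f}%"
        )


@dataclass
class ComparisonResult:
    """A named test statistic with its two-tailed p-value."""

    statistic_name: str
    statistic: float
    p_value: float
    df: float | None = None
    warning: str | None = None


def _check_classes(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pos = labels == "PR"
    neg = labels == "PEA"
    if not pos.any() or not neg.any():
        raise DegenerateInputError("need both PR and PEA examples")
    return pos, neg


def roc_auc(scores: np.ndarray, labels: np.ndarray | list) -> float:
    """AUC as the concordance probability P(score_PR > score_PEA), ties ½.

    Computed exactly from midranks (Mann-Whitney form); identical to the
    trapezoidal area under the empirical ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(scores) != len(labels):
        raise ShapeError("scores and labels must have equal length")
    pos, neg = _check_classes(labels)
    ranks = stats.rankdata(scores)  # midranks handle ties as 1/2
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def confusion_metrics(
    decisions: np.ndarray | list, labels: np.ndarray | list, feature: str = "CCp",
    auc: float = float("nan"), threshold: float | None = None,
) -> PerformanceReport:
    """Confusion counts and derived rates for binary pulse decisions.

    ``decisions`` holds "pulse_present"/"pulse_absent" (or booleans), with
    pulse_present meaning the segment is called PR.
    """
    decisions = np.asarray(decisions)
    labels = np.asarray(labels)
    if len(decisions) != len(labels):
        raise ShapeError("decisions and labels must have equal length")
    if decisions.dtype.kind in "USO":
        pred_pos = decisions == "pulse_present"
    else:
        pred_pos = decisions.astype(bool)
    pos, neg = _check_classes(labels)
    tp = int(np.count_nonzero(pred_pos & pos))
    fn = int(np.count_nonzero(~pred_pos & pos))
    tn = int(np.count_nonzero(~pred_pos & neg))
    fp = int(np.count_nonzero(pred_pos & neg))
    return PerformanceReport(
        feature=feature,
        auc=float(auc),
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        accuracy=(tp + tn) / (tp + fp + tn + fn),
        tp=tp, fp=fp, tn=tn, fn=fn,
        threshold=threshold,
    )


def students_t(
    a: np.ndarray, b: np.ndarray, welch: bool = False
) -> ComparisonResult:
    """Two-sample two-tailed Student's t (pooled variance by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise DegenerateInputError("each group needs at least two observations")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if welch:
        se2 = va / na + vb / nb
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se2 = sp2 * (1 / na + 1 / nb)
        df = na + nb - 2
    if se2 == 0.0:
        if ma == mb:
            return ComparisonResult("t_test", 0.0, 1.0, df=float(df))
        return ComparisonResult(
            "t_test", math.inf if ma > mb else -math.inf, 0.0, df=float(df),
            warning="zero pooled variance with unequal means",
        )
    t = (ma - mb) / math.sqrt(se2)
    p = 2.0 * stats.t.sf(abs(t), df)
    return ComparisonResult("t_test", float(t), float(p), df=float(df))


def pearson_r(x: np.ndarray, y: np.ndarray) -> ComparisonResult:
    """Sample Pearson correlation with two-tailed p via the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ShapeError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise DegenerateInputError("Pearson correlation needs n >= 3")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = math.sqrt(float(dx @ dx))
    sy = math.sqrt(float(dy @ dy))
    if sx == 0.0 or sy == 0.0:
        raise DegenerateInputError("zero variance: correlation undefined")
    r = float(dx @ dy) / (sx * sy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1 - r * r))
        p = 2.0 * stats.t.sf(abs(t), n - 2)
    return ComparisonResult("pearson_r", r, float(p), df=float(n - 2))


def _delong_structural_components(
    scores: np.ndarray, pos: np.ndarray, neg: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus the DeLong V10/V01 placement components via midranks."""
    xs = scores[pos]
    ys = scores[neg]
    m, n = len(xs), len(ys)
    all_ranks = stats.rankdata(np.r_[xs, ys])
    rx = stats.rankdata(xs)
    ry = stats.rankdata(ys)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - rx) / n          # P(score_PEA < x), ties 1/2
    v01 = 1.0 - (all_ranks[m:] - ry) / m    # P(x < score_PR), ties 1/2
    return float(auc), v10, v01


def compare_auc(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    labels: np.ndarray | list,
    method: str = "delong",
) -> ComparisonResult:
    """Paired Z-test for two correlated AUCs measured on the same segments.

    ``method="delong"`` uses DeLong's nonparametric covariance estimate;
    ``method="hanley"`` the Hanley-McNeil approximation with an average
    correlation correction.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if not (len(scores_a) == len(scores_b) == len(labels)):
        raise ShapeError("paired scores and labels must have equal length")
    pos, neg = _check_classes(labels)
    auc_a, v10_a, v01_a = _delong_structural_components(scores_a, pos, neg)
    auc_b, v10_b, v01_b = _delong_structural_components(scores_b, pos, neg)
    m, n = int(pos.sum()), int(neg.sum())
    if method == "delong":
        s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
        s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
        cov = s10 / m + s01 / n
        var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    elif method == "hanley":
        def hm_var(a):
            q1 = a / (2 - a)
            q2 = 2 * a * a / (1 + a)
            return (a * (1 - a) + (m - 1) * (q1 - a * a)
                    + (n - 1) * (q2 - a * a)) / (m * n)
        ra = np.corrcoef(np.r_[v10_a, v01_a], np.r_[v10_b, v01_b])[0, 1]
        va, vb = hm_var(auc_a), hm_var(auc_b)
        var_diff = va + vb - 2 * ra * math.sqrt(va * vb)
    else:
        raise DegenerateInputError(f"unknown AUC comparison method {method!r}")
    if var_diff <= 0:
        if auc_a == auc_b:
            return ComparisonResult("auc_z", 0.0, 1.0)
        return ComparisonResult(
            "auc_z", math.copysign(math.inf, auc_a - auc_b), 0.0,
            warning="degenerate variance in AUC comparison",
        )
    z = (auc_a - auc_b) / math.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return ComparisonResult("auc_z", float(z), float(p))


def chi_square_prop(k1: int, n1: int, k2: int, n2: int,
                    correction: bool = False) -> ComparisonResult:
    """2x2 Pearson chi-square comparing two proportions (df = 1).

    Continuity correction off by default.  A warning flag is set when any
    expected cell count is below 1.
    """
    if n1 < 1 or n2 < 1:
        raise DegenerateInputError("both samples need at least one trial")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if (table < 0).any():
        raise DegenerateInputError("successes cannot exceed trials")
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    warning = None
    if (expected < 1).any():
        warning = "expected cell count below 1"
    if (expected == 0).any():
        return ComparisonResult("chi_square", 0.0, 1.0, df=1.0,
                                warning="degenerate margin")
    resid = np.abs(table - expected)
    if correction:
        resid = np.maximum(resid - 0.5, 0.0)
    chi2 = float((resid**2 / expected).sum())
    p = float(stats.chi2.sf(chi2, 1))
    return ComparisonResult("chi_square", chi2, p, df=1.0, warning=warning)


def evaluate_feature(
    features: FeatureTable,
    feature: str,
    model: ThresholdModel | None = None,
    split: str = "testing",
) -> PerformanceReport:
    """Score one feature on one split of a feature table.

    If no model is given, a threshold is first fitted on the *other* split.
    AUC comes from the raw scores; sensitivity/specificity/accuracy from the
    thresholded decisions.
    """
    if feature not in FEATURE_COLUMNS:
        raise DegenerateInputError(
            f"unknown feature {feature!r}; expected one of {list(FEATURE_COLUMNS)}"
        )
    col = FEATURE_COLUMNS[feature]
    if model is None:
        other = "training" if split == "testing" else "testing"
        fit = features.subset(other)
        model = optimize_threshold(fit[col].to_numpy(), fit["label"].to_numpy(),
                                   feature=feature)
    part = features.subset(split)
    scores = part[col].to_numpy(dtype=float)
    labels = part["label"].to_numpy()
    auc = roc_auc(scores, labels)
    decisions = np.where(scores > model.threshold, "pulse_present", "pulse_absent")
    return confusion_metrics(decisions, labels, feature=feature, auc=auc,
                             threshold=model.threshold)
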