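"""Spontaneous pulse detection from the ECG-ACC cross-correlation peak.

The detector computes the normalized cross-correlation sequence between the
band-pass-filtered ECG ``x`` and acceleration ``y`` of one compression-free
segment over the full lag range l = 0, ±1, ... ±(N-1):

    r_xy(l) = sum_n x(n) y(n-l) / sqrt(sum x(n)^2 * sum y(n)^2)

with out-of-range products treated as zero (linear, non-circular
correlation).  The square-root energy normalization bounds the sequence in
[-1, 1] (Cauchy-Schwarz); the alternative "energy_product" mode divides by
the plain product of energies instead and is kept for comparison only.

The peak correlation coefficient CCp is the signed maximum of the sequence;
a segment is classified as having a spontaneous pulse when CCp exceeds a
threshold learned on a training set by exhaustive accuracy maximization.

A positive mechanical (electromechanical) delay of the acceleration relative
to the ECG appears at a *negative* lag under the convention above, so the
delay estimate is ``-peak_lag / sample_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .exceptions import ConfigurationError, DegenerateInputError, ShapeError
from .preprocess import ACC_FILTER, ECG_FILTER, FilterSpec, bandpass
from .segmentation import Segment

NORMALIZATIONS = ("energy_sqrt", "energy_product")

#: CCp decision threshold reported for the study's training set.
DEFAULT_CCP_THRESHOLD = 0.22


@dataclass
class CrossCorrelation:
    """Normalized cross-correlation sequence over lags -(N-1) .. +(N-1)."""

    lags: np.ndarray
    values: np.ndarray
    normalization: str = "energy_sqrt"

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.lags) != len(self.values):
            raise ShapeError("lags and values must have equal length")
        if self.normalization not in NORMALIZATIONS:
            raise ConfigurationError(
                f"unknown normalization {self.normalization!r}"
            )


@dataclass
class DetectionResult:
    """CCp, its lag, and (once thresholded) the binary pulse decision."""

    segment_id: str
    ccp: float
    peak_lag: int
    decision: str | None = None
    threshold_used: float | None = None

    @property
    def delay_estimate_s(self) -> float | None:
        """Mechanical-delay estimate in seconds; requires the sample rate
        stored by :func:`ccp_for_segment` (see ``sample_rate_hz``)."""
        if self.sample_rate_hz is None:
            return None
        return -self.peak_lag / self.sample_rate_hz

    sample_rate_hz: float | None = None


@dataclass
class ThresholdModel:
    """A single-feature decision rule: positive iff value > threshold."""

    feature: str
    threshold: float
    direction: str = "greater_is_positive"
    training_accuracy: float | None = None


def normalized_xcorr(
    x: np.ndarray, y: np.ndarray, normalization: str = "energy_sqrt"
) -> CrossCorrelation:
    """Full-lag normalized cross-correlation of two equal-length series.

    FFT-accelerated; agrees with the direct O(N²) lag-by-lag sum to ~1e-12.
    Raises on length mismatch or an all-zero input (the correlation is
    undefined without signal energy).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
        raise ShapeError(
            f"x and y must be 1-D of equal length, got {x.shape} and {y.shape}"
        )
    n = len(x)
    if n < 2:
        raise ShapeError("need at least two samples")
    ex = float(np.dot(x, x))
    ey = float(np.dot(y, y))
    if ex == 0.0 or ey == 0.0:
        raise DegenerateInputError("all-zero input: correlation undefined")
    if normalization == "energy_sqrt":
        denom = np.sqrt(ex * ey)
    elif normalization == "energy_product":
        denom = ex * ey
    else:
        raise ConfigurationError(f"unknown normalization {normalization!r}")
    # scipy full correlation index i corresponds to lag l = i - (N-1) with
    # c[l] = sum_n x(n) y(n-l), matching the definition above.
    values = sps.correlate(x, y, mode="full", method="auto") / denom
    lags = np.arange(-(n - 1), n)
    return CrossCorrelation(lags=lags, values=values, normalization=normalization)


def peak_correlation(cc: CrossCorrelation) -> tuple[float, int]:
    """Signed maximum of the sequence and its lag.

    Ties in value are broken toward the smallest absolute lag, then toward
    the negative lag.
    """
    values = cc.values
    vmax = values.max()
    candidates = cc.lags[values == vmax]
    order = np.lexsort((candidates, np.abs(candidates)))
    return float(vmax), int(candidates[order[0]])


def ccp_for_segment(
    seg: Segment,
    sample_rate_hz: float | None = None,
    ecg_spec: FilterSpec = ECG_FILTER,
    acc_spec: FilterSpec = ACC_FILTER,
    normalization: str = "energy_sqrt",
    use_abs: bool = False,
) -> DetectionResult:
    """Filter the segment's ECG and ACC, cross-correlate, take the peak.

    ``use_abs`` switches CCp to the maximum of absolute values (off by
    default: CCp is the signed maximum).
    """
    fs = sample_rate_hz or seg.sample_rate_hz
    xf = bandpass(seg.ecg, fs, ecg_spec)
    yf = bandpass(seg.acc, fs, acc_spec)
    cc = normalized_xcorr(xf, yf, normalization=normalization)
    if use_abs:
        cc = replace(cc, values=np.abs(cc.values))
    ccp, lag = peak_correlation(cc)
    return DetectionResult(
        segment_id=seg.segment_id, ccp=ccp, peak_lag=lag, sample_rate_hz=fs
    )


def detect_pulse(result: DetectionResult, model: ThresholdModel) -> DetectionResult:
    """Apply a CCp threshold model: pulse present iff ccp > threshold."""
    if model.feature.lower() != "ccp":
        raise ConfigurationError(
            f"detect_pulse requires a CCp model, got feature {model.feature!r}"
        )
    decision = "pulse_present" if result.ccp > model.threshold else "pulse_absent"
    return replace(result, decision=decision, threshold_used=model.threshold)


def optimize_threshold(
    values: np.ndarray, labels: np.ndarray | list, feature: str = "CCp"
) -> ThresholdModel:
    """Exhaustive accuracy-maximizing threshold for rule value > threshold.

    Candidate thresholds are the midpoints between consecutive distinct
    sorted values, plus one candidate below the minimum and one above the
    maximum.  Accuracy ties are broken by the higher sensitivity, then the
    smaller threshold.  PR is the positive class.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if len(values) != len(labels):
        raise ShapeError("values and labels must have equal length")
    if not np.all(np.isfinite(values)):
        raise DegenerateInputError("non-finite feature values")
    pos = labels == "PR"
    neg = labels == "PEA"
    if not pos.any() or not neg.any():
        raise DegenerateInputError(
            "threshold training needs both PR and PEA examples"
        )
    distinct = np.unique(values)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    span = max(distinct[-1] - distinct[0], 1.0)
    candidates = np.r_[distinct[0] - 0.05 * span, mids, distinct[-1] + 0.05 * span]
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    best = None  # (accuracy, sensitivity, -threshold)
    best_model = None
    for thr in candidates:
        pred_pos = values > thr
        tp = int(np.count_nonzero(pred_pos & pos))
        tn = int(np.count_nonzero(~pred_pos & neg))
        acc = (tp + tn) / (n_pos + n_neg)
        sens = tp / n_pos
        key = (acc, sens, -thr)
        if best is None or key > best:
            best = key
            best_model = ThresholdModel(
                feature=feature, threshold=float(thr), training_accuracy=acc
            )
    return best_model
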