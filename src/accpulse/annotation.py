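"""Segment labelling: rhythm class, hemodynamics, heart rate and pressures.

The study's labels were assigned by a physician; here an automatic stand-in
reproduces the same rules so a synthetic dataset can be labelled end to end:

* organized rhythm  := at least one QRS complex in the 3-s window;
* perfusing rhythm (PR) := organized AND systolic pressure > 60 mmHg AND
  pulse pressure > 10 mmHg (strict inequalities);
* pulseless electrical activity (PEA) := organized but not PR;
* disorganized segments get hemodynamic class ``not_applicable``.

QRS detection is a Pan-Tompkins-style rectified-derivative detector with a
0.2 s refractory period.  Manual QRS marks can be supplied to override the
detector, mirroring the study's human annotation path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal as sps

from .exceptions import DataError
from .segmentation import Segment

#: Refractory period between QRS detections (s).
QRS_REFRACTORY_S = 0.2
#: Moving-window-integration length (s), about one wide QRS complex.
MWI_WINDOW_S = 0.15
#: Peaks must exceed this fraction of the largest integrated peak.
PEAK_FRACTION = 0.30
#: Minimum fraction of ECG energy above QRS_GATE_HZ.  Sharp QRS deflections
#: carry substantial energy above 10 Hz whereas fibrillation-like activity
#: is concentrated in the 3-8 Hz band, so segments failing this gate are
#: treated as having no discrete complexes.
HF_ENERGY_FRACTION_MIN = 0.02
QRS_GATE_HZ = 10.0
#: Absolute floor (mV²·s scale) below which a trace is treated as flat line.
FLATLINE_EPS = 1e-8

RHYTHM_CLASSES = ("organized", "disorganized")
HEMODYNAMIC_CLASSES = ("PR", "PEA", "not_applicable")
EXCLUSION_REASONS = ("rhythm_transition", "defibrillation_shock", "none")

#: PR definition thresholds (mmHg), strict inequalities.
SAP_THRESHOLD_MMHG = 60.0
PULSE_PRESSURE_THRESHOLD_MMHG = 10.0


@dataclass
class SegmentAnnotation:
    """Labels and hemodynamic measurements for one segment."""

    segment_id: str
    rhythm: str
    hemodynamic: str
    sap_mmhg: float
    pulse_pressure_mmhg: float
    map_mmhg: float
    hr_bpm: float | None
    qrs_indices: list[int] = field(default_factory=list)
    excluded: bool = False
    exclusion_reason: str = "none"
    source: str = "automatic"

    def __post_init__(self) -> None:
        if self.rhythm not in RHYTHM_CLASSES:
            raise DataError(f"unknown rhythm class {self.rhythm!r}")
        if self.hemodynamic not in HEMODYNAMIC_CLASSES:
            raise DataError(f"unknown hemodynamic class {self.hemodynamic!r}")
        if self.exclusion_reason not in EXCLUSION_REASONS:
            raise DataError(f"unknown exclusion reason {self.exclusion_reason!r}")
        self.excluded = self.exclusion_reason != "none"


def detect_qrs(ecg: np.ndarray, sample_rate_hz: float) -> list[int]:
    """Detect QRS fiducial points on an already band-pass-filtered ECG.

    Rectified derivative -> squaring -> moving-window integration -> peak
    picking with an adaptive threshold and a 0.2 s refractory period.  The
    fiducial is placed on the local extremum of the filtered ECG inside each
    integration peak.  Returns a strictly increasing (possibly empty) list.
    """
    x = np.asarray(ecg, dtype=float)
    fs = float(sample_rate_hz)
    if len(x) < int(0.5 * fs):
        return []
    deriv = np.gradient(x) * fs
    energy = deriv * deriv
    # taper the edges: complexes cut by the window boundary produce filter
    # transients that would otherwise dominate the adaptive threshold
    n_taper = min(int(0.1 * fs), len(energy) // 4)
    if n_taper > 1:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_taper) / n_taper))
        energy[:n_taper] *= ramp
        energy[-n_taper:] *= ramp[::-1]
    mwi = ndimage.uniform_filter1d(energy, size=max(1, int(MWI_WINDOW_S * fs)),
                                   mode="nearest")
    peak_max = float(mwi.max())
    if peak_max < FLATLINE_EPS:
        return []
    sos_hp = sps.butter(4, QRS_GATE_HZ, btype="highpass", fs=fs, output="sos")
    hf = sps.sosfiltfilt(sos_hp, x)
    if float(hf @ hf) < HF_ENERGY_FRACTION_MIN * float(x @ x):
        return []
    refractory = max(1, int(QRS_REFRACTORY_S * fs))
    # zero-pad so maxima at the window edges are still picked up
    locs, _ = sps.find_peaks(np.r_[0.0, mwi, 0.0],
                             height=PEAK_FRACTION * peak_max,
                             distance=refractory)
    locs = locs - 1
    half = max(1, int(MWI_WINDOW_S * fs / 2))
    fiducials: list[int] = []
    for loc in locs:
        lo, hi = max(0, loc - half), min(len(x), loc + half + 1)
        fid = lo + int(np.argmax(np.abs(x[lo:hi])))
        if not fiducials or fid - fiducials[-1] >= refractory:
            fiducials.append(fid)
    return fiducials


def classify_rhythm(seg_or_len, qrs: list[int]) -> str:
    """Organized iff at least one QRS complex is present in the segment."""
    return "organized" if len(qrs) >= 1 else "disorganized"


def abp_features(abp: np.ndarray, sample_rate_hz: float | None = None):
    """Systolic, diastolic, pulse pressure and mean pressure of a raw ABP slice.

    SAP is the maximum, DAP the minimum, pulse pressure their difference and
    MAP the arithmetic mean over the window.
    """
    abp = np.asarray(abp, dtype=float)
    if not np.all(np.isfinite(abp)):
        raise DataError("non-finite samples in ABP slice")
    sap = float(abp.max())
    dap = float(abp.min())
    return sap, dap, sap - dap, float(abp.mean())


def map_from_dap_pp(dap_mmhg: float, pulse_pressure_mmhg: float) -> float:
    """Alternative MAP estimator DAP + PP/3 (off by default; the window
    mean of the ABP samples is the primary definition)."""
    return dap_mmhg + pulse_pressure_mmhg / 3.0


def classify_hemodynamics(
    rhythm: str, sap_mmhg: float, pulse_pressure_mmhg: float
) -> str:
    """PR iff organized with SAP > 60 and pulse pressure > 10 (strict)."""
    if rhythm == "disorganized":
        return "not_applicable"
    if sap_mmhg > SAP_THRESHOLD_MMHG and pulse_pressure_mmhg > PULSE_PRESSURE_THRESHOLD_MMHG:
        return "PR"
    return "PEA"


def heart_rate(qrs: list[int], sample_rate_hz: float) -> float | None:
    """Heart rate (bpm) from the median RR interval; None with < 2 complexes.

    The median is robust to one missed or spurious detection in a short
    window, unlike count-over-duration.
    """
    if len(qrs) < 2:
        return None
    idx = np.asarray(qrs, dtype=float)
    if np.any(np.diff(idx) <= 0):
        raise DataError("QRS indices must be strictly increasing")
    rr_s = np.diff(idx) / sample_rate_hz
    return float(60.0 / np.median(rr_s))


def annotate_segment(
    seg: Segment,
    filtered_ecg: np.ndarray | None = None,
    manual_qrs: list[int] | None = None,
    exclusion_reason: str = "none",
) -> SegmentAnnotation:
    """Produce the full annotation for one segment.

    ``filtered_ecg`` may be supplied to avoid re-filtering; otherwise the
    segment ECG is band-passed here.  ``manual_qrs`` overrides the detector
    (source becomes "manual"), mirroring the study's physician annotation.
    """
    from .preprocess import preprocess_ecg

    if manual_qrs is not None:
        qrs = sorted(int(i) for i in manual_qrs)
        source = "manual"
    else:
        if filtered_ecg is None:
            filtered_ecg = preprocess_ecg(seg.ecg, seg.sample_rate_hz)
        qrs = detect_qrs(filtered_ecg, seg.sample_rate_hz)
        source = "automatic"
    rhythm = classify_rhythm(seg, qrs)
    sap, _dap, pp, map_ = abp_features(seg.abp)
    hemo = classify_hemodynamics(rhythm, sap, pp)
    return SegmentAnnotation(
        segment_id=seg.segment_id,
        rhythm=rhythm,
        hemodynamic=hemo,
        sap_mmhg=sap,
        pulse_pressure_mmhg=pp,
        map_mmhg=map_,
        hr_bpm=heart_rate(qrs, seg.sample_rate_hz),
        qrs_indices=list(qrs),
        exclusion_reason=exclusion_reason,
        source=source,
    )
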