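"""Chest-compression episode detection and compression-free segment extraction.

Compressions produce ~46 m/s² oscillations in the acceleration channel while
the pulse-synchronous oscillations during pauses are ~1.8 m/s², so a pause is
simply a maximal run where the moving-RMS envelope of the acceleration stays
below an amplitude threshold (10 m/s² by default, between the two regimes)
for at least a minimum duration.  Fixed-length analysis segments (3 s = 900
samples at 300 Hz) are anchored at the start of each qualifying pause.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .exceptions import ConfigurationError, LengthError
from .io import Recording

logger = logging.getLogger(__name__)

#: Envelope window (s); long enough to smooth over a 2 Hz compression cycle.
ENVELOPE_WINDOW_S = 0.5
#: Pause / compression amplitude threshold (m/s²).
PAUSE_THRESHOLD_MS2 = 10.0
#: Minimum pause duration (s); the study used 3-5 s compression pauses.
MIN_PAUSE_S = 3.0
#: Analysis segment duration (s).
SEGMENT_DURATION_S = 3.0


@dataclass(frozen=True)
class PauseInterval:
    """Half-open sample-index interval [start_idx, end_idx) of one CC pause."""

    start_idx: int
    end_idx: int
    sample_rate_hz: float

    def __post_init__(self) -> None:
        if not self.start_idx < self.end_idx:
            raise ConfigurationError(
                f"pause interval start {self.start_idx} must precede end "
                f"{self.end_idx}"
            )

    @property
    def duration_s(self) -> float:
        return (self.end_idx - self.start_idx) / self.sample_rate_hz


@dataclass
class Segment:
    """One fixed-length compression-free analysis window with channel slices."""

    segment_id: str
    source_record: str
    start_idx: int
    sample_rate_hz: float
    ecg: np.ndarray
    abp: np.ndarray
    acc: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ecg = np.asarray(self.ecg, dtype=float)
        self.abp = np.asarray(self.abp, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        if not (len(self.ecg) == len(self.abp) == len(self.acc)):
            raise LengthError("segment channel slices must have equal length")

    @property
    def n_samples(self) -> int:
        return len(self.ecg)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz


def acc_envelope(
    acc: np.ndarray, sample_rate_hz: float, window_s: float = ENVELOPE_WINDOW_S
) -> np.ndarray:
    """Moving root-mean-square of the mean-removed acceleration.

    The window is centred; edges are handled by reflection.  A one-sample
    window degenerates to the absolute mean-removed signal.
    """
    if window_s <= 0:
        raise ConfigurationError(f"window_s must be positive, got {window_s}")
    n = max(1, int(round(window_s * sample_rate_hz)))
    x = np.asarray(acc, dtype=float)
    x = x - x.mean()
    ms = ndimage.uniform_filter1d(x * x, size=n, mode="reflect")
    return np.sqrt(np.maximum(ms, 0.0))


def detect_pauses(
    acc: np.ndarray,
    sample_rate_hz: float,
    threshold_ms2: float = PAUSE_THRESHOLD_MS2,
    min_pause_s: float = MIN_PAUSE_S,
    window_s: float = ENVELOPE_WINDOW_S,
) -> list[PauseInterval]:
    """Find maximal sub-threshold runs of the envelope lasting >= min_pause_s.

    Returns non-overlapping intervals in temporal order.
    """
    if threshold_ms2 <= 0 or min_pause_s <= 0:
        raise ConfigurationError("threshold_ms2 and min_pause_s must be positive")
    acc = np.asarray(acc, dtype=float)
    min_len = int(round(min_pause_s * sample_rate_hz))
    if len(acc) < min_len:
        raise LengthError(
            f"record of {len(acc)} samples is shorter than one minimum pause "
            f"({min_len} samples)"
        )
    quiet = acc_envelope(acc, sample_rate_hz, window_s) < threshold_ms2
    # run-length encode the boolean mask
    edges = np.flatnonzero(np.diff(quiet.astype(np.int8)))
    starts = np.r_[0, edges + 1]
    ends = np.r_[edges + 1, len(quiet)]
    pauses = [
        PauseInterval(int(s), int(e), sample_rate_hz)
        for s, e in zip(starts, ends)
        if quiet[s] and (e - s) >= min_len
    ]
    return pauses


def extract_segments(
    rec: Recording,
    pauses: list[PauseInterval],
    duration_s: float = SEGMENT_DURATION_S,
    guard_offset_s: float = 0.0,
) -> list[Segment]:
    """Cut one fixed-length segment at the start of each qualifying pause.

    Pauses shorter than ``guard_offset_s + duration_s`` yield no segment and
    are logged as skipped.  Segments are anchored at the pause start (plus
    the optional guard offset), never re-centred.
    """
    if duration_s <= 0:
        raise ConfigurationError("duration_s must be positive")
    n = int(round(duration_s * rec.sample_rate_hz))
    guard = int(round(guard_offset_s * rec.sample_rate_hz))
    segments: list[Segment] = []
    for k, pause in enumerate(pauses):
        start = pause.start_idx + guard
        if start + n > pause.end_idx or start + n > len(rec):
            logger.info(
                "skipping pause %d at sample %d: duration %.2f s < %.2f s",
                k, pause.start_idx, pause.duration_s, guard_offset_s + duration_s,
            )
            continue
        sl = slice(start, start + n)
        segments.append(
            Segment(
                segment_id=f"{rec.record_id}_p{k:03d}",
                source_record=rec.record_id,
                start_idx=start,
                sample_rate_hz=rec.sample_rate_hz,
                ecg=rec.ecg[sl].copy(),
                abp=rec.abp[sl].copy(),
                acc=rec.acc[sl].copy(),
            )
        )
    return segments
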