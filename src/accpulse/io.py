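"""Reading and writing multichannel waveform records and feature tables.

The canonical interchange format is a plain CSV with one row per sample and
the header ``time_s,ecg_mv,abp_mmhg,acc_ms2``.  Lines starting with ``#``
before the header are treated as comments.  Time is in seconds, samples are
indexed from 0, and all index intervals in this package are half-open
``[start, end)``.

Feature tables hold one row per analysed segment (set assignment, class
label, mean arterial pressure, peak correlation coefficient, heart rate) and
may be CSV or XLSX; column headers are mapped through a configurable
dictionary because external tables name them inconsistently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    AnnotationError,
    DataError,
    EmptyInputError,
    FormatError,
    ShapeError,
    TimingError,
)

logger = logging.getLogger(__name__)

WAVEFORM_COLUMNS = ("time_s", "ecg_mv", "abp_mmhg", "acc_ms2")

#: Relative tolerance on the uniformity of the time base.
TIMEBASE_RTOL = 1e-6

#: Default header map for feature tables: canonical name -> accepted aliases.
DEFAULT_FEATURE_COLUMNS = {
    "segment_id": ("segment_id", "segment", "id"),
    "set_assignment": ("set_assignment", "set", "split", "dataset"),
    "label": ("label", "class", "rhythm_label", "group"),
    "map_mmhg": ("map_mmhg", "map", "map (mmhg)", "mean_arterial_pressure"),
    "ccp": ("ccp", "cc_p", "peak_correlation", "ccp_value"),
    "hr_bpm": ("hr_bpm", "hr", "heart_rate", "hr (beats/min)"),
}

DEFAULT_LABEL_MAP = {"pr": "PR", "pea": "PEA"}
DEFAULT_SET_MAP = {"training": "training", "train": "training",
                   "testing": "testing", "test": "testing"}


@dataclass
class Recording:
    """Time-aligned ECG / ABP / ACC channels sampled at a common rate.

    Parameters
    ----------
    record_id : str
        Free-text label for the record.
    sample_rate_hz : float
        Sampling rate, > 0.  The study hardware sampled at 300 Hz.
    ecg, abp, acc : ndarray
        Equal-length channel arrays in mV, mmHg and m/s².
    t0_s : float
        Time of the first sample.
    metadata : dict
        Free-form key -> text map (animal id, arrest model, ...).
    """

    record_id: str
    sample_rate_hz: float
    ecg: np.ndarray
    abp: np.ndarray
    acc: np.ndarray
    t0_s: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ecg = np.asarray(self.ecg, dtype=float)
        self.abp = np.asarray(self.abp, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        if not (len(self.ecg) == len(self.abp) == len(self.acc)):
            raise ShapeError(
                f"channel lengths differ: ecg={len(self.ecg)} "
                f"abp={len(self.abp)} acc={len(self.acc)}"
            )
        if len(self.ecg) < 1:
            raise EmptyInputError("recording has no samples")
        if not self.sample_rate_hz > 0:
            raise DataError(f"sample_rate_hz must be > 0, got {self.sample_rate_hz}")
        for name in ("ecg", "abp", "acc"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise DataError(f"non-finite samples in channel {name!r}")

    def __len__(self) -> int:
        return len(self.ecg)

    @property
    def duration_s(self) -> float:
        return len(self) / self.sample_rate_hz

    @property
    def time_s(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self)) / self.sample_rate_hz


def read_recording(path: str | Path, record_id: str | None = None) -> Recording:
    """Read a waveform CSV into a :class:`Recording`.

    The sample rate is inferred from the median time step; the time column
    must be strictly increasing and uniform within relative tolerance
    ``TIMEBASE_RTOL``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path} is empty") from None
    if df.empty:
        raise EmptyInputError(f"{path} contains a header but no samples")
    for col in WAVEFORM_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path} is missing required column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise TimingError(f"{path}: time column is not strictly increasing")
        step = float(np.median(dt))
        if np.max(np.abs(dt - step)) > TIMEBASE_RTOL * max(step, abs(t[-1])):
            raise TimingError(
                f"{path}: non-uniform time base (max deviation "
                f"{np.max(np.abs(dt - step)):.3g} s from step {step:.3g} s)"
            )
        rate = 1.0 / step
    else:
        rate = float("nan")
        raise TimingError(f"{path}: cannot infer sample rate from a single sample")
    return Recording(
        record_id=record_id or path.stem,
        sample_rate_hz=rate,
        t0_s=float(t[0]),
        ecg=df["ecg_mv"].to_numpy(dtype=float),
        abp=df["abp_mmhg"].to_numpy(dtype=float),
        acc=df["acc_ms2"].to_numpy(dtype=float),
    )


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a :class:`Recording` as a waveform CSV (full float precision)."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": rec.time_s,
            "ecg_mv": rec.ecg,
            "abp_mmhg": rec.abp,
            "acc_ms2": rec.acc,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")
    return path


@dataclass
class FeatureTable:
    """Per-segment features used by threshold training and evaluation.

    ``frame`` has columns segment_id, set_assignment (training/testing),
    label (PR/PEA), map_mmhg, ccp, hr_bpm.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = list(DEFAULT_FEATURE_COLUMNS)
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise FormatError(f"feature table is missing columns {missing}")
        if self.frame["segment_id"].duplicated().any():
            dupes = self.frame.loc[
                self.frame["segment_id"].duplicated(), "segment_id"
            ].tolist()
            raise FormatError(f"duplicate segment_id values: {dupes[:5]}")
        bad_sets = set(self.frame["set_assignment"]) - {"training", "testing"}
        if bad_sets:
            raise AnnotationError(f"unmapped set_assignment values: {sorted(bad_sets)}")
        bad_labels = set(self.frame["label"]) - {"PR", "PEA"}
        if bad_labels:
            raise AnnotationError(f"unmapped label values: {sorted(bad_labels)}")

    def subset(self, split: str) -> pd.DataFrame:
        return self.frame[self.frame["set_assignment"] == split]

    def counts(self) -> pd.Series:
        return self.frame.groupby(["set_assignment", "label"]).size()


def _resolve_columns(df: pd.DataFrame, column_map: dict | None) -> pd.DataFrame:
    """Rename columns of *df* onto the canonical feature-table names."""
    lower = {str(c).strip().lower(): c for c in df.columns}
    rename: dict = {}
    for canonical, aliases in DEFAULT_FEATURE_COLUMNS.items():
        if column_map and canonical in column_map:
            aliases = (column_map[canonical],)
        for alias in aliases:
            key = str(alias).strip().lower()
            if key in lower:
                rename[lower[key]] = canonical
                break
        else:
            raise FormatError(
                f"no column found for {canonical!r}; tried {list(aliases)}"
            )
    return df.rename(columns=rename)[list(DEFAULT_FEATURE_COLUMNS)]


def read_feature_table(
    path: str | Path,
    column_map: dict | None = None,
    label_map: dict | None = None,
    sheet: int | str = 0,
) -> FeatureTable:
    """Read a per-segment feature table from CSV or XLSX.

    ``column_map`` maps canonical names (segment_id, set_assignment, label,
    map_mmhg, ccp, hr_bpm) to the file's header names when they differ from
    the built-in aliases.  Labels are normalised onto {PR, PEA}; unmapped
    values raise :class:`AnnotationError`.
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        df = pd.read_excel(path, sheet_name=sheet)
    else:
        df = pd.read_csv(path, comment="#")
    if df.empty:
        raise EmptyInputError(f"{path} contains no rows")
    df = _resolve_columns(df, column_map)

    lmap = dict(DEFAULT_LABEL_MAP)
    if label_map:
        lmap.update({str(k).strip().lower(): v for k, v in label_map.items()})
    labels = df["label"].astype(str).str.strip().str.lower()
    unmapped = sorted(set(labels) - set(lmap))
    if unmapped:
        raise AnnotationError(f"unmapped label values: {unmapped}")
    df["label"] = labels.map(lmap)

    sets = df["set_assignment"].astype(str).str.strip().str.lower()
    unmapped = sorted(set(sets) - set(DEFAULT_SET_MAP))
    if unmapped:
        raise AnnotationError(f"unmapped set_assignment values: {unmapped}")
    df["set_assignment"] = sets.map(DEFAULT_SET_MAP)
    df["segment_id"] = df["segment_id"].astype(str)
    for col in ("map_mmhg", "ccp", "hr_bpm"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    table = FeatureTable(df.reset_index(drop=True))
    for (split, label), n in table.counts().items():
        logger.info("feature table: %s %s rows = %d", split, label, n)
    return table
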