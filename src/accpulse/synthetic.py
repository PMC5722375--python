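"""Seeded generator of porcine-CPR-like waveforms and labelled datasets.

The generator emulates the statistical structure the pulse detector relies
on, so every pipeline stage is testable without animal data:

* ECG: trains of wide peri-arrest complexes (a sharp biphasic QRS spike plus
  a co-centred slow hump, per-segment morphology drawn at random), with ±5 %
  RR jitter, 0.3 Hz baseline wander and Gaussian noise; disorganized rhythms
  are a 3-8 Hz band-limited Gaussian process with no repeating template.
* ABP: per-beat pressure pulses (fast systolic upstroke, exponential
  diastolic decay) delayed 100-200 ms after each QRS, scaled to a target
  mean pressure: perfusing rhythms (PR) satisfy SAP > 60 / pulse pressure
  > 10 mmHg, pulseless electrical activity (PEA) does not.
* ACC: ~2 Hz compression bursts of ~46 m/s² during compression episodes;
  during pauses, Gaussian background noise plus - only for PR - a
  pulse-synchronous mechanical transient after each QRS at a fixed
  electromechanical delay.  The transient has the beat's own time course, so
  its 0.5-7.5 Hz component is a damped low-frequency oscillation
  phase-locked to the ECG.

Group-level parameters default to the reported porcine study statistics
(heart rate 159±51 vs 86±45 bpm, MAP 115.3±36.3 vs 15.2±9.5 mmHg,
compression vs pulse oscillation amplitude 46.35±15.95 vs 1.83±0.96 m/s²).
Everything is reproducible from (params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .exceptions import ConfigurationError
from .io import Recording
from .segmentation import PauseInterval, Segment


@dataclass(frozen=True)
class GeneratorParams:
    """Study-condition parameters of the synthetic generator.

    ``(mean, sd)`` pairs are sampled from clipped normal distributions.
    Sampled heart rates are clipped to [30, 300] bpm and pressures to
    physiological ranges.
    """

    sample_rate_hz: float = 300.0
    duration_s: float = 3.0
    hr_pr_bpm: tuple[float, float] = (159.0, 51.0)
    hr_pea_bpm: tuple[float, float] = (86.0, 45.0)
    map_pr_mmhg: tuple[float, float] = (115.3, 36.3)
    map_pea_mmhg: tuple[float, float] = (15.2, 9.5)
    cc_osc_amp_ms2: tuple[float, float] = (46.35, 15.95)
    pulse_osc_amp_ms2: tuple[float, float] = (1.83, 0.96)
    acc_noise_sd_ms2: float = 0.4
    ecg_noise_sd_mv: float = 0.05
    abp_noise_sd_mmhg: float = 0.5
    baseline_wander_mv: float = 0.05
    mech_delay_s: tuple[float, float] = (0.05, 0.20)
    rr_jitter_frac: float = 0.05
    beat_amp_jitter_frac: float = 0.25
    pause_s: tuple[float, float] = (3.0, 5.0)
    compression_rate_hz: float = 1.83  # ~110 compressions/min
    compression_episode_s: tuple[float, float] = (12.0, 18.0)
    hr_clip_bpm: tuple[float, float] = (30.0, 300.0)

    def rate(self) -> float:
        return self.sample_rate_hz


DEFAULT_PARAMS = GeneratorParams()


def _clipped_normal(rng, mean_sd, lo=None, hi=None) -> float:
    v = rng.normal(*mean_sd)
    if lo is not None:
        v = max(lo, v)
    if hi is not None:
        v = min(hi, v)
    return float(v)


def _make_beat(rng: np.random.Generator, fs: float) -> tuple[np.ndarray, int]:
    """One beat template: sharp biphasic QRS + co-centred slow hump.

    The hump stands in for the fused low-frequency repolarisation component
    of wide peri-arrest complexes; it carries the beat's sub-7.5 Hz energy.
    Returns (template, fiducial index).
    """
    qrs_width_s = rng.uniform(0.07, 0.13)
    hump_amp = rng.uniform(0.2, 0.6)
    hump_width_s = rng.uniform(0.12, 0.22)
    length = int(0.5 * fs)
    beat = np.zeros(length)
    fid = length // 2
    n = max(3, int(qrs_width_s * fs))
    t = np.linspace(-1, 1, n)
    spike = -t * np.exp(-0.5 * (t / 0.35) ** 2)
    spike /= np.abs(spike).max()
    i0 = fid - n // 2
    beat[i0:i0 + n] += spike
    nh = max(3, int(hump_width_s * fs))
    th = np.linspace(-2.5, 2.5, nh)
    j0 = fid - nh // 2
    beat[j0:j0 + nh] += hump_amp * np.exp(-0.5 * th * th)
    return beat, fid


def _add_train(
    x: np.ndarray,
    template: np.ndarray,
    fid: int,
    times_s: np.ndarray,
    fs: float,
    scales: np.ndarray | None = None,
) -> np.ndarray:
    """Superimpose copies of *template* with fiducials at *times_s* (clipped
    at the array edges)."""
    for k, tq in enumerate(np.atleast_1d(times_s)):
        i = int(round(tq * fs)) - fid
        s, e = max(0, i), min(len(x), i + len(template))
        if e <= s:
            continue
        a = 1.0 if scales is None else scales[k]
        x[s:e] += a * template[s - i:e - i]
    return x


def _beat_times(
    rng: np.random.Generator,
    hr_bpm: float,
    duration_s: float,
    rr_jitter_frac: float,
    window: tuple[float, float] | None = None,
) -> np.ndarray:
    """Jittered QRS fiducial times.

    With ``window=(lo, hi)`` the train is confined so complete beat cycles
    lie inside the analysis window (used by controlled delay-recovery
    experiments); otherwise the train covers [0, duration) with a random
    phase, so edge beats may be cut by the window exactly as in a slice of a
    longer recording.
    """
    rr = 60.0 / hr_bpm
    if window is None:
        lo, hi = 0.0, duration_s
    else:
        lo, hi = window
    t = lo + rng.uniform(0, min(rr, max(hi - lo, 1e-6)))
    times = []
    while t < hi:
        times.append(t)
        t += rr * (1.0 + rng.uniform(-rr_jitter_frac, rr_jitter_frac))
    return np.asarray(times)


def gen_ecg(
    rhythm_class: str,
    hr_bpm: float,
    duration_s: float,
    noise_sd: float,
    rng: np.random.Generator,
    params: GeneratorParams = DEFAULT_PARAMS,
    full_beats: bool = False,
):
    """Synthesize one ECG trace.

    Returns ``(ecg, qrs_times_s, beat_template, fiducial)``; for
    disorganized rhythms the QRS list is empty and the template is None.
    """
    fs = params.sample_rate_hz
    n = int(round(duration_s * fs))
    if rhythm_class == "disorganized":
        sos = sps.butter(4, [3.0, 8.0], btype="bandpass", fs=fs, output="sos")
        raw = rng.standard_normal(n + 600)
        vf = sps.sosfiltfilt(sos, raw)[300:300 + n]
        vf *= 0.35 / max(vf.std(), 1e-12)
        vf += noise_sd * rng.standard_normal(n)
        return vf, np.array([]), None, 0
    beat, fid = _make_beat(rng, fs)
    window = None
    if full_beats:
        margin = len(beat) / fs / 2.0
        window = (margin, duration_s - margin - params.mech_delay_s[1])
    times = _beat_times(rng, hr_bpm, duration_s, params.rr_jitter_frac, window)
    ecg = _add_train(np.zeros(n), beat, fid, times, fs)
    tgrid = np.arange(n) / fs
    ecg += params.baseline_wander_mv * np.sin(
        2 * np.pi * 0.3 * tgrid + rng.uniform(0, 2 * np.pi)
    )
    ecg += noise_sd * rng.standard_normal(n)
    return ecg, times, beat, fid


def gen_abp(
    hemo_class: str,
    qrs_times: np.ndarray,
    params: GeneratorParams,
    rng: np.random.Generator,
    duration_s: float | None = None,
):
    """Synthesize one ABP trace driven by the QRS train.

    Returns ``(abp, truth)`` where truth holds the realised sap / dap /
    pulse_pressure / map of the noise-free construction.
    """
    fs = params.sample_rate_hz
    duration_s = duration_s or params.duration_s
    n = int(round(duration_s * fs))
    if hemo_class == "PR":
        target_map = _clipped_normal(rng, params.map_pr_mmhg, lo=75.0, hi=250.0)
        pp = _clipped_normal(rng, (40.0, 10.0), lo=15.0, hi=60.0)
    elif hemo_class == "PEA":
        target_map = _clipped_normal(rng, params.map_pea_mmhg, lo=3.0, hi=45.0)
        pp = float(rng.uniform(2.0, 8.0))
    else:
        raise ConfigurationError(f"unknown hemodynamic class {hemo_class!r}")
    # per-beat pulse: fast systolic upstroke, exponential diastolic decay
    delay = rng.uniform(0.10, 0.20)
    kt = np.arange(int(0.7 * fs)) / fs
    kernel = (1.0 - np.exp(-kt / 0.03)) * np.exp(-kt / 0.22)
    kernel /= kernel.max()
    pulse = np.zeros(n)
    for tq in np.atleast_1d(qrs_times):
        i = int(round((tq + delay) * fs))
        s, e = max(0, i), min(n, i + len(kernel))
        if e <= s:
            continue
        # beats do not stack: systole resets the decay
        pulse[s:e] = np.maximum(pulse[s:e], kernel[: e - s])
    dias = target_map - pp * float(pulse.mean())
    abp = dias + pp * pulse
    truth = {
        "sap_mmhg": float(abp.max()),
        "dap_mmhg": float(abp.min()),
        "pulse_pressure_mmhg": float(abp.max() - abp.min()),
        "map_mmhg": float(abp.mean()),
        "abp_delay_s": float(delay),
    }
    abp = abp + params.abp_noise_sd_mmhg * rng.standard_normal(n)
    return abp, truth


def gen_acc(
    hemo_class: str,
    qrs_times: np.ndarray,
    compression_schedule: list[tuple[float, float]],
    params: GeneratorParams,
    rng: np.random.Generator,
    duration_s: float | None = None,
    beat: np.ndarray | None = None,
    fid: int | None = None,
    mech_delay_s: float | None = None,
    pulse_amp_ms2: float | None = None,
):
    """Synthesize one chest-acceleration trace.

    ``compression_schedule`` lists (start_s, end_s) compression episodes;
    everything else is pause.  During pauses the trace is background noise
    plus, iff the hemodynamic class is PR, a beat-shaped mechanical
    transient after each QRS at the electromechanical delay.

    Returns ``(acc, truth)`` with the realised delay and amplitudes.
    """
    fs = params.sample_rate_hz
    duration_s = duration_s or params.duration_s
    n = int(round(duration_s * fs))
    acc = params.acc_noise_sd_ms2 * rng.standard_normal(n)
    delay = (
        mech_delay_s
        if mech_delay_s is not None
        else float(rng.uniform(*params.mech_delay_s))
    )
    amp = (
        pulse_amp_ms2
        if pulse_amp_ms2 is not None
        else _clipped_normal(rng, params.pulse_osc_amp_ms2, lo=0.2)
    )
    if hemo_class == "PR" and len(np.atleast_1d(qrs_times)) > 0:
        if beat is None:
            beat, fid = _make_beat(rng, fs)
        jolt = beat / np.abs(beat).max()
        times = np.atleast_1d(qrs_times) + delay
        scales = amp * np.clip(
            1.0 + params.beat_amp_jitter_frac * rng.standard_normal(len(times)),
            0.2, None,
        )
        _add_train(acc, jolt, fid, times, fs, scales)
    cc_amps = []
    tgrid = np.arange(n) / fs
    for (start_s, end_s) in compression_schedule:
        a_cc = _clipped_normal(rng, params.cc_osc_amp_ms2, lo=15.0)
        cc_amps.append(a_cc)
        mask = (tgrid >= start_s) & (tgrid < end_s)
        phase = rng.uniform(0, 2 * np.pi)
        osc = np.sin(2 * np.pi * params.compression_rate_hz * tgrid[mask] + phase)
        osc += 0.3 * np.sin(4 * np.pi * params.compression_rate_hz * tgrid[mask] + phase)
        # brief ramp at episode edges
        m = int(np.count_nonzero(mask))
        ramp = np.minimum(1.0, np.minimum(np.arange(m), np.arange(m)[::-1]) / (0.15 * fs))
        acc[mask] += a_cc * osc * ramp
    truth = {
        "mech_delay_s": delay,
        "pulse_amp_ms2": amp if hemo_class == "PR" else 0.0,
        "cc_amps_ms2": cc_amps,
    }
    return acc, truth


def generate_segment(
    label: str,
    params: GeneratorParams = DEFAULT_PARAMS,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    segment_id: str = "synthetic",
    full_beats: bool = False,
    mech_delay_s: float | None = None,
    pulse_amp_ms2: float | None = None,
):
    """One labelled 3-s compression-free segment with ground truth.

    ``label`` is "PR", "PEA" or "disorganized".  Returns
    ``(Segment, truth_dict)``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    fs = params.sample_rate_hz
    if label == "PR":
        hr = _clipped_normal(rng, params.hr_pr_bpm, *params.hr_clip_bpm)
        rhythm = "organized"
    elif label == "PEA":
        hr = _clipped_normal(rng, params.hr_pea_bpm, *params.hr_clip_bpm)
        rhythm = "organized"
    elif label == "disorganized":
        hr = float("nan")
        rhythm = "disorganized"
    else:
        raise ConfigurationError(f"unknown label {label!r}")
    ecg, qrs_times, beat, fid = gen_ecg(
        rhythm, hr, params.duration_s, params.ecg_noise_sd_mv, rng, params,
        full_beats=full_beats,
    )
    hemo = label if label in ("PR", "PEA") else "PEA"
    abp, abp_truth = gen_abp(
        hemo if rhythm == "organized" else "PEA", qrs_times, params, rng
    )
    acc, acc_truth = gen_acc(
        hemo if rhythm == "organized" else "PEA",
        qrs_times, [], params, rng,
        beat=beat, fid=fid,
        mech_delay_s=mech_delay_s, pulse_amp_ms2=pulse_amp_ms2,
    )
    seg = Segment(
        segment_id=segment_id,
        source_record="synthetic",
        start_idx=0,
        sample_rate_hz=fs,
        ecg=ecg, abp=abp, acc=acc,
    )
    truth = {
        "segment_id": segment_id,
        "label": label,
        "rhythm": rhythm,
        "hr_bpm": hr,
        "qrs_times_s": qrs_times,
        **abp_truth,
        **acc_truth,
    }
    return seg, truth


def generate_dataset(
    n_pr: int,
    n_pea: int,
    params: GeneratorParams = DEFAULT_PARAMS,
    seed: int = 0,
    n_animals: int = 15,
    full_beats: bool = False,
):
    """Independent labelled segments with per-segment ground truth.

    Segments are attributed to synthetic "animals" so that animal-grouped
    train/test splits can be exercised.  Returns
    ``(list_of_segments, truth_frame)``; fully reproducible from
    (params, seed).
    """
    if n_pr < 0 or n_pea < 0:
        raise ConfigurationError("segment counts must be non-negative")
    rng = np.random.default_rng(seed)
    labels = ["PR"] * n_pr + ["PEA"] * n_pea
    segments: list[Segment] = []
    rows = []
    for k, label in enumerate(labels):
        sid = f"syn{k:04d}"
        seg, truth = generate_segment(
            label, params, rng=rng, segment_id=sid, full_beats=full_beats
        )
        truth = dict(truth)
        truth.pop("qrs_times_s")
        truth["animal_id"] = f"a{rng.integers(n_animals):02d}"
        segments.append(seg)
        rows.append(truth)
    return segments, pd.DataFrame(rows)


def assign_split(
    truth: pd.DataFrame,
    seed: int = 0,
    n_train: dict | None = None,
    by_animal: bool = False,
) -> pd.DataFrame:
    """Add a set_assignment column (training/testing) to a truth frame.

    With exact per-class training counts (``n_train={"PR": 32, "PEA": 74}``)
    rows are shuffled within class; with ``by_animal`` whole animals are
    assigned to one split (the study's grouping rule) approximating a
    half/half division.
    """
    rng = np.random.default_rng(seed)
    out = truth.copy()
    out["set_assignment"] = "testing"
    if by_animal:
        animals = sorted(out["animal_id"].unique())
        rng.shuffle(animals)
        train_animals = set(animals[: len(animals) // 2])
        out.loc[out["animal_id"].isin(train_animals), "set_assignment"] = "training"
        return out
    n_train = n_train or {}
    for label, k in n_train.items():
        idx = out.index[out["label"] == label].to_numpy()
        rng.shuffle(idx)
        out.loc[idx[:k], "set_assignment"] = "training"
    return out


def generate_recording(
    label: str,
    params: GeneratorParams = DEFAULT_PARAMS,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    n_pauses: int = 3,
    record_id: str = "synthetic_rec",
):
    """A CPR-like recording alternating compression episodes and pauses.

    Returns ``(Recording, truth)``; truth includes the ground-truth pause
    intervals (as :class:`PauseInterval`) and the compression schedule.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    fs = params.sample_rate_hz
    schedule = []  # compression episodes (start, end)
    pauses_s = []
    t = 0.0
    for _ in range(n_pauses):
        ep = rng.uniform(*params.compression_episode_s)
        schedule.append((t, t + ep))
        t += ep
        pause = rng.uniform(*params.pause_s)
        pauses_s.append((t, t + pause))
        t += pause
    ep = rng.uniform(*params.compression_episode_s)
    schedule.append((t, t + ep))
    t += ep
    duration = t
    if label == "PR":
        hr = _clipped_normal(rng, params.hr_pr_bpm, *params.hr_clip_bpm)
    else:
        hr = _clipped_normal(rng, params.hr_pea_bpm, *params.hr_clip_bpm)
    ecg, qrs_times, beat, fid = gen_ecg(
        "organized", hr, duration, params.ecg_noise_sd_mv, rng, params
    )
    abp, abp_truth = gen_abp(label, qrs_times, params, rng, duration_s=duration)
    acc, acc_truth = gen_acc(
        label, qrs_times, schedule, params, rng,
        duration_s=duration, beat=beat, fid=fid,
    )
    rec = Recording(
        record_id=record_id,
        sample_rate_hz=fs,
        ecg=ecg, abp=abp, acc=acc,
        metadata={"label": label},
    )
    truth = {
        "label": label,
        "hr_bpm": hr,
        "qrs_times_s": qrs_times,
        "compression_schedule_s": schedule,
        "pause_intervals": [
            PauseInterval(int(round(s * fs)), int(round(e * fs)), fs)
            for s, e in pauses_s
        ],
        **abp_truth,
        **acc_truth,
    }
    return rec, truth
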