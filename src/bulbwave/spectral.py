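"""Spectral quantification of LFP recordings.

The pipeline mirrors classical slice-electrophysiology practice: 20-s
segments taken every 5 min, a single Hamming-tapered periodogram per segment
(window-power corrected so the PSD integral equals the segment variance),
spectra restricted to 1-50 Hz, per-condition averaging of the last two
segments, trapezoidal band integration over theta (2-12 Hz), beta (13-35 Hz),
gamma (35-50 Hz) and the full 1-50 Hz range, normalization of integrated
power to the control condition (control = 100%), argmax peak frequency, and
per-segment time-courses of normalized full-band power.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .lfpsim import Recording

__all__ = [
    "SegmentSchedule",
    "Segment",
    "PowerSpectrum",
    "Band",
    "DEFAULT_BANDS",
    "FULL_BAND",
    "TimeCourse",
    "CohortResult",
    "extract_segments",
    "periodogram_hamming",
    "condition_spectrum",
    "band_power",
    "normalize_power",
    "peak_frequency",
    "power_time_course",
    "analyze_cohort",
]


@dataclass(frozen=True)
class SegmentSchedule:
    """Segment timing: 20-s windows every 5 min; last two per condition averaged."""

    segment_length_s: float = 20.0
    period_min: float = 5.0
    n_condition_segments_averaged: int = 2

    def __post_init__(self) -> None:
        if self.segment_length_s <= 0:
            raise ValueError("segment_length_s must be positive")
        if self.period_min * 60.0 < self.segment_length_s:
            raise ValueError("period must be at least one segment long")
        if self.n_condition_segments_averaged < 1:
            raise ValueError("n_condition_segments_averaged must be >= 1")


@dataclass
class Segment:
    start_s: float
    samples: np.ndarray
    condition: str | None  # None when the segment straddles an epoch boundary
    epoch_index: int | None

    @property
    def start_min(self) -> float:
        return self.start_s / 60.0


@dataclass
class PowerSpectrum:
    """One-sided PSD (µV²/Hz) on a strictly increasing frequency grid."""

    freqs: np.ndarray
    power: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.size != self.power.size:
            raise ValueError("freqs and power must have equal length")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")


@dataclass(frozen=True)
class Band:
    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"band {self.name}: lo must be below hi")


# theta/beta/gamma leave the 12-13 Hz gap of the printed definitions; 35 Hz
# sits at the beta/gamma edge and contributes half-weight to each under the
# trapezoidal integral, so bands never double count
DEFAULT_BANDS = (
    Band("theta", 2.0, 12.0),
    Band("beta", 13.0, 35.0),
    Band("gamma", 35.0, 50.0),
    Band("full", 1.0, 50.0),
)
FULL_BAND = DEFAULT_BANDS[3]


def extract_segments(recording: Recording, schedule: SegmentSchedule | None = None) -> list[Segment]:
    """Cut the recording into scheduled segments and assign them to conditions.

    Segments start at t = k * period (k = 0, 1, ...), each exactly
    ``segment_length_s`` long; a partial trailing segment is discarded.  A
    segment belongs to a condition only if it lies wholly inside that
    condition's epoch.
    """
    schedule = schedule or SegmentSchedule()
    fs = recording.sampling_rate
    seg_n = int(round(schedule.segment_length_s * fs))
    if recording.n_samples < seg_n:
        raise ValueError(
            f"recording ({recording.duration_s:.1f} s) shorter than one segment "
            f"({schedule.segment_length_s:.1f} s)"
        )
    period_n = int(round(schedule.period_min * 60.0 * fs))
    epochs = recording.timeline.epochs if recording.timeline is not None else []
    out: list[Segment] = []
    start = 0
    while start + seg_n <= recording.n_samples:
        t0 = start / fs
        t1 = t0 + schedule.segment_length_s
        condition = None
        epoch_index = None
        for i, e in enumerate(epochs):
            if t0 >= e.start_min * 60.0 - 1e-9 and t1 <= e.end_min * 60.0 + 1e-9:
                condition, epoch_index = e.label, i
                break
        out.append(Segment(t0, recording.samples[start : start + seg_n], condition, epoch_index))
        start += period_n
    return out


def periodogram_hamming(
    samples: np.ndarray,
    sampling_rate: float,
    f_min: float = 1.0,
    f_max: float = 50.0,
    provenance: dict | None = None,
) -> PowerSpectrum:
    """Single Hamming-tapered periodogram of a whole segment, in µV²/Hz.

    The taper is corrected by its mean square so the PSD integral over all
    frequencies equals the (detrended) segment variance; the returned
    spectrum is restricted to [f_min, f_max].  Frequency resolution is the
    reciprocal of the segment duration (0.05 Hz for 20-s segments).
    """
    x = np.asarray(samples, dtype=float)
    if f_max > sampling_rate / 2.0:
        raise ValueError(f"f_max ({f_max} Hz) above Nyquist ({sampling_rate / 2.0} Hz)")
    if x.size < 2 * f_max * (x.size / sampling_rate):
        raise ValueError("segment too short for the requested f_max")
    freqs, pxx = sp_signal.periodogram(
        x, fs=sampling_rate, window="hamming", detrend="constant", scaling="density"
    )
    mask = (freqs >= f_min - 1e-12) & (freqs <= f_max + 1e-12)
    return PowerSpectrum(freqs[mask], pxx[mask], dict(provenance or {}))


def _resolve_epoch(recording: Recording, condition: str, which: str | int) -> int:
    indices = [
        i for i, e in enumerate(recording.timeline.epochs) if e.label == condition
    ]
    if not indices:
        raise ValueError(f"condition {condition!r} not present in the recording timeline")
    if which == "first":
        return indices[0]
    if which == "last":
        return indices[-1]
    if int(which) in indices:
        return int(which)
    raise ValueError(f"epoch {which!r} is not a {condition!r} epoch")


def condition_spectrum(
    recording: Recording,
    condition: str,
    schedule: SegmentSchedule | None = None,
    f_min: float = 1.0,
    f_max: float = 50.0,
    epoch: str | int = "last",
) -> PowerSpectrum:
    """Bin-wise mean periodogram of the last n segments of a condition epoch.

    When the label occurs in several epochs, ``epoch`` selects which one
    ("first", "last", or an explicit epoch index).
    """
    schedule = schedule or SegmentSchedule()
    idx = _resolve_epoch(recording, condition, epoch)
    segs = [s for s in extract_segments(recording, schedule) if s.epoch_index == idx]
    n = schedule.n_condition_segments_averaged
    if len(segs) < n:
        raise ValueError(
            f"condition {condition!r} has only {len(segs)} whole segment(s); "
            f"{n} required"
        )
    segs = segs[-n:]
    spectra = [
        periodogram_hamming(s.samples, recording.sampling_rate, f_min, f_max) for s in segs
    ]
    power = np.mean([sp.power for sp in spectra], axis=0)
    prov = {
        "recording": recording.subject_meta.get("slice_id"),
        "condition": condition,
        "segment_start_s": [s.start_s for s in segs],
    }
    return PowerSpectrum(spectra[0].freqs, power, prov)


def band_power(spectrum: PowerSpectrum, band: Band) -> float:
    """Trapezoidal integral of the PSD over the band, in µV².

    Edges falling between grid points are linearly interpolated, so adjacent
    bands tile an interval exactly (their integrals add up to the integral
    over the union).
    """
    f, p = spectrum.freqs, spectrum.power
    if band.lo < f[0] - 1e-9 or band.hi > f[-1] + 1e-9:
        raise ValueError(
            f"band {band.name} [{band.lo}, {band.hi}] outside the spectrum range "
            f"[{f[0]:g}, {f[-1]:g}] Hz"
        )
    lo = max(band.lo, f[0])
    hi = min(band.hi, f[-1])
    inner = f[(f > lo) & (f < hi)]
    xs = np.concatenate(([lo], inner, [hi]))
    ps = np.interp(xs, f, p)
    return float(np.trapezoid(ps, xs))


def normalize_power(test_power: float, control_power: float) -> float:
    """Integrated power as percent of the control integral (control = 100%)."""
    if control_power <= 0:
        raise ValueError(f"control power must be positive, got {control_power}")
    return 100.0 * test_power / control_power


def peak_frequency(spectrum: PowerSpectrum, f_min: float = 1.0, f_max: float = 50.0) -> float:
    """Frequency of the maximal power bin in [f_min, f_max]; ties -> lowest.

    Returns NaN for an all-zero spectrum (undefined peak).
    """
    mask = (spectrum.freqs >= f_min - 1e-12) & (spectrum.freqs <= f_max + 1e-12)
    if not mask.any():
        raise ValueError("spectrum is empty in the requested range")
    p = spectrum.power[mask]
    if np.all(p == 0):
        return float("nan")
    return float(spectrum.freqs[mask][np.argmax(p)])


@dataclass
class TimeCourse:
    """Normalized full-band power per scheduled segment."""

    times_min: np.ndarray  # minutes (from drug onset or recording start)
    normalized_power: np.ndarray  # % of control
    conditions: list[str | None]
    time_origin: str = "onset"

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.normalized_power = np.asarray(self.normalized_power, dtype=float)
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")

    def at(self, time_min: float) -> float:
        """Normalized power of the segment starting at ``time_min`` (exact match)."""
        idx = np.nonzero(np.isclose(self.times_min, time_min))[0]
        if idx.size == 0:
            raise KeyError(f"no segment starts at {time_min} min")
        return float(self.normalized_power[idx[0]])


def power_time_course(
    recording: Recording,
    schedule: SegmentSchedule | None = None,
    reference_condition: str = "control",
    band: Band = FULL_BAND,
    time_origin: str = "onset",
) -> TimeCourse:
    """Per-segment band power normalized to the reference condition.

    The reference spectrum is the condition average (last n segments) of the
    *first* epoch carrying ``reference_condition``; every segment after that
    epoch contributes one time point.  ``time_origin`` selects whether times
    are minutes from drug onset (the end of the reference epoch) or from the
    start of the recording.
    """
    if time_origin not in ("onset", "start"):
        raise ValueError("time_origin must be 'onset' or 'start'")
    schedule = schedule or SegmentSchedule()
    ref_idx = _resolve_epoch(recording, reference_condition, "first")
    ref_spec = condition_spectrum(
        recording, reference_condition, schedule, f_min=band.lo, f_max=band.hi, epoch=ref_idx
    )
    ref_power = band_power(ref_spec, band)
    onset_min = recording.timeline.epochs[ref_idx].end_min
    times, values, conditions = [], [], []
    for seg in extract_segments(recording, schedule):
        if seg.start_min < onset_min - 1e-9:
            continue
        spec = periodogram_hamming(seg.samples, recording.sampling_rate, band.lo, band.hi)
        values.append(normalize_power(band_power(spec, band), ref_power))
        times.append(seg.start_min - (onset_min if time_origin == "onset" else 0.0))
        conditions.append(seg.condition)
    return TimeCourse(np.array(times), np.array(values), conditions, time_origin)


@dataclass
class CohortResult:
    """Per-slice band results and their cohort summary."""

    per_slice: pd.DataFrame  # recording, condition, band, absolute/normalized power, peak
    summary: pd.DataFrame  # condition, band, mean/sem of normalized power, n


def analyze_cohort(
    recordings: Sequence[Recording],
    schedule: SegmentSchedule | None = None,
    bands: Sequence[Band] = DEFAULT_BANDS,
) -> CohortResult:
    """Band powers, normalization to control, and peak frequency per slice.

    All recordings must share the same timeline structure.  The control
    reference is the condition average of the first control epoch; each other
    condition is measured from the last epoch carrying its label.  Returns
    one row per (recording, condition, band) plus a cohort mean ± SEM table
    (SEM is NaN for a single recording).
    """
    if not recordings:
        raise ValueError("no recordings given")
    schedule = schedule or SegmentSchedule()
    labels0 = [e.label for e in recordings[0].timeline.epochs]
    for r in recordings[1:]:
        if [e.label for e in r.timeline.epochs] != labels0:
            raise ValueError("recordings have heterogeneous timelines")

    rows = []
    conditions = list(dict.fromkeys(labels0))  # unique, in order
    for k, rec in enumerate(recordings):
        rec_id = rec.subject_meta.get("slice_id", f"rec{k + 1:02d}")
        ref_spec = condition_spectrum(rec, "control", schedule, epoch="first")
        for cond in conditions:
            which = "first" if cond == "control" else "last"
            spec = condition_spectrum(rec, cond, schedule, epoch=which)
            peak = peak_frequency(spec)
            for band in bands:
                absolute = band_power(spec, band)
                reference = band_power(ref_spec, band)
                rows.append(
                    {
                        "recording": rec_id,
                        "condition": cond,
                        "band": band.name,
                        "absolute_power_uv2": absolute,
                        "normalized_power_pct": normalize_power(absolute, reference),
                        "peak_frequency_hz": peak,
                    }
                )
    per_slice = pd.DataFrame(rows)

    def _sem(x: pd.Series) -> float:
        return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")

    summary = (
        per_slice.groupby(["condition", "band"], sort=False)
        .agg(
            mean_normalized_pct=("normalized_power_pct", "mean"),
            sem_normalized_pct=("normalized_power_pct", _sem),
            mean_peak_frequency_hz=("peak_frequency_hz", "mean"),
            n=("normalized_power_pct", "size"),
        )
        .reset_index()
    )
    return CohortResult(per_slice, summary)
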