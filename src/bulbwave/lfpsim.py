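"""Synthetic olfactory-bulb LFP recordings and behavioral datasets.

The generator emulates the statistical structure of granule-cell-layer field
recordings from olfactory bulb slices: broadband 1/f background activity with
a single spectral resonance near 13 Hz, band-limited by the acquisition
filters (0.5 Hz highpass, 1.5 kHz lowpass), whose instantaneous power is
multiplied by a condition-dependent gain envelope.  Amyloid-beta application
is modelled as a frequency-uniform, concentration- and age-dependent
attenuation of that power with delayed-exponential onset; washout relaxes the
gain back to unity and lidocaine drives it to near zero.  Every recording
carries its ground-truth envelope so that downstream spectral estimates can
be checked against the generative truth.

The behavioral generator draws hidden-food search latencies from a lognormal
family, right-censored at the 600-s test cap, with a group-by-week effect
that is absent from the visible-food, food-intake, and body-weight controls.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import fft as sp_fft

CONDITION_LABELS = (
    "control",
    "abeta_3nM",
    "abeta_10nM",
    "abeta_30nM",
    "inverse_abeta",
    "washout",
    "lidocaine",
)

__all__ = [
    "CONDITION_LABELS",
    "SimulationParams",
    "Epoch",
    "ConditionTimeline",
    "AttenuationModel",
    "GainEnvelope",
    "Recording",
    "BehaviorDesign",
    "CohortDesign",
    "build_gain_envelope",
    "simulate_recording",
    "simulate_cohort",
    "simulate_behavior_study",
    "preset_cohort_design",
    "PRESET_NAMES",
]


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class SimulationParams:
    """Spectral and acquisition parameters of the synthetic LFP.

    The generative one-sided PSD is ``S(f) ∝ f**-alpha + rho * L(f)`` on the
    pass band, where ``L`` is a second-order (Lorentzian) resonance of center
    ``peak_freq`` and full bandwidth ``resonance_bandwidth`` normalized to 1
    at its center, and ``rho = resonance_strength`` is the resonance height
    relative to the 1/f background at 1 Hz.  ``base_amplitude`` fixes the RMS
    of the trace (µV) at unit gain.  ``drift_log_sd``/``drift_tau_min``
    parameterize a slow Ornstein-Uhlenbeck log-power drift emulating
    slice-to-slice and within-slice stability noise.
    """

    sampling_rate: float = 3000.0  # Hz
    peak_freq: float = 13.3  # Hz
    resonance_bandwidth: float = 4.0  # Hz
    resonance_strength: float = 8.0  # dimensionless
    one_over_f_exponent: float = 1.0
    base_amplitude: float = 50.0  # µV RMS at unit gain
    highpass_cutoff: float = 0.5  # Hz
    lowpass_cutoff: float = 1500.0  # Hz
    drift_log_sd: float = 0.08
    drift_tau_min: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate < 2.0 * self.lowpass_cutoff:
            raise ValueError(
                "sampling_rate must be at least twice the lowpass cutoff "
                f"(got {self.sampling_rate} Hz vs lowpass {self.lowpass_cutoff} Hz)"
            )
        if not (1.0 < self.peak_freq < 50.0):
            raise ValueError(f"peak_freq must lie in (1, 50) Hz, got {self.peak_freq}")
        if self.base_amplitude <= 0:
            raise ValueError("base_amplitude must be positive")
        if self.resonance_bandwidth <= 0:
            raise ValueError("resonance_bandwidth must be positive")
        if self.drift_log_sd < 0 or self.drift_tau_min <= 0:
            raise ValueError("drift parameters must be nonnegative (sd) / positive (tau)")


@dataclass(frozen=True)
class Epoch:
    label: str
    start_min: float
    end_min: float

    def __post_init__(self) -> None:
        if self.label not in CONDITION_LABELS:
            raise ValueError(
                f"unknown condition label {self.label!r}; expected one of {CONDITION_LABELS}"
            )
        if not self.end_min > self.start_min:
            raise ValueError(f"epoch {self.label}: end_min must exceed start_min")


@dataclass(frozen=True)
class ConditionTimeline:
    """Ordered, contiguous condition epochs; the first must be control."""

    epochs: tuple[Epoch, ...]

    def __init__(self, epochs: Sequence[Epoch | tuple]) -> None:
        eps = tuple(e if isinstance(e, Epoch) else Epoch(*e) for e in epochs)
        if not eps:
            raise ValueError("timeline needs at least one epoch")
        if eps[0].label != "control":
            raise ValueError("timeline must start with a control epoch")
        for a, b in zip(eps, eps[1:]):
            if not np.isclose(a.end_min, b.start_min):
                raise ValueError(
                    f"epochs must be contiguous: {a.label} ends at {a.end_min} min "
                    f"but {b.label} starts at {b.start_min} min"
                )
        object.__setattr__(self, "epochs", eps)

    @property
    def start_min(self) -> float:
        return self.epochs[0].start_min

    @property
    def end_min(self) -> float:
        return self.epochs[-1].end_min

    @property
    def duration_min(self) -> float:
        return self.end_min - self.start_min

    def to_records(self) -> list[dict]:
        return [dataclasses.asdict(e) for e in self.epochs]

    @classmethod
    def from_records(cls, records: Sequence[Mapping]) -> "ConditionTimeline":
        return cls([Epoch(r["label"], r["start_min"], r["end_min"]) for r in records])


@dataclass(frozen=True)
class AttenuationModel:
    """Plateau power gains per condition (optionally per age) and kinetics.

    ``plateau_power_gain`` maps a condition label either to a gain or to a
    ``{age_weeks: gain}`` mapping.  Onset follows a dead time of
    ``onset_delay_min`` and then an exponential approach to the plateau with
    half-time ``onset_halftime_min``; washout relaxes toward 1 with
    ``washout_halftime_min``.
    """

    plateau_power_gain: Mapping[str, float | Mapping[int, float]]
    onset_halftime_min: float = 10.8
    washout_halftime_min: float = 15.0
    onset_delay_min: float = 0.0

    def __post_init__(self) -> None:
        if self.onset_halftime_min < 0 or self.washout_halftime_min < 0:
            raise ValueError("halftimes must be nonnegative")
        if self.onset_delay_min < 0:
            raise ValueError("onset_delay_min must be nonnegative")
        for label in self.plateau_power_gain:
            if label not in CONDITION_LABELS:
                raise ValueError(f"unknown condition label in model: {label!r}")
        inv = self.plateau_power_gain.get("inverse_abeta")
        for g in _iter_gains(inv):
            if g != 1.0:
                raise ValueError("inverse_abeta plateau gain must be 1.0")
        lid = self.plateau_power_gain.get("lidocaine")
        for g in _iter_gains(lid):
            if g > 0.05:
                raise ValueError("lidocaine plateau gain must be <= 0.05")
        for label, spec in self.plateau_power_gain.items():
            for g in _iter_gains(spec):
                if not (0.0 <= g <= 1.2):
                    raise ValueError(f"plateau gain for {label} out of [0, 1.2]: {g}")

    def plateau(self, label: str, age_weeks: int | None = None) -> float:
        if label == "control":
            return 1.0
        if label not in self.plateau_power_gain:
            if label == "washout":
                return 1.0
            raise KeyError(f"no plateau gain for condition {label!r}")
        spec = self.plateau_power_gain[label]
        if isinstance(spec, Mapping):
            if age_weeks not in spec:
                raise KeyError(f"no plateau gain for {label!r} at age {age_weeks} weeks")
            return float(spec[age_weeks])
        return float(spec)


def _iter_gains(spec):
    if spec is None:
        return
    if isinstance(spec, Mapping):
        yield from (float(v) for v in spec.values())
    else:
        yield float(spec)


# ---------------------------------------------------------------------------
# gain envelope


@dataclass(frozen=True)
class _Piece:
    start_min: float
    end_min: float
    start_gain: float
    plateau: float
    halftime_min: float
    delay_min: float

    def value(self, t_min: np.ndarray) -> np.ndarray:
        t = np.asarray(t_min, dtype=float)
        if self.start_gain == self.plateau:
            return np.full(t.shape, self.plateau)
        out = np.full(t.shape, self.start_gain)
        t0 = self.start_min + self.delay_min
        active = t >= t0
        if self.halftime_min < 1e-9:  # effectively instantaneous
            out[active] = self.plateau
        else:
            out[active] = self.plateau + (self.start_gain - self.plateau) * np.exp2(
                -(t[active] - t0) / self.halftime_min
            )
        return out

    @property
    def end_gain(self) -> float:
        return float(self.value(np.array([self.end_min]))[0])


@dataclass(frozen=True)
class GainEnvelope:
    """Piecewise delayed-exponential power gain as a function of time (min)."""

    pieces: tuple[_Piece, ...]

    @property
    def start_min(self) -> float:
        return self.pieces[0].start_min

    @property
    def end_min(self) -> float:
        return self.pieces[-1].end_min

    def __call__(self, t_min) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t_min, dtype=float))
        out = np.empty_like(t)
        edges = [p.start_min for p in self.pieces] + [self.pieces[-1].end_min]
        idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(self.pieces) - 1)
        for i, piece in enumerate(self.pieces):
            m = idx == i
            if m.any():
                out[m] = piece.value(t[m])
        return out if np.ndim(t_min) else float(out[0])

    def to_records(self) -> list[dict]:
        return [dataclasses.asdict(p) for p in self.pieces]

    @classmethod
    def from_records(cls, records: Sequence[Mapping]) -> "GainEnvelope":
        return cls(tuple(_Piece(**{k: float(v) for k, v in r.items()}) for r in records))


def constant_envelope(gain: float, start_min: float, end_min: float) -> GainEnvelope:
    """A trivially flat envelope (useful for null and scaling experiments)."""
    return GainEnvelope((_Piece(start_min, end_min, gain, gain, 0.0, 0.0),))


def build_gain_envelope(
    timeline: ConditionTimeline,
    model: AttenuationModel,
    age_weeks: int | None = None,
) -> GainEnvelope:
    """Realize a timeline's ground-truth power-gain envelope.

    Gain is exactly 1 throughout an initial control epoch, decays with the
    model's delayed-exponential kinetics toward each drug epoch's plateau,
    relaxes toward 1 during washout, and is continuous at epoch boundaries.
    """
    pieces: list[_Piece] = []
    entry = 1.0
    for epoch in timeline.epochs:
        if epoch.label == "control" and np.isclose(entry, 1.0):
            piece = _Piece(epoch.start_min, epoch.end_min, 1.0, 1.0, 0.0, 0.0)
        elif epoch.label in ("washout", "control"):
            piece = _Piece(
                epoch.start_min, epoch.end_min, entry,
                model.plateau(epoch.label, age_weeks),
                model.washout_halftime_min, 0.0,
            )
        else:
            piece = _Piece(
                epoch.start_min, epoch.end_min, entry,
                model.plateau(epoch.label, age_weeks),
                model.onset_halftime_min, model.onset_delay_min,
            )
        pieces.append(piece)
        entry = piece.end_gain
    return GainEnvelope(tuple(pieces))


# ---------------------------------------------------------------------------
# recordings


@dataclass
class Recording:
    """A single-channel LFP trace (µV) with its experiment metadata."""

    samples: np.ndarray
    sampling_rate: float
    timeline: ConditionTimeline
    subject_meta: dict = field(default_factory=dict)
    ground_truth: GainEnvelope | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if np.isnan(self.samples).any():
            raise ValueError("recording contains NaN samples")
        if self.timeline is not None:
            if self.duration_min + 1e-9 < self.timeline.duration_min:
                raise ValueError(
                    f"recording duration {self.duration_min:.3f} min does not cover "
                    f"its timeline ({self.timeline.duration_min:.3f} min)"
                )

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def duration_min(self) -> float:
        return self.duration_s / 60.0


def _generative_psd_shape(freqs: np.ndarray, params: SimulationParams) -> np.ndarray:
    """Unnormalized one-sided PSD shape on a frequency grid (µV²/Hz up to scale)."""
    f = np.asarray(freqs, dtype=float)
    shape = np.zeros_like(f)
    band = (f >= params.highpass_cutoff) & (f <= params.lowpass_cutoff)
    fb = f[band]
    background = fb ** (-params.one_over_f_exponent)
    f0 = params.peak_freq
    q = f0 / params.resonance_bandwidth
    x = fb / f0
    # second-order resonator magnitude, normalized to 1 at f0
    lorentz = 1.0 / (q * q * ((1.0 - x * x) ** 2 + (x / q) ** 2))
    shape[band] = background + params.resonance_strength * lorentz
    return shape


def _ou_log_drift(rng: np.random.Generator, duration_s: float, params: SimulationParams) -> tuple[np.ndarray, np.ndarray]:
    """Slow OU log-power drift sampled on a 1-s grid (stationary start)."""
    n = int(np.ceil(duration_s)) + 1
    t = np.arange(n, dtype=float)
    if params.drift_log_sd == 0.0:
        return t, np.zeros(n)
    phi = np.exp(-1.0 / (params.drift_tau_min * 60.0))
    innov_sd = params.drift_log_sd * np.sqrt(1.0 - phi * phi)
    eps = rng.standard_normal(n)
    drift = np.empty(n)
    drift[0] = params.drift_log_sd * eps[0]
    for i in range(1, n):
        drift[i] = phi * drift[i - 1] + innov_sd * eps[i]
    return t, drift


def simulate_recording(
    params: SimulationParams,
    envelope: GainEnvelope,
    duration_min: float,
    timeline: ConditionTimeline | None = None,
    subject_meta: Mapping | None = None,
) -> Recording:
    """Synthesize one seeded LFP recording under a power-gain envelope.

    The stationary trace is built in the frequency domain (white Gaussian
    noise shaped to the generative PSD, exact on average), then scaled by
    ``sqrt(gain(t) * drift(t))`` so instantaneous power follows the envelope
    times the slow stability drift.  Identical parameters and seed give a
    bit-identical trace.
    """
    if duration_min + 1e-9 < envelope.end_min - envelope.start_min:
        raise ValueError(
            f"duration ({duration_min} min) shorter than the envelope/timeline "
            f"({envelope.end_min - envelope.start_min} min)"
        )
    if timeline is None:
        timeline = ConditionTimeline([Epoch("control", 0.0, duration_min)])
    fs = params.sampling_rate
    n = int(round(duration_min * 60.0 * fs))
    rng = np.random.default_rng(params.seed)

    nfft = sp_fft.next_fast_len(n, real=True)
    white = rng.standard_normal(nfft)
    freqs = sp_fft.rfftfreq(nfft, 1.0 / fs)
    shape = _generative_psd_shape(freqs, params)
    # scale so that total variance at unit gain equals base_amplitude**2
    total = np.trapezoid(shape, freqs)
    psd = shape * (params.base_amplitude**2 / total)
    transfer = np.sqrt(psd * fs / 2.0)
    x = sp_fft.irfft(sp_fft.rfft(white) * transfer, nfft)[:n]

    t_s = np.arange(n) / fs
    gain = envelope(envelope.start_min + t_s / 60.0)
    drift_t, drift = _ou_log_drift(rng, n / fs, params)
    power_factor = gain * np.exp(np.interp(t_s, drift_t, drift))
    x *= np.sqrt(power_factor)

    meta = dict(subject_meta or {})
    meta.setdefault("seed", params.seed)
    return Recording(x, fs, timeline, meta, ground_truth=envelope)


@dataclass(frozen=True)
class CohortDesign:
    """One age group's slice-experiment design."""

    n_slices: int
    params: SimulationParams
    timeline: ConditionTimeline
    model: AttenuationModel
    age_weeks: int = 8
    duration_min: float | None = None  # defaults to timeline duration
    species: str = "mouse"

    def __post_init__(self) -> None:
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")


def simulate_cohort(designs: Sequence[CohortDesign], seed: int) -> list[Recording]:
    """Simulate a cohort of slices with per-slice seeds derived from ``seed``.

    Per-slice seeds come from a counter-based derivation
    (``numpy.random.SeedSequence(seed)``), so the same master seed always
    reproduces the cohort bit-identically.
    """
    if not designs:
        raise ValueError("empty cohort design")
    total = sum(d.n_slices for d in designs)
    child_seeds = np.random.SeedSequence(seed).generate_state(total, dtype=np.uint32) % np.uint32(2**31)
    out: list[Recording] = []
    k = 0
    for d in designs:
        envelope = build_gain_envelope(d.timeline, d.model, d.age_weeks)
        duration = d.duration_min if d.duration_min is not None else d.timeline.duration_min
        for i in range(d.n_slices):
            p = dataclasses.replace(d.params, seed=int(child_seeds[k]))
            meta = {
                "species": d.species,
                "age_weeks": d.age_weeks,
                "slice_id": f"age{d.age_weeks}w_s{i + 1:02d}",
            }
            out.append(simulate_recording(p, envelope, duration, d.timeline, meta))
            k += 1
    return out


# ---------------------------------------------------------------------------
# presets mirroring the study designs

_STANDARD_CONTROL_MIN = 20.0

# plateau power gains per condition and age (fractions of control power)
_AGE_PLATEAUS = {
    3: {"abeta_3nM": 0.967, "abeta_10nM": 0.804, "abeta_30nM": 0.532},
    6: {"abeta_3nM": 0.932, "abeta_10nM": 0.542, "abeta_30nM": 0.441},
    8: {"abeta_3nM": 0.652, "abeta_10nM": 0.546, "abeta_30nM": 0.468},
}

# onset kinetics fitted to the 30 nM time-course (75.7% at 15 min, 58.8% at
# 25 min, plateau 40.1%): dead time 6.9 min then exponential halftime 10.8 min
_ONSET_HALFTIME_MIN = 10.8
_ONSET_DELAY_MIN = 6.9
_WASHOUT_HALFTIME_MIN = 15.0

PRESET_NAMES = ("age3", "age6", "age8", "stability", "inverse", "washout", "lidocaine")


def preset_cohort_design(name: str, params: SimulationParams | None = None) -> CohortDesign:
    """Build one of the named slice-experiment designs.

    ``age3``/``age6``/``age8``: 20-min control then sequential 1-h epochs of
    3, 10, and 30 nM amyloid-beta (n=7).  ``stability``: 181 min of
    uninterrupted control recording (n=7).  ``inverse``: 1 h of the reversed
    peptide, plateau gain 1 (n=6).  ``washout``: 1 h of 30 nM followed by 80
    min of washout (n=7).  ``lidocaine``: near-total suppression (n=7).
    """
    p = params or SimulationParams()
    c = _STANDARD_CONTROL_MIN
    if name in ("age3", "age6", "age8"):
        age = int(name[3:])
        timeline = ConditionTimeline(
            [
                ("control", 0.0, c),
                ("abeta_3nM", c, c + 60.0),
                ("abeta_10nM", c + 60.0, c + 120.0),
                ("abeta_30nM", c + 120.0, c + 180.0),
            ]
        )
        model = AttenuationModel(
            _AGE_PLATEAUS[age], _ONSET_HALFTIME_MIN, _WASHOUT_HALFTIME_MIN, _ONSET_DELAY_MIN
        )
        return CohortDesign(7, p, timeline, model, age_weeks=age)
    if name == "stability":
        # 181 min so that a 20-s segment starting exactly at minute 180 exists
        timeline = ConditionTimeline([("control", 0.0, c), ("control", c, 181.0)])
        return CohortDesign(7, p, timeline, AttenuationModel({}), age_weeks=8)
    if name == "inverse":
        timeline = ConditionTimeline([("control", 0.0, c), ("inverse_abeta", c, c + 60.0)])
        model = AttenuationModel({"inverse_abeta": 1.0})
        return CohortDesign(6, p, timeline, model, age_weeks=8)
    if name == "washout":
        timeline = ConditionTimeline(
            [("control", 0.0, c), ("abeta_30nM", c, c + 60.0), ("washout", c + 60.0, c + 140.0)]
        )
        model = AttenuationModel(
            {"abeta_30nM": 0.401}, _ONSET_HALFTIME_MIN, _WASHOUT_HALFTIME_MIN, _ONSET_DELAY_MIN
        )
        return CohortDesign(7, p, timeline, model, age_weeks=8)
    if name == "lidocaine":
        timeline = ConditionTimeline([("control", 0.0, c), ("lidocaine", c, c + 30.0)])
        model = AttenuationModel({"lidocaine": 0.02}, 3.0, _WASHOUT_HALFTIME_MIN, 0.0)
        return CohortDesign(7, p, timeline, model, age_weeks=8)
    raise ValueError(f"unknown preset {name!r}; expected one of {PRESET_NAMES}")


# ---------------------------------------------------------------------------
# behavioral study


def _default_latency_location() -> dict:
    # log-seconds medians: vehicle stable ~120 s; treated animals lose the
    # ability to find the hidden food from week 2 (median beyond the cap)
    return {
        ("vehicle", 1): np.log(120.0),
        ("vehicle", 2): np.log(120.0),
        ("vehicle", 3): np.log(120.0),
        ("vehicle", 4): np.log(120.0),
        ("abeta", 1): np.log(150.0),
        ("abeta", 2): np.log(650.0),
        ("abeta", 3): np.log(800.0),
        ("abeta", 4): np.log(1000.0),
    }


@dataclass(frozen=True)
class BehaviorDesign:
    """Design of the hidden-food study and its motivation/motor controls."""

    n_per_group: int = 9
    groups: tuple[str, str] = ("vehicle", "abeta")
    weeks: tuple[int, ...] = (1, 2, 3, 4)
    latency_location: Mapping[tuple[str, int], float] = field(
        default_factory=_default_latency_location
    )
    latency_scale: float = 0.9  # log-seconds sd
    animal_sd: float = 0.3  # per-animal log intercept sd (pairs weeks)
    cap_s: float = 600.0
    visible_location: float = np.log(25.0)  # log-seconds, no group/week effect
    visible_scale: float = 0.5
    intake_means: Mapping[int, float] = field(default_factory=lambda: {30: 8.0, 120: 15.0})
    intake_sd: float = 2.0
    weight_gain_slope: float = 2.0  # % of baseline per week
    weight_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.latency_scale <= 0 or self.visible_scale <= 0:
            raise ValueError("latency scales must be positive")
        for key, loc in self.latency_location.items():
            if not np.isfinite(loc):
                raise ValueError(f"non-finite latency location for {key}")


@dataclass
class BehaviorStudy:
    """Tidy tables produced by :func:`simulate_behavior_study`."""

    latency: pd.DataFrame  # animal_id, group, week, task, feeding, latency_s, censored
    intake: pd.DataFrame  # animal_id, group, window_min, grams
    weight: pd.DataFrame  # animal_id, group, week, pct_of_baseline


def _censor(raw: np.ndarray, cap: float) -> tuple[np.ndarray, np.ndarray]:
    censored = raw >= cap
    return np.where(censored, cap, raw), censored


def simulate_behavior_study(design: BehaviorDesign) -> BehaviorStudy:
    """Simulate latency, intake, and weight tables under the stated design.

    Hidden-task latencies are lognormal with the design's per-(group, week)
    log-location plus a per-animal intercept, right-censored at ``cap_s``.
    Visible-task latencies, food intake, and weight gain carry no group
    effect.  Seeded and reproducible.
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    # main cohort: hidden task, fed, followed over the four weeks
    for group in design.groups:
        intercepts = rng.normal(0.0, design.animal_sd, design.n_per_group)
        for i in range(design.n_per_group):
            aid = f"{group[0]}{i + 1:02d}"
            for week in design.weeks:
                loc = design.latency_location[(group, week)] + intercepts[i]
                raw = float(np.exp(rng.normal(loc, design.latency_scale)))
                lat, cen = _censor(np.array([raw]), design.cap_s)
                rows.append(
                    ("main", aid, group, week, "hidden", "fed", float(lat[0]), bool(cen[0]))
                )
    # control cohort: hidden and visible tasks, food-deprived (week 3) and fed
    # (week 4) strata
    for group in design.groups:
        intercepts = rng.normal(0.0, design.animal_sd, design.n_per_group)
        for i in range(design.n_per_group):
            aid = f"c{group[0]}{i + 1:02d}"
            for feeding, week in (("deprived", 3), ("fed", 4)):
                loc = design.latency_location[(group, week)] + intercepts[i]
                raw = float(np.exp(rng.normal(loc, design.latency_scale)))
                lat, cen = _censor(np.array([raw]), design.cap_s)
                rows.append(
                    ("control", aid, group, week, "hidden", feeding, float(lat[0]), bool(cen[0]))
                )
                vis = float(np.exp(rng.normal(design.visible_location, design.visible_scale)))
                lat, cen = _censor(np.array([vis]), design.cap_s)
                rows.append(
                    ("control", aid, group, week, "visible", feeding, float(lat[0]), bool(cen[0]))
                )
    latency = pd.DataFrame(
        rows,
        columns=[
            "cohort", "animal_id", "group", "week", "task", "feeding", "latency_s", "censored",
        ],
    )

    intake_rows = []
    for group in design.groups:
        for i in range(design.n_per_group):
            aid = f"c{group[0]}{i + 1:02d}"
            for window, mean in design.intake_means.items():
                grams = max(0.0, float(rng.normal(mean, design.intake_sd)))
                intake_rows.append((aid, group, int(window), grams))
    intake = pd.DataFrame(intake_rows, columns=["animal_id", "group", "window_min", "grams"])

    weight_rows = []
    for group in design.groups:
        for i in range(design.n_per_group):
            aid = f"{group[0]}{i + 1:02d}"
            for week in design.weeks:
                pct = 100.0 + design.weight_gain_slope * week + float(
                    rng.normal(0.0, design.weight_sd)
                )
                weight_rows.append((aid, group, week, pct))
    weight = pd.DataFrame(weight_rows, columns=["animal_id", "group", "week", "pct_of_baseline"])

    return BehaviorStudy(latency, intake, weight)
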