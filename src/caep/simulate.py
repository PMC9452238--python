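"""Synthetic neonatal CAEP epoch generator.

The simulator emulates single-channel neonatal recordings: each epoch is a
positive P1 deflection (a smooth Gaussian bump at 200-300 ms post-stimulus)
superimposed on EEG-like noise, with occasional high-amplitude movement
artifacts.  P1 latency increases as stimulus intensity decreases; amplitude
grows above a per-subject true threshold and vanishes below it.  Population
defaults come from published neonatal normative rows (`caep.norms`).

Randomness is hierarchical: one integer seed drives a
``numpy.random.SeedSequence`` that spawns per-subject and per-epoch-set
streams, so any subset of a cohort is reproducible in isolation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

from . import norms
from .containers import FREQUENCIES_HZ, EpochSet, StimulusConfig
from .exceptions import DomainError

__all__ = [
    "SubjectModel",
    "PopulationModel",
    "p1_latency",
    "p1_amplitude",
    "p1_template",
    "simulate_epoch_set",
    "simulate_cohort",
]

#: Default epoch window (ms relative to stimulus onset) and sampling rate.
DEFAULT_WINDOW_MS = (-100.0, 600.0)
DEFAULT_FS = 1000.0

#: Gaussian P1 bump half-width at half maximum (ms).
DEFAULT_HALF_WIDTH_MS = 60.0

#: Band (Hz) to which simulated EEG noise is limited (the analysis passband).
DEFAULT_NOISE_BAND = (0.2, 30.0)

#: Artifact pulse defaults: amplitude (uV) and duration (ms).
ARTIFACT_AMPLITUDE_UV = 200.0
ARTIFACT_DURATION_MS = 100.0


@dataclass
class SubjectModel:
    """Ground-truth parameters of one simulated subject.

    Per-frequency maps give the true electrophysiological threshold (dB HL),
    the P1 amplitude anchor at 80 dB HL (uV) and the P1 latency at 80 dB HL
    (ms).  ``latency_slope`` (ms/dB, >= 0) controls how much latency grows as
    intensity falls; ``amplitude_growth`` is the exponent of the
    suprathreshold growth law (1 = linear in dB between threshold and the
    80 dB anchor).  ``noise_rms`` is the per-sample RMS of the EEG-like noise
    in each epoch and ``artifact_rate`` the per-epoch artifact probability.
    """

    subject_id: str
    true_threshold_dbhl: Mapping[float, float]
    p1_amplitude_80: Mapping[float, float]
    p1_latency_80: Mapping[float, float]
    latency_slope: float = 1.0
    amplitude_growth: float = 1.0
    noise_rms: float = 25.0
    artifact_rate: float = 0.02

    def __post_init__(self) -> None:
        for f, t in self.true_threshold_dbhl.items():
            if not 0 <= t <= 80:
                raise DomainError(f"threshold at {f} Hz outside [0, 80]: {t}")
        for f, a in self.p1_amplitude_80.items():
            if a <= 0:
                raise DomainError(f"P1 amplitude at {f} Hz must be positive: {a}")
        for f, l in self.p1_latency_80.items():
            if not 100 <= l <= 500:
                raise DomainError(f"P1 latency at {f} Hz outside [100, 500]: {l}")
        if self.latency_slope < 0:
            raise DomainError(f"latency_slope must be >= 0, got {self.latency_slope}")
        if self.noise_rms <= 0:
            raise DomainError(f"noise_rms must be positive, got {self.noise_rms}")
        if not 0 <= self.artifact_rate < 1:
            raise DomainError(f"artifact_rate must lie in [0, 1): {self.artifact_rate}")


def p1_latency(intensity_dbhl: float, subject: SubjectModel, frequency_hz: float) -> float:
    """P1 latency (ms) of `subject` at a given intensity and frequency.

    Latency rises linearly as intensity falls below the 80 dB HL anchor:
    ``lat80 + latency_slope * (80 - intensity)``.
    """
    if not 0 <= intensity_dbhl <= 80:
        raise DomainError(f"intensity outside [0, 80] dB HL: {intensity_dbhl}")
    lat80 = subject.p1_latency_80[frequency_hz]
    return lat80 + subject.latency_slope * (80.0 - intensity_dbhl)


def p1_amplitude(intensity_dbhl: float, subject: SubjectModel, frequency_hz: float) -> float:
    """P1 amplitude (uV) of `subject` at a given intensity and frequency.

    Zero below the subject's true threshold; above it the amplitude grows
    with intensity and reaches the subject's 80 dB HL anchor exactly at
    80 dB HL (default: linearly in dB above threshold).
    """
    if not 0 <= intensity_dbhl <= 80:
        raise DomainError(f"intensity outside [0, 80] dB HL: {intensity_dbhl}")
    thr = subject.true_threshold_dbhl[frequency_hz]
    a80 = subject.p1_amplitude_80[frequency_hz]
    if intensity_dbhl < thr:
        return 0.0
    if thr >= 80.0:
        # Degenerate anchor: threshold at the top of the range.
        return a80 if intensity_dbhl >= 80.0 else 0.0
    frac = (intensity_dbhl - thr) / (80.0 - thr)
    return a80 * frac**subject.amplitude_growth


def p1_template(
    times_ms: np.ndarray,
    latency_ms: float,
    amplitude_uv: float,
    half_width_ms: float = DEFAULT_HALF_WIDTH_MS,
) -> np.ndarray:
    """Noise-free P1 waveform: a positive Gaussian bump.

    ``half_width_ms`` is the half width at half maximum; the Gaussian sigma
    is ``half_width / sqrt(2 ln 2)``.
    """
    sigma = half_width_ms / math.sqrt(2.0 * math.log(2.0))
    t = np.asarray(times_ms, dtype=float)
    return amplitude_uv * np.exp(-0.5 * ((t - latency_ms) / sigma) ** 2)


@lru_cache(maxsize=8)
def _filtfilt_rms_gain(n_samples: int, fs: float, low_hz: float, high_hz: float) -> float:
    """RMS gain of zero-phase band-pass filtering applied to white noise.

    Computed exactly from the finite-length filtering operator so that
    band-limited noise can be rescaled to a prescribed per-sample RMS.
    """
    sos = signal.butter(4, (low_hz, high_hz), btype="band", fs=fs, output="sos")
    op = signal.sosfiltfilt(sos, np.eye(n_samples), axis=-1)
    return float(np.sqrt((op**2).sum() / n_samples))


def _eeg_noise(
    rng: np.random.Generator,
    n_epochs: int,
    n_samples: int,
    fs: float,
    rms_uv: float,
    band_hz: tuple[float, float] | None,
    color: str,
) -> np.ndarray:
    """Zero-mean noise with per-sample RMS ``rms_uv``, optionally band-limited."""
    white = rng.normal(0.0, 1.0, size=(n_epochs, n_samples))
    if color == "pink":
        # 1/f shaping in the frequency domain before band-limiting.
        spec = np.fft.rfft(white, axis=1)
        freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
        shape = np.ones_like(freqs)
        nonzero = freqs > 0
        shape[nonzero] = 1.0 / np.sqrt(freqs[nonzero])
        shape[0] = 0.0
        white = np.fft.irfft(spec * shape, n=n_samples, axis=1)
        white /= white.std()
    elif color != "white":
        raise DomainError(f"unknown noise color {color!r}")
    if band_hz is None:
        noise = white
    else:
        sos = signal.butter(4, band_hz, btype="band", fs=fs, output="sos")
        noise = signal.sosfiltfilt(sos, white, axis=1)
        if color == "white":
            noise /= _filtfilt_rms_gain(n_samples, fs, *band_hz)
        else:
            noise /= noise.std()
    return rms_uv * noise


def simulate_epoch_set(
    subject: SubjectModel,
    stimulus: StimulusConfig,
    n_epochs: int,
    seed: int | np.random.SeedSequence | np.random.Generator,
    *,
    fs: float = DEFAULT_FS,
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
    half_width_ms: float = DEFAULT_HALF_WIDTH_MS,
    noise_band_hz: tuple[float, float] | None = DEFAULT_NOISE_BAND,
    noise_color: str = "white",
    artifact_amplitude_uv: float = ARTIFACT_AMPLITUDE_UV,
    artifact_duration_ms: float = ARTIFACT_DURATION_MS,
) -> EpochSet:
    """Simulate one recording run: `n_epochs` stimulus-locked epochs.

    Each epoch is the subject's P1 template at the stimulus intensity plus
    band-limited noise; with probability ``subject.artifact_rate`` an epoch
    additionally receives a +/-200 uV square pulse emulating a movement
    artifact.  Identical seeds produce bit-identical output.
    """
    if n_epochs < 1:
        raise DomainError(f"n_epochs must be >= 1, got {n_epochs}")
    rng = np.random.default_rng(seed)
    t0, t1 = window_ms
    n_samples = int(round((t1 - t0) * fs / 1000.0))
    times = t0 + np.arange(n_samples) * 1000.0 / fs

    lat = p1_latency(stimulus.intensity_dbhl, subject, stimulus.frequency_hz)
    amp = p1_amplitude(stimulus.intensity_dbhl, subject, stimulus.frequency_hz)
    template = p1_template(times, lat, amp, half_width_ms)

    data = template + _eeg_noise(
        rng, n_epochs, n_samples, fs, subject.noise_rms, noise_band_hz, noise_color
    )

    # Movement artifacts: random-sign square pulses at random onsets.
    hit = rng.random(n_epochs) < subject.artifact_rate
    pulse_len = max(1, int(round(artifact_duration_ms * fs / 1000.0)))
    for i in np.flatnonzero(hit):
        onset = rng.integers(0, max(1, n_samples - pulse_len))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        data[i, onset : onset + pulse_len] += sign * artifact_amplitude_uv

    return EpochSet(
        data=data,
        fs=fs,
        t_start_ms=t0,
        stimulus=stimulus,
        subject_id=subject.subject_id,
    )


@dataclass
class PopulationModel:
    """Per-frequency parameter distributions for cohort simulation.

    Thresholds are drawn from a normal truncated to [0, 80] dB HL and rounded
    to the 5 dB grid; amplitude anchors from a positive truncated normal;
    latency anchors from a normal clipped to [100, 500] ms.  Defaults encode
    the published neonatal normative rows.
    """

    threshold_mean: Mapping[float, float] = field(
        default_factory=lambda: {f: norms.CAEP_THRESHOLD[f]["mean"] for f in FREQUENCIES_HZ}
    )
    threshold_sd: Mapping[float, float] = field(
        default_factory=lambda: {f: norms.CAEP_THRESHOLD[f]["sd"] for f in FREQUENCIES_HZ}
    )
    amplitude_mean: Mapping[float, float] = field(
        default_factory=lambda: {f: norms.P1_AMPLITUDE_80[f]["mean"] for f in FREQUENCIES_HZ}
    )
    amplitude_sd: Mapping[float, float] = field(
        default_factory=lambda: {f: norms.P1_AMPLITUDE_80[f]["sd"] for f in FREQUENCIES_HZ}
    )
    latency_mean: Mapping[float, float] = field(
        default_factory=lambda: {f: norms.P1_LATENCY_80[f]["mean"] for f in FREQUENCIES_HZ}
    )
    latency_sd: Mapping[float, float] = field(
        default_factory=lambda: {f: norms.P1_LATENCY_80[f]["sd"] for f in FREQUENCIES_HZ}
    )
    latency_slope: float = 1.0
    amplitude_growth: float = 1.0
    noise_rms: float = 25.0
    artifact_rate: float = 0.02

    def __post_init__(self) -> None:
        for name in ("threshold_sd", "amplitude_sd", "latency_sd"):
            for f, sd in getattr(self, name).items():
                if sd < 0:
                    raise DomainError(f"{name}[{f}] must be >= 0, got {sd}")

    @property
    def frequencies(self) -> tuple[float, ...]:
        return tuple(self.threshold_mean)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    """Draw from N(mean, sd) truncated to [lo, hi] by rejection."""
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    # Pathological parameters: fall back to clipping.
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def simulate_cohort(
    n_subjects: int,
    population: PopulationModel | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> list[SubjectModel]:
    """Draw `n_subjects` subjects from the population distributions."""
    if n_subjects < 1:
        raise DomainError(f"n_subjects must be >= 1, got {n_subjects}")
    pop = population if population is not None else PopulationModel()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    subjects = []
    for i, child in enumerate(ss.spawn(n_subjects)):
        rng = np.random.default_rng(child)
        thr, amp, lat = {}, {}, {}
        for f in pop.frequencies:
            t = _truncated_normal(rng, pop.threshold_mean[f], pop.threshold_sd[f], 0.0, 80.0)
            thr[f] = float(5.0 * round(t / 5.0))
            amp[f] = _truncated_normal(rng, pop.amplitude_mean[f], pop.amplitude_sd[f], 1e-6, np.inf)
            lat[f] = float(np.clip(rng.normal(pop.latency_mean[f], pop.latency_sd[f]), 100.0, 500.0))
        subjects.append(
            SubjectModel(
                subject_id=f"sim{i:03d}",
                true_threshold_dbhl=thr,
                p1_amplitude_80=amp,
                p1_latency_80=lat,
                latency_slope=pop.latency_slope,
                amplitude_growth=pop.amplitude_growth,
                noise_rms=pop.noise_rms,
                artifact_rate=pop.artifact_rate,
            )
        )
    return subjects
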