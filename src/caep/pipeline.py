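"""End-to-end orchestration: simulate -> preprocess -> detect -> threshold.

These helpers wire the module-level operations into the clinical workflow:
band-pass filtering and artifact rejection produce the accepted-epoch
stream, the sequential Hotelling's T2 rule yields a verdict per intensity,
and the adaptive staircase drives intensities to the electrophysiological
threshold.  All randomness flows from a single seed through spawned
``numpy.random.SeedSequence`` streams.
"""
from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from . import norms
from .config import AnalysisConfig
from .containers import FREQUENCIES_HZ, EpochSet, StimulusConfig
from .detect import DetectionResult, sequential_detect
from .preprocess import average_epochs, bandpass_filter, reject_artifacts
from .simulate import SubjectModel, simulate_epoch_set
from .threshold import StaircaseTrace, run_staircase
from .waveform import P1Measurement, pick_p1

__all__ = [
    "accept_epochs",
    "detect_response",
    "make_simulated_responder",
    "estimate_threshold",
    "measure_p1_at",
    "high_intensity_detection_study",
    "cohort_parameter_frame",
]


def accept_epochs(raw: EpochSet, config: AnalysisConfig | None = None) -> tuple[EpochSet, int]:
    """Filter then artifact-reject a raw epoch set; returns (accepted, n_rejected)."""
    cfg = config or AnalysisConfig()
    filtered = bandpass_filter(raw, cfg.filter_low_hz, cfg.filter_high_hz, cfg.filter_order)
    return reject_artifacts(filtered, cfg.reject_uv, cfg.reject_mode)


def detect_response(raw: EpochSet, config: AnalysisConfig | None = None) -> DetectionResult:
    """Full objective detection on a raw epoch set."""
    cfg = config or AnalysisConfig()
    accepted, _ = accept_epochs(raw, cfg)
    if accepted.is_empty:
        return DetectionResult(
            present=False, t2=float("nan"), p_value=float("nan"),
            n_epochs=0, stage="insufficient",
        )
    return sequential_detect(accepted, cfg.detection())


def make_simulated_responder(
    subject: SubjectModel,
    frequency_hz: float,
    seed: int | np.random.SeedSequence,
    config: AnalysisConfig | None = None,
):
    """Responder callable for :func:`caep.threshold.run_staircase`.

    Each call simulates a fresh recording run of ``delivered_epochs`` stimuli
    at the requested intensity and runs the detection pipeline on it.  Seeds
    are spawned per intensity so verdicts at different levels use
    independent noise.
    """
    cfg = config or AnalysisConfig()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = iter(ss.spawn(64))

    def responder(intensity_dbhl: int) -> DetectionResult:
        stim = StimulusConfig(frequency_hz=frequency_hz, intensity_dbhl=intensity_dbhl)
        raw = simulate_epoch_set(subject, stim, cfg.delivered_epochs, next(streams))
        return detect_response(raw, cfg)

    return responder


def estimate_threshold(
    subject: SubjectModel,
    frequency_hz: float,
    seed: int | np.random.SeedSequence,
    config: AnalysisConfig | None = None,
) -> StaircaseTrace:
    """Run the adaptive staircase for one simulated subject and frequency."""
    responder = make_simulated_responder(subject, frequency_hz, seed, config)
    return run_staircase(responder, frequency_hz)


def measure_p1_at(
    subject: SubjectModel,
    frequency_hz: float,
    intensity_dbhl: int,
    seed: int | np.random.SeedSequence,
    config: AnalysisConfig | None = None,
) -> tuple[P1Measurement, float]:
    """Average a simulated run and measure P1; returns (measurement, residual noise)."""
    cfg = config or AnalysisConfig()
    stim = StimulusConfig(frequency_hz=frequency_hz, intensity_dbhl=intensity_dbhl)
    raw = simulate_epoch_set(subject, stim, cfg.delivered_epochs, seed)
    accepted, _ = accept_epochs(raw, cfg)
    used = accepted.with_data(accepted.data[: cfg.n_max])
    avg = average_epochs(used, noise_window_ms=cfg.bin_window_ms)
    return pick_p1(avg, cfg.p1_window_ms, cfg.p1_smooth_hz), avg.residual_noise


def high_intensity_detection_study(
    n_subjects: int = 39,
    seed: int | np.random.SeedSequence = 0,
    config: AnalysisConfig | None = None,
    residual_noise_target_uv: float = 3.2,
) -> pd.DataFrame:
    """Detection study at the 80 dB HL protocol maximum.

    Simulates ``n_subjects`` subjects cycling through the four test
    frequencies, each with the normative mean P1 amplitude and latency at
    its frequency, with per-epoch noise scaled so that the residual noise of
    a full 150-epoch average sits at ``residual_noise_target_uv``.  Returns
    one row per subject with the detection verdict and statistics.
    """
    cfg = config or AnalysisConfig()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    noise_rms = residual_noise_target_uv * math.sqrt(cfg.n_max)
    rows = []
    for i, child in enumerate(ss.spawn(n_subjects)):
        f = FREQUENCIES_HZ[i % len(FREQUENCIES_HZ)]
        subject = SubjectModel(
            subject_id=f"hi{i:03d}",
            true_threshold_dbhl={f: norms.CAEP_THRESHOLD[f]["median"]},
            p1_amplitude_80={f: norms.P1_AMPLITUDE_80[f]["mean"]},
            p1_latency_80={f: norms.P1_LATENCY_80[f]["mean"]},
            noise_rms=noise_rms,
        )
        stim = StimulusConfig(frequency_hz=f, intensity_dbhl=80)
        raw = simulate_epoch_set(subject, stim, cfg.delivered_epochs, child)
        res = detect_response(raw, cfg)
        rows.append(
            {
                "subject_id": subject.subject_id,
                "frequency_hz": f,
                "present": res.present,
                "t2": res.t2,
                "p_value": res.p_value,
                "n_epochs": res.n_epochs,
                "stage": res.stage,
                "residual_noise": res.residual_noise,
            }
        )
    return pd.DataFrame(rows)


def cohort_parameter_frame(
    subjects: Sequence[SubjectModel],
    frequencies: Sequence[float] = FREQUENCIES_HZ,
) -> pd.DataFrame:
    """Ground-truth cohort parameters as a tidy results frame.

    One row per subject x frequency with the generating P1 latency and
    amplitude anchors (80 dB HL) and true thresholds - the round-trip input
    for :func:`caep.report.build_tables`.
    """
    rows = []
    for s in subjects:
        for f in frequencies:
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "frequency_hz": f,
                    "latency_ms": s.p1_latency_80[f],
                    "amplitude_uv": s.p1_amplitude_80[f],
                    "threshold_dbhl": s.true_threshold_dbhl[f],
                }
            )
    return pd.DataFrame(rows)
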