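"""Epoch preprocessing: filtering, artifact rejection, averaging, noise tiers.

Residual noise is the RMS over samples of the standard error of the mean
waveform, sqrt(mean_t(var_epochs(x_t) / N)); for independent noise of
per-sample RMS sigma it scales as sigma / sqrt(N).  The quality tiers are
good (<= 3.2 uV), slightly compromised (3.2-3.6 uV) and poor (> 3.6 uV);
poor averages are not acceptable evidence for a present response.
"""
from __future__ import annotations

import numpy as np
from scipy import signal

from .containers import AveragedResponse, EpochSet, QualityTier
from .exceptions import DomainError, EmptyEpochSetError, InsufficientEpochsError

__all__ = [
    "bandpass_filter",
    "reject_artifacts",
    "average_epochs",
    "residual_noise",
    "classify_quality",
    "GOOD_NOISE_UV",
    "MAX_NOISE_UV",
]

#: Residual-noise cutoffs (uV): good <= 3.2, acceptable <= 3.6, poor above.
GOOD_NOISE_UV = 3.2
MAX_NOISE_UV = 3.6

#: Default digital analysis passband (Hz) for cortical responses.
DEFAULT_BAND_HZ = (0.2, 30.0)

#: Default absolute-amplitude artifact rejection threshold (uV).
DEFAULT_REJECT_UV = 150.0


def design_bandpass(fs: float, low_hz: float, high_hz: float, order: int = 4) -> np.ndarray:
    """Butterworth band-pass (or low-pass when ``low_hz == 0``) in SOS form."""
    if not 0 <= low_hz < high_hz < fs / 2:
        raise DomainError(
            f"need 0 <= low < high < fs/2, got low={low_hz}, high={high_hz}, fs={fs}"
        )
    if low_hz == 0:
        return signal.butter(order, high_hz, btype="low", fs=fs, output="sos")
    return signal.butter(order, (low_hz, high_hz), btype="band", fs=fs, output="sos")


def bandpass_filter(
    epochs: EpochSet,
    low_hz: float = DEFAULT_BAND_HZ[0],
    high_hz: float = DEFAULT_BAND_HZ[1],
    order: int = 4,
) -> EpochSet:
    """Zero-phase band-pass each epoch; DC is removed whenever ``low_hz > 0``."""
    sos = design_bandpass(epochs.fs, low_hz, high_hz, order)
    if epochs.is_empty:
        return epochs.with_data(epochs.data)
    return epochs.with_data(signal.sosfiltfilt(sos, epochs.data, axis=1))


def reject_artifacts(
    epochs: EpochSet,
    reject_uv: float = DEFAULT_REJECT_UV,
    mode: str = "absolute",
) -> tuple[EpochSet, int]:
    """Drop epochs whose amplitude exceeds ``reject_uv``.

    ``mode`` selects the criterion: ``"absolute"`` rejects when any sample
    magnitude exceeds the threshold, ``"peak_to_peak"`` when the epoch's
    peak-to-peak range does.  Surviving epochs keep their order and values.
    An all-rejected result is returned as an empty EpochSet (``is_empty``),
    which downstream operations treat as no data.
    """
    if reject_uv <= 0:
        raise DomainError(f"reject_uv must be positive, got {reject_uv}")
    if mode == "absolute":
        bad = np.abs(epochs.data).max(axis=1) > reject_uv
    elif mode == "peak_to_peak":
        bad = np.ptp(epochs.data, axis=1) > reject_uv
    else:
        raise DomainError(f"unknown rejection mode {mode!r}")
    kept = epochs.with_data(epochs.data[~bad])
    return kept, int(bad.sum())


def residual_noise(epochs: EpochSet, window_ms: tuple[float, float] | None = None) -> float:
    """RMS standard error of the mean waveform (uV), optionally in a window."""
    if epochs.n_epochs < 2:
        raise InsufficientEpochsError(
            f"residual noise needs >= 2 epochs, got {epochs.n_epochs}"
        )
    data = epochs.data
    if window_ms is not None:
        t = epochs.times()
        mask = (t >= window_ms[0]) & (t < window_ms[1])
        if not mask.any():
            raise DomainError(f"window {window_ms} contains no samples")
        data = data[:, mask]
    sem2 = data.var(axis=0, ddof=1) / epochs.n_epochs
    return float(np.sqrt(sem2.mean()))


def classify_quality(rn: float) -> QualityTier:
    """Map a residual-noise value (uV) onto the recording quality tiers."""
    if rn < 0 or not np.isfinite(rn):
        raise DomainError(f"residual noise must be finite and >= 0, got {rn}")
    if rn <= GOOD_NOISE_UV:
        return QualityTier.GOOD
    if rn <= MAX_NOISE_UV:
        return QualityTier.SLIGHTLY_COMPROMISED
    return QualityTier.POOR


def average_epochs(
    epochs: EpochSet, noise_window_ms: tuple[float, float] | None = None
) -> AveragedResponse:
    """Per-sample arithmetic mean across epochs, with residual-noise tiering.

    With a single epoch the residual noise is undefined (NaN) and the quality
    is left unset.
    """
    if epochs.is_empty:
        raise EmptyEpochSetError("cannot average an empty epoch set")
    waveform = epochs.data.mean(axis=0)
    if epochs.n_epochs >= 2:
        rn = residual_noise(epochs, noise_window_ms)
        quality = classify_quality(rn)
    else:
        rn, quality = float("nan"), None
    return AveragedResponse(
        waveform=waveform,
        fs=epochs.fs,
        t_start_ms=epochs.t_start_ms,
        n_epochs_used=epochs.n_epochs,
        residual_noise=rn,
        quality=quality,
        stimulus=epochs.stimulus,
        subject_id=epochs.subject_id,
    )
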