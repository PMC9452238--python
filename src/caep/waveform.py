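"""P1 peak measurement and latency-intensity description.

P1 is taken as the highest positive local peak of the averaged waveform
within the 100-500 ms search window, with amplitude measured baseline-to-peak
against the mean of the pre-stimulus segment.  Because the neonatal P1 is a
slow (< ~5 Hz) deflection while the averaged noise extends across the whole
analysis passband, the waveform is low-pass smoothed (zero phase, default
10 Hz) before peak location; the smoothing leaves the P1 bump itself
essentially untouched.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal, stats

from .containers import AveragedResponse
from .exceptions import DomainError

__all__ = [
    "P1Measurement",
    "LatencyIntensityFit",
    "pick_p1",
    "latency_intensity_curve",
]

#: Default P1 search window, ms post-stimulus.
DEFAULT_P1_WINDOW_MS = (100.0, 500.0)

#: Default zero-phase low-pass corner (Hz) applied before peak picking.
DEFAULT_SMOOTH_HZ = 10.0


@dataclass(frozen=True)
class P1Measurement:
    """Latency (ms) and baseline-to-peak amplitude (uV) of the P1 component.

    ``found`` is False when the search window contains no positive local
    peak; latency and amplitude are NaN in that case.
    """

    latency_ms: float
    amplitude_uv: float
    search_window_ms: tuple[float, float]
    found: bool

    @classmethod
    def not_found(cls, window: tuple[float, float]) -> "P1Measurement":
        return cls(float("nan"), float("nan"), window, False)


def pick_p1(
    avg: AveragedResponse,
    window_ms: tuple[float, float] = DEFAULT_P1_WINDOW_MS,
    smooth_hz: float | None = DEFAULT_SMOOTH_HZ,
    baseline_window_ms: tuple[float, float] | None = None,
) -> P1Measurement:
    """Locate the P1 peak of an averaged response.

    Parameters
    ----------
    avg
        The averaged waveform.
    window_ms
        Search window; must lie within the epoch span.
    smooth_hz
        Corner of the zero-phase low-pass applied before peak location
        (None disables smoothing).
    baseline_window_ms
        Segment whose mean defines the amplitude baseline.  Defaults to the
        whole pre-stimulus segment; when the epoch has no pre-stimulus
        samples the baseline is 0 uV.

    Ties between equally high peaks resolve to the earliest.
    """
    start, end = window_ms
    if start < avg.t_start_ms - 1e-9 or end > avg.t_end_ms + 1e-9:
        raise DomainError(
            f"search window {window_ms} outside epoch span "
            f"({avg.t_start_ms}, {avg.t_end_ms})"
        )
    wave = avg.waveform
    if smooth_hz is not None and smooth_hz < avg.fs / 2:
        sos = signal.butter(4, smooth_hz, btype="low", fs=avg.fs, output="sos")
        wave = signal.sosfiltfilt(sos, wave)
    t = avg.times()

    if baseline_window_ms is None:
        base_mask = t < 0
    else:
        base_mask = (t >= baseline_window_ms[0]) & (t < baseline_window_ms[1])
    baseline = float(wave[base_mask].mean()) if base_mask.any() else 0.0

    in_window = (t >= start) & (t <= end)
    idx = np.flatnonzero(in_window)
    peaks, _ = signal.find_peaks(wave)
    peaks = peaks[np.isin(peaks, idx)]
    if peaks.size == 0:
        return P1Measurement.not_found(window_ms)
    amplitudes = wave[peaks] - baseline
    best = peaks[np.argmax(amplitudes)]  # argmax returns the first maximum: earliest tie
    amp = float(wave[best] - baseline)
    # Floor against numerical ripple from zero-phase smoothing: a peak must
    # stand above ~0.1% of the waveform's overall scale to count.
    floor = 1e-3 * float(np.max(np.abs(wave))) if wave.any() else 0.0
    if amp <= floor:
        return P1Measurement.not_found(window_ms)
    return P1Measurement(
        latency_ms=float(t[best]),
        amplitude_uv=amp,
        search_window_ms=window_ms,
        found=True,
    )


@dataclass(frozen=True)
class LatencyIntensityFit:
    """Ordinary least-squares line of P1 latency on stimulus intensity."""

    slope_ms_per_db: float
    intercept_ms: float
    n_points: int

    @property
    def slope_sign(self) -> int:
        return int(np.sign(self.slope_ms_per_db))


def latency_intensity_curve(
    measurements: Sequence[tuple[float, P1Measurement]],
) -> LatencyIntensityFit:
    """Fit latency as a linear function of intensity (ms per dB).

    Only measurements with ``found`` True enter the fit; at least two
    distinct intensities are required.  A negative slope is the expected
    physiology: latency falls as intensity rises.
    """
    pts = [(i, m.latency_ms) for i, m in measurements if m.found]
    if len(pts) < 2:
        raise DomainError(f"need >= 2 found P1 measurements, got {len(pts)}")
    x = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    if np.unique(x).size < 2:
        raise DomainError("need >= 2 distinct intensities for a line fit")
    if np.allclose(y, y[0]):
        # Degenerate: constant latency; linregress would return slope 0 too,
        # but short-circuit to avoid its r-value warnings.
        return LatencyIntensityFit(0.0, float(y[0]), len(pts))
    fit = stats.linregress(x, y)
    return LatencyIntensityFit(float(fit.slope), float(fit.intercept), len(pts))
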