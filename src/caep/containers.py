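"""Shared data containers for epoch-level EEG data and averaged responses.

Voltages are in microvolts (uV) throughout, times in milliseconds relative to
stimulus onset (negative = pre-stimulus baseline), and sampling rates in Hz.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import DomainError

#: Stimulus intensities live on a 5 dB grid between 0 and 80 dB HL.
INTENSITY_GRID_DB = tuple(range(0, 85, 5))

#: Test frequencies of the protocol.
FREQUENCIES_HZ = (500, 1000, 2000, 4000)


class QualityTier(str, enum.Enum):
    """Recording quality implied by the residual noise of an average.

    A residual noise at or below 3.2 uV marks a good-quality recording,
    between 3.2 and 3.6 uV a slightly compromised one, and above 3.6 uV a
    poor one.  Poor recordings are not valid evidence for a present response.
    """

    GOOD = "good"
    SLIGHTLY_COMPROMISED = "slightly_compromised"
    POOR = "poor"


@dataclass(frozen=True)
class StimulusConfig:
    """Tone-burst stimulus parameters.

    The tone burst is 40 ms long with a 10 ms cosine rise/fall and a 30 ms
    plateau, presented with alternating polarity roughly every 1.125 s
    (a ~0.9 Hz nominal presentation rate; the acoustic waveform itself is
    never synthesised here, only its metadata carried along).
    """

    frequency_hz: float
    intensity_dbhl: float
    isi_s: float = 1.125
    tone_duration_ms: float = 40.0
    rise_fall_ms: float = 10.0
    plateau_ms: float = 30.0

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0:
            raise DomainError(f"frequency must be positive, got {self.frequency_hz}")
        if not 0 <= self.intensity_dbhl <= 80:
            raise DomainError(
                f"intensity must lie in [0, 80] dB HL, got {self.intensity_dbhl}"
            )
        if self.intensity_dbhl % 5 != 0:
            raise DomainError(
                f"intensity must sit on the 5 dB grid, got {self.intensity_dbhl}"
            )


@dataclass
class EpochSet:
    """A stack of stimulus-locked EEG epochs from one recording condition.

    Attributes
    ----------
    data
        Array of shape (n_epochs, n_samples) holding scalp voltage in uV.
    fs
        Sampling rate in Hz.
    t_start_ms
        Time of the first sample relative to stimulus onset (ms); negative
        values mean the epoch includes a pre-stimulus baseline.
    stimulus
        Stimulus metadata, if known.
    subject_id
        Identifier of the recorded subject, if known.
    """

    data: np.ndarray
    fs: float
    t_start_ms: float
    stimulus: StimulusConfig | None = None
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DomainError(f"epoch data must be 2-D, got shape {self.data.shape}")
        if self.fs <= 0:
            raise DomainError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def t_end_ms(self) -> float:
        return self.t_start_ms + self.n_samples * 1000.0 / self.fs

    @property
    def is_empty(self) -> bool:
        return self.n_epochs == 0

    def times(self) -> np.ndarray:
        """Sample times in ms relative to stimulus onset."""
        return self.t_start_ms + np.arange(self.n_samples) * 1000.0 / self.fs

    def with_data(self, data: np.ndarray) -> "EpochSet":
        """Copy of this set with `data` replaced, metadata preserved."""
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass
class AveragedResponse:
    """The across-epoch average waveform with its noise bookkeeping.

    ``residual_noise`` is the RMS (over samples) of the standard error of the
    mean waveform and quantifies the noise remaining after averaging
    ``n_epochs_used`` epochs.  ``quality`` maps that value onto the
    good / slightly compromised / poor tiers; it is ``None`` when residual
    noise could not be estimated (single epoch).
    """

    waveform: np.ndarray
    fs: float
    t_start_ms: float
    n_epochs_used: int
    residual_noise: float = float("nan")
    quality: QualityTier | None = None
    stimulus: StimulusConfig | None = field(default=None, repr=False)
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float).ravel()

    @property
    def n_samples(self) -> int:
        return self.waveform.size

    @property
    def t_end_ms(self) -> float:
        return self.t_start_ms + self.n_samples * 1000.0 / self.fs

    def times(self) -> np.ndarray:
        return self.t_start_ms + np.arange(self.n_samples) * 1000.0 / self.fs
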