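"""Run configuration: every tunable default in one place, YAML-loadable."""
from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .detect import DetectionConfig
from .exceptions import DomainError

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    """End-to-end analysis parameters.

    Filtering and rejection feed the accepted-epoch stream; the detection
    block parameterises the sequential Hotelling's T2 rule; the waveform
    block the P1 measurement.  ``delivered_epochs`` is how many stimuli a
    simulated run presents per intensity so that, after artifact rejection,
    the 150-epoch cap is normally reachable.
    """

    filter_low_hz: float = 0.2
    filter_high_hz: float = 30.0
    filter_order: int = 4
    reject_uv: float = 150.0
    reject_mode: str = "absolute"

    n_bins: int = 9
    bin_window_ms: tuple[float, float] = (100.0, 550.0)
    alpha_early: float = 0.001
    alpha_final: float = 0.05
    n_min: int = 50
    n_max: int = 150
    cadence: int = 1
    max_residual_noise: float = 3.6

    p1_window_ms: tuple[float, float] = (100.0, 500.0)
    p1_smooth_hz: float = 10.0

    delivered_epochs: int = 180

    def detection(self) -> DetectionConfig:
        return DetectionConfig(
            n_bins=self.n_bins,
            bin_window_ms=tuple(self.bin_window_ms),
            alpha_early=self.alpha_early,
            alpha_final=self.alpha_final,
            n_min=self.n_min,
            n_max=self.n_max,
            cadence=self.cadence,
            max_residual_noise=self.max_residual_noise,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DomainError(f"unknown config keys: {sorted(unknown)}")
        for key in ("bin_window_ms", "p1_window_ms"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["bin_window_ms"] = list(data["bin_window_ms"])
        data["p1_window_ms"] = list(data["p1_window_ms"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
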