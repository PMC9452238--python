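"""Adaptive intensity staircase for electrophysiological threshold search.

The protocol (a modified Van Dun decision scheme) starts at the 80 dB HL
maximum to confirm the auditory pathway responds at all, then probes
30 dB HL.  While responses are present it descends through 15, 5 and
0 dB HL; on the first absent verdict at any descending level it ascends in
5 dB steps until a response is found (or a level already known to respond
is reached).  The electrophysiological threshold is the lowest intensity
with a present verdict that has an absent verdict 5 dB below it - except at
0 dB HL, the floor of the grid.  Intensities live on the 5 dB grid in
[0, 80]; no level is ever tested twice.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .detect import DetectionResult
from .exceptions import DomainError, InconsistentTraceError

__all__ = [
    "STOP",
    "StaircaseStep",
    "StaircaseTrace",
    "next_level",
    "run_staircase",
    "randomize_frequency_order",
]

#: Sentinel returned by :func:`next_level` when the staircase is finished.
STOP = None

#: Intensity (dB HL) at which every staircase starts.
START_LEVEL = 80
#: Descending probe sequence after a response at the start level.
DESCENT_LEVELS = (30, 15, 5, 0)
#: Step size (dB) of the ascending phase.
ASCENT_STEP = 5


@dataclass(frozen=True)
class StaircaseStep:
    """One tested intensity and the detector's verdict there."""

    intensity_dbhl: int
    result: DetectionResult

    @property
    def present(self) -> bool:
        return self.result.present


@dataclass
class StaircaseTrace:
    """Ordered record of one frequency's staircase.

    ``threshold_dbhl`` is ``None`` while the staircase is incomplete and
    also when no response was found at 80 dB HL (``reached`` False, reported
    as "not reached (>80 dB HL)").
    """

    frequency_hz: float
    steps: list[StaircaseStep] = field(default_factory=list)
    threshold_dbhl: int | None = None
    complete: bool = False

    @property
    def reached(self) -> bool:
        return self.threshold_dbhl is not None

    @property
    def tested_levels(self) -> list[int]:
        return [s.intensity_dbhl for s in self.steps]

    @property
    def threshold_label(self) -> str:
        if not self.complete:
            return "incomplete"
        if self.threshold_dbhl is None:
            return "not reached (>80 dB HL)"
        return f"{self.threshold_dbhl} dB HL"


def _check_level(level: int) -> None:
    if not 0 <= level <= 80 or level % 5 != 0:
        raise InconsistentTraceError(f"intensity {level} off the 5 dB grid in [0, 80]")


def _replay(steps: Sequence[StaircaseStep]) -> tuple[int | None, int | None, bool]:
    """Replay a trace through the protocol state machine.

    Returns ``(next_level, threshold, finished)``.  ``next_level`` is None
    when the staircase is finished; ``threshold`` is None when it is either
    unfinished or unreachable (absent at 80 dB HL).
    Raises :class:`InconsistentTraceError` when the trace deviates from the
    protocol (wrong order, duplicate levels, off-grid intensities).
    """
    if not steps:
        return START_LEVEL, None, False

    it = iter(steps)
    first = next(it)
    _check_level(first.intensity_dbhl)
    if first.intensity_dbhl != START_LEVEL:
        raise InconsistentTraceError(
            f"staircase must start at {START_LEVEL} dB HL, got {first.intensity_dbhl}"
        )
    if not first.present:
        if any(True for _ in it):
            raise InconsistentTraceError("trace continues after absent at 80 dB HL")
        return STOP, None, True

    # Verdicts seen so far during replay; future steps must never influence
    # the state machine, so this is built incrementally.
    seen: dict[int, bool] = {START_LEVEL: True}
    phase = "descend"
    desc_idx = 0  # next index into DESCENT_LEVELS to expect
    expected = DESCENT_LEVELS[0]
    for step in it:
        _check_level(step.intensity_dbhl)
        if step.intensity_dbhl != expected:
            raise InconsistentTraceError(
                f"expected level {expected} dB HL next, trace has {step.intensity_dbhl}"
            )
        if step.intensity_dbhl in seen:
            raise InconsistentTraceError(
                f"level {step.intensity_dbhl} dB HL tested twice"
            )
        seen[step.intensity_dbhl] = step.present
        if phase == "descend":
            if step.present:
                if step.intensity_dbhl == 0:
                    return STOP, 0, True
                desc_idx += 1
                expected = DESCENT_LEVELS[desc_idx]
            else:
                phase = "ascend"
                expected = step.intensity_dbhl + ASCENT_STEP
                # a level just above already known present stops the ascent
                if seen.get(expected):
                    return STOP, expected, True
        else:  # ascend
            if step.present:
                return STOP, step.intensity_dbhl, True
            expected = step.intensity_dbhl + ASCENT_STEP
            if expected in seen:
                if seen[expected]:
                    return STOP, expected, True
                raise InconsistentTraceError(
                    f"ascent reached level {expected} dB HL already tested absent"
                )
    return expected, None, False


def next_level(trace: StaircaseTrace) -> int | None:
    """Next intensity to test (dB HL), or :data:`STOP` when finished.

    Deterministic function of the verdicts recorded so far; raises
    :class:`InconsistentTraceError` for traces the protocol cannot produce.
    """
    nxt, _, _ = _replay(trace.steps)
    return nxt


def run_staircase(
    responder: Callable[[int], DetectionResult],
    frequency_hz: float,
) -> StaircaseTrace:
    """Drive the staircase for one frequency using ``responder``.

    ``responder`` maps an intensity on the 5 dB grid to a
    :class:`~caep.detect.DetectionResult`.  Responder exceptions propagate
    with the partial trace attached to the exception (``partial_trace``).
    """
    trace = StaircaseTrace(frequency_hz=frequency_hz)
    while True:
        nxt, thr, finished = _replay(trace.steps)
        if finished:
            trace.threshold_dbhl = thr
            trace.complete = True
            return trace
        try:
            result = responder(nxt)
        except Exception as err:
            err.partial_trace = trace  # type: ignore[attr-defined]
            raise
        trace.steps.append(StaircaseStep(intensity_dbhl=nxt, result=result))


def randomize_frequency_order(
    frequencies: Sequence[float],
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> list[float]:
    """Uniformly random, seed-reproducible presentation order of frequencies.

    The clinical protocol randomises the order of test frequencies to avoid
    habituation of the central auditory pathway.
    """
    if len(frequencies) == 0:
        raise DomainError("frequency list must be non-empty")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(frequencies))
    return [frequencies[i] for i in order]
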