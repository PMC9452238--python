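"""Published normative summary rows for neonatal CAEP measures.

These per-frequency descriptive rows (N = 39 normal-hearing neonates) are the
reference values behind the simulator's population defaults: P1 latency and
baseline-to-peak amplitude measured at 80 dB HL, and electrophysiological
thresholds from the adaptive staircase.  ``ci`` is the printed full width of
the 95% t-based confidence interval of the mean.
"""
from __future__ import annotations

from types import MappingProxyType

#: P1 latency at 80 dB HL (ms) per stimulus frequency (Hz).
P1_LATENCY_80 = MappingProxyType({
    500: {"mean": 242.79, "median": 243.0, "sd": 51.30, "min": 137.0, "max": 419.0, "ci": 33.27, "n": 39},
    1000: {"mean": 225.54, "median": 226.0, "sd": 36.31, "min": 125.0, "max": 307.0, "ci": 23.54, "n": 39},
    2000: {"mean": 232.74, "median": 231.0, "sd": 39.84, "min": 160.0, "max": 353.0, "ci": 25.83, "n": 39},
    4000: {"mean": 244.51, "median": 241.0, "sd": 46.26, "min": 157.0, "max": 370.0, "ci": 30.00, "n": 39},
})

#: P1 amplitude at 80 dB HL (uV) per stimulus frequency (Hz).
P1_AMPLITUDE_80 = MappingProxyType({
    500: {"mean": 6.41, "median": 6.07, "sd": 3.39, "min": 1.30, "max": 18.78, "ci": 2.20, "n": 39},
    1000: {"mean": 7.36, "median": 7.15, "sd": 4.10, "min": 2.48, "max": 21.83, "ci": 2.66, "n": 39},
    2000: {"mean": 6.31, "median": 5.43, "sd": 3.31, "min": 2.13, "max": 14.49, "ci": 2.14, "n": 39},
    4000: {"mean": 5.88, "median": 5.78, "sd": 2.83, "min": 1.94, "max": 15.95, "ci": 1.84, "n": 39},
})

#: Electrophysiological CAEP thresholds (dB HL) per stimulus frequency (Hz).
CAEP_THRESHOLD = MappingProxyType({
    500: {"mean": 24.87, "median": 25.0, "sd": 10.41, "min": 0.0, "max": 40.0, "ci": 6.76, "n": 39},
    1000: {"mean": 25.00, "median": 30.0, "sd": 9.03, "min": 0.0, "max": 35.0, "ci": 5.86, "n": 39},
    2000: {"mean": 28.72, "median": 30.0, "sd": 7.84, "min": 0.0, "max": 40.0, "ci": 5.08, "n": 39},
    4000: {"mean": 29.49, "median": 30.0, "sd": 6.66, "min": 15.0, "max": 50.0, "ci": 4.32, "n": 39},
})
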