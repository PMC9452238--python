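"""Descriptive statistics and normative-style summary tables.

Each measure (P1 latency, P1 amplitude at 80 dB HL, threshold) is summarised
per frequency with rows Mean / Median / SD / Min / Max / CI / N, where CI is
the full width of the 95% t-based confidence interval of the mean,
2 * t(0.975, N-1) * SD / sqrt(N).  Display rounding is half-up to two
decimals; full precision is kept internally.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import FREQUENCIES_HZ
from .exceptions import DomainError

__all__ = [
    "DescriptiveStats",
    "summarize",
    "t_ci_width",
    "build_tables",
    "round_half_up",
]

TABLE_ROWS = ("Mean", "Median", "SD", "Min", "Max", "CI", "N")

#: Measures expected per subject in a cohort results frame.
MEASURE_COLUMNS = {
    "latency": "latency_ms",
    "amplitude": "amplitude_uv",
    "threshold": "threshold_dbhl",
}


@dataclass(frozen=True)
class DescriptiveStats:
    """Summary row: mean, median, unbiased SD, range, 95% CI width, N."""

    mean: float
    median: float
    sd: float
    minimum: float
    maximum: float
    ci_width: float
    n: int


def t_ci_width(sd: float, n: int, level: float = 0.95) -> float:
    """Full width of the t-based confidence interval of a mean.

    ``2 * t((1 + level)/2, n-1) * sd / sqrt(n)`` - the quantity printed in
    the normative tables' CI rows.
    """
    if n < 2:
        raise DomainError(f"CI width needs n >= 2, got {n}")
    if sd < 0:
        raise DomainError(f"sd must be >= 0, got {sd}")
    tq = stats.t.ppf((1.0 + level) / 2.0, n - 1)
    return float(2.0 * tq * sd / np.sqrt(n))


def summarize(values: Iterable[float]) -> DescriptiveStats:
    """Descriptive statistics of a sample (n >= 2).

    SD uses the unbiased (N-1) estimator; the CI width uses the Student-t
    quantile at the sample's own degrees of freedom.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise DomainError(f"summarize needs >= 2 values, got {x.size}")
    sd = float(x.std(ddof=1))
    return DescriptiveStats(
        mean=float(x.mean()),
        median=float(np.median(x)),
        sd=sd,
        minimum=float(x.min()),
        maximum=float(x.max()),
        ci_width=t_ci_width(sd, x.size),
        n=int(x.size),
    )


def round_half_up(value: float, decimals: int = 2) -> float:
    """Decimal half-up rounding, matching tabular print style."""
    if not np.isfinite(value):
        return value
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _column(values: np.ndarray) -> list[float]:
    values = values[np.isfinite(values)]
    if values.size == 0:
        return [np.nan] * 7
    if values.size == 1:
        v = float(values[0])
        return [v, v, np.nan, v, v, np.nan, 1]
    s = summarize(values)
    return [s.mean, s.median, s.sd, s.minimum, s.maximum, s.ci_width, s.n]


def build_tables(
    cohort_results: pd.DataFrame,
    frequencies: Sequence[float] = FREQUENCIES_HZ,
) -> dict[str, pd.DataFrame]:
    """Build the three per-frequency summary tables of a cohort study.

    ``cohort_results`` needs one row per subject x frequency with columns
    ``subject_id``, ``frequency_hz`` and the measure columns ``latency_ms``,
    ``amplitude_uv`` (both at 80 dB HL) and ``threshold_dbhl``.  Missing
    measurements produce NA cells with a warning, never a silent drop.

    Returns ``{"latency": ..., "amplitude": ..., "threshold": ...}`` with
    rows Mean/Median/SD/Min/Max/CI/N and one column per frequency, rounded
    half-up to two decimals.
    """
    required = {"subject_id", "frequency_hz", *MEASURE_COLUMNS.values()}
    missing_cols = required - set(cohort_results.columns)
    if missing_cols:
        raise DomainError(f"cohort results missing columns: {sorted(missing_cols)}")

    tables: dict[str, pd.DataFrame] = {}
    for name, col in MEASURE_COLUMNS.items():
        table = {}
        for f in frequencies:
            vals = cohort_results.loc[
                cohort_results["frequency_hz"] == f, col
            ].to_numpy(dtype=float)
            n_missing = int(np.sum(~np.isfinite(vals)))
            if n_missing or vals.size == 0:
                warnings.warn(
                    f"{name} at {f} Hz: {n_missing or 'all'} missing measurement(s)",
                    stacklevel=2,
                )
            table[f] = [round_half_up(v) for v in _column(vals)]
        tables[name] = pd.DataFrame(table, index=list(TABLE_ROWS))
    return tables


def tables_to_tsv(tables: dict[str, pd.DataFrame]) -> str:
    """Serialise the three summary tables as TSV blocks."""
    blocks = []
    for name, df in tables.items():
        blocks.append(f"# {name}")
        blocks.append(df.to_csv(sep="\t"))
    return "\n".join(blocks)
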