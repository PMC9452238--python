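"""Objective CAEP detection: nine-bin reduction, Hotelling's T2, stopping rule.

Each accepted epoch is reduced to a nine-dimensional vector of mean voltages
over equal contiguous time bins spanning the response window.  Hotelling's
T2 - the multivariate one-sample extension of Student's t - tests whether
the mean bin vector is zero:

    T2 = N * xbar' S^-1 xbar,      F = (N - p) / (p (N - 1)) * T2,

with xbar the bin-mean vector, S the unbiased sample covariance across
epochs, p the number of bins, and F referred to an F(p, N - p) distribution.

The two-stage stopping rule evaluates the test at every accepted-epoch count
from 50 onwards, declaring a response present immediately when p < 0.001;
failing that, at 150 epochs the response is present iff p < 0.05.  A present
verdict additionally requires that the residual noise of the averaged data
is no worse than the 3.6 uV quality ceiling.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import EpochSet, QualityTier
from .exceptions import (
    DegenerateCovarianceError,
    DomainError,
    InsufficientEpochsError,
)
from .preprocess import MAX_NOISE_UV, classify_quality, residual_noise

__all__ = [
    "BinnedEpochs",
    "DetectionConfig",
    "DetectionResult",
    "bin_epochs",
    "hotelling_t2",
    "sequential_test",
    "sequential_detect",
]

#: Default binning window (ms post-stimulus) bracketing the neonatal P1.
DEFAULT_BIN_WINDOW_MS = (100.0, 550.0)
DEFAULT_N_BINS = 9


@dataclass
class BinnedEpochs:
    """Epochs reduced to per-bin mean voltages: an (epochs, n_bins) matrix."""

    data: np.ndarray
    bin_window_ms: tuple[float, float]

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_bins(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class DetectionConfig:
    """Parameters of the sequential detection rule."""

    n_bins: int = DEFAULT_N_BINS
    bin_window_ms: tuple[float, float] = DEFAULT_BIN_WINDOW_MS
    alpha_early: float = 0.001
    alpha_final: float = 0.05
    n_min: int = 50
    n_max: int = 150
    #: Early-stage testing cadence in accepted epochs (1 = test at every epoch).
    cadence: int = 1
    max_residual_noise: float = MAX_NOISE_UV


@dataclass
class DetectionResult:
    """Outcome of objective response detection.

    ``stage`` is ``"early"`` when the p < alpha_early criterion fired before
    the epoch cap, ``"final"`` when the decision was made at the cap, and
    ``"insufficient"`` when fewer than ``n_min`` accepted epochs were
    available (no verdict: ``present`` is False).
    """

    present: bool
    t2: float
    p_value: float
    n_epochs: int
    stage: str
    residual_noise: float = float("nan")
    quality: QualityTier | None = None


def bin_epochs(
    epochs: EpochSet,
    bin_window_ms: tuple[float, float] = DEFAULT_BIN_WINDOW_MS,
    n_bins: int = DEFAULT_N_BINS,
) -> BinnedEpochs:
    """Reduce each epoch to its mean voltage in equal contiguous time bins.

    Samples are assigned to half-open bins [start, end) between the window
    edges.  The window must lie inside the epoch.
    """
    if n_bins < 1:
        raise DomainError(f"n_bins must be >= 1, got {n_bins}")
    start, end = bin_window_ms
    if start >= end:
        raise DomainError(f"empty bin window {bin_window_ms}")
    if start < epochs.t_start_ms - 1e-9 or end > epochs.t_end_ms + 1e-9:
        raise DomainError(
            f"bin window {bin_window_ms} outside epoch span "
            f"({epochs.t_start_ms}, {epochs.t_end_ms})"
        )
    t = epochs.times()
    edges = np.linspace(start, end, n_bins + 1)
    means = np.empty((epochs.n_epochs, n_bins))
    for j in range(n_bins):
        mask = (t >= edges[j] - 1e-9) & (t < edges[j + 1] - 1e-9)
        if not mask.any():
            raise DomainError(f"bin {j} of window {bin_window_ms} contains no samples")
        means[:, j] = epochs.data[:, mask].mean(axis=1)
    return BinnedEpochs(data=means, bin_window_ms=(start, end))


def hotelling_t2(binned: BinnedEpochs) -> tuple[float, float, float]:
    """One-sample Hotelling's T2 against the zero mean vector.

    Returns ``(t2, f_stat, p_value)`` with the p-value from the upper tail
    of F(p, N - p).  Requires N > p and an invertible sample covariance.
    """
    x = binned.data
    n, p = x.shape
    if n <= p:
        raise InsufficientEpochsError(
            f"Hotelling's T2 needs more epochs ({n}) than bins ({p})"
        )
    xbar = x.mean(axis=0)
    s = np.cov(x, rowvar=False, ddof=1).reshape(p, p)
    try:
        sol = np.linalg.solve(s, xbar)
    except np.linalg.LinAlgError as err:
        raise DegenerateCovarianceError("singular bin covariance") from err
    if not np.all(np.isfinite(sol)):
        raise DegenerateCovarianceError("singular bin covariance")
    t2 = float(n * xbar @ sol)
    f_stat = (n - p) / (p * (n - 1)) * t2
    p_value = float(stats.f.sf(f_stat, p, n - p))
    return t2, float(f_stat), p_value


def _prefix_t2(x: np.ndarray, ns: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """T2 and p-value of every prefix length in ``ns`` of the (N, p) matrix.

    Vectorised over prefix lengths via cumulative first and second moments;
    used by the sequential rule, where the same statistic is re-evaluated as
    epochs accumulate.
    """
    n_total, p = x.shape
    csum = np.cumsum(x, axis=0)
    couter = np.cumsum(np.einsum("ni,nj->nij", x, x), axis=0)
    ns = np.asarray(ns)
    counts = ns.astype(float)[:, None]
    means = csum[ns - 1] / counts
    scatter = couter[ns - 1] - counts[:, :, None] * np.einsum(
        "ki,kj->kij", means, means
    )
    cov = scatter / (counts[:, :, None] - 1.0)
    try:
        sol = np.linalg.solve(cov, means[..., None])[..., 0]
    except np.linalg.LinAlgError as err:
        raise DegenerateCovarianceError("singular bin covariance") from err
    t2 = counts[:, 0] * np.einsum("ki,ki->k", means, sol)
    f_stat = (counts[:, 0] - p) / (p * (counts[:, 0] - 1)) * t2
    pvals = stats.f.sf(f_stat, p, ns - p)
    return t2, pvals


def sequential_test(
    binned: BinnedEpochs, config: DetectionConfig = DetectionConfig()
) -> DetectionResult:
    """Apply the two-stage sequential rule to an ordered binned-epoch matrix.

    Epochs are consumed in the order given.  The early stage tests every
    ``config.cadence``-th accepted-epoch count in [n_min, n_max) at
    ``alpha_early``; the final decision at ``n_max`` uses ``alpha_final``.
    Residual noise and quality are not known at this level (see
    :func:`sequential_detect`).
    """
    m = binned.n_epochs
    if m < config.n_min:
        return DetectionResult(
            present=False,
            t2=float("nan"),
            p_value=float("nan"),
            n_epochs=m,
            stage="insufficient",
        )
    n_cap = min(m, config.n_max)
    early_ns = np.arange(config.n_min, n_cap, config.cadence)
    ns = np.append(early_ns, n_cap) if (early_ns.size == 0 or early_ns[-1] != n_cap) else early_ns
    x = binned.data[:n_cap]
    if n_cap <= binned.n_bins:
        raise InsufficientEpochsError(
            f"sequential rule needs n_min > n_bins, got n_min={config.n_min}, "
            f"bins={binned.n_bins}"
        )
    t2s, pvals = _prefix_t2(x, ns)

    early_hits = np.flatnonzero((pvals < config.alpha_early) & (ns < config.n_max))
    if early_hits.size:
        k = early_hits[0]
        return DetectionResult(
            present=True,
            t2=float(t2s[k]),
            p_value=float(pvals[k]),
            n_epochs=int(ns[k]),
            stage="early",
        )
    if n_cap < config.n_max:
        # Ran out of accepted epochs before the cap without an early hit.
        return DetectionResult(
            present=False,
            t2=float(t2s[-1]),
            p_value=float(pvals[-1]),
            n_epochs=n_cap,
            stage="insufficient",
        )
    return DetectionResult(
        present=bool(pvals[-1] < config.alpha_final),
        t2=float(t2s[-1]),
        p_value=float(pvals[-1]),
        n_epochs=int(config.n_max),
        stage="final",
    )


def sequential_detect(
    epochs: EpochSet, config: DetectionConfig = DetectionConfig()
) -> DetectionResult:
    """Run the full objective detection on accepted (post-rejection) epochs.

    Bins the epochs, applies the sequential rule, then attaches the residual
    noise of the final average - all accepted epochs up to the cap, within
    the binning window - and its quality tier.  A present verdict is refused
    when that recording is poor (residual noise above the 3.6 uV ceiling);
    an early statistical stop does not excuse a noisy recording.
    """
    binned = bin_epochs(epochs, config.bin_window_ms, config.n_bins)
    result = sequential_test(binned, config)
    n_avail = min(epochs.n_epochs, config.n_max)
    if n_avail >= 2:
        final = epochs.with_data(epochs.data[:n_avail])
        rn = residual_noise(final, config.bin_window_ms)
        result.residual_noise = rn
        result.quality = classify_quality(rn)
        if result.quality is QualityTier.POOR and result.present:
            result.present = False
    return result
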