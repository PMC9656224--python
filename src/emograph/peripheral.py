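"""Time-domain statistical descriptors for peripheral physiological channels.

Twelve statistics per channel per window, in a fixed order:
mean, variance, std, max, min, skewness, kurtosis, q25, q50, q75,
zero-crossing rate, approximate entropy.  Moments are population (divide by
N); kurtosis is excess; quantiles use linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import cdist

from .core import Window

__all__ = [
    "STATISTIC_NAMES",
    "PeripheralFeatureBlock",
    "basic_stats",
    "zero_crossing_rate",
    "approximate_entropy",
    "peripheral_feature_vector",
]

STATISTIC_NAMES = (
    "mean", "variance", "std", "max", "min", "skewness", "kurtosis",
    "q25", "q50", "q75", "zcr", "apen",
)

#: Default embedding length and tolerance factor for approximate entropy.
APEN_M = 2
APEN_R_FACTOR = 0.2


@dataclass
class PeripheralFeatureBlock:
    """Ordered per-channel statistics: channels outer, statistics inner."""

    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.names),):
            raise ValueError("values and names must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")


def basic_stats(x: np.ndarray) -> tuple[float, ...]:
    """(mean, variance, std, max, min, skewness, kurtosis, q25, q50, q75).

    Population moments; constant signals yield skewness = kurtosis = 0
    rather than NaN.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("basic_stats needs a 1-D vector of length >= 2")
    mu = x.mean()
    var = x.var()  # population
    # ptp == 0 catches constants whose variance is nonzero only through
    # rounding; var == 0 catches underflow of a genuinely tiny spread
    if np.ptp(x) == 0 or var == 0:
        var = std = 0.0
        skew = kurt = 0.0
    else:
        std = np.sqrt(var)
        z = (x - mu) / std
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4) - 3.0)
    q25, q50, q75 = np.quantile(x, [0.25, 0.5, 0.75])
    return (
        float(mu), float(var), float(std), float(x.max()), float(x.min()),
        skew, kurt, float(q25), float(q50), float(q75),
    )


def zero_crossing_rate(x: np.ndarray) -> float:
    """Strict sign changes of the mean-centred signal per sample step.

    Exact zeros after centring inherit the previous nonzero sign (leading
    zeros inherit the first nonzero sign), so plateaus do not count as
    crossings.  Result lies in [0, 1].
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("zero_crossing_rate needs a 1-D vector of length >= 2")
    s = np.sign(x - x.mean())
    nonzero = s != 0
    if not nonzero.any():
        return 0.0
    idx = np.where(nonzero, np.arange(s.size), -1)
    np.maximum.accumulate(idx, out=idx)
    first = s[nonzero][0]
    filled = np.where(idx >= 0, s[np.maximum(idx, 0)], first)
    return float(np.count_nonzero(filled[1:] != filled[:-1]) / (s.size - 1))


def _phi(x: np.ndarray, m: int, r: float) -> float:
    templates = sliding_window_view(x, m)
    d = cdist(templates, templates, metric="chebyshev")
    c = np.count_nonzero(d <= r, axis=1) / templates.shape[0]
    return float(np.mean(np.log(c)))


def approximate_entropy(
    x: np.ndarray, m: int = APEN_M, r: float | None = None
) -> float:
    """ApEn(m, r) = phi_m(r) - phi_{m+1}(r) with self-matches included.

    Template similarity is Chebyshev distance <= r; ``r`` defaults to
    0.2 x population std.  A constant signal (std = 0 with relative r)
    is defined to have ApEn 0.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size <= m + 1:
        raise ValueError(f"approximate_entropy needs length > m + 1 = {m + 1}")
    if r is None:
        std = x.std()
        if std == 0:
            return 0.0
        r = APEN_R_FACTOR * std
    if r < 0:
        raise ValueError("tolerance r must be >= 0")
    return _phi(x, m, r) - _phi(x, m + 1, r)


def channel_statistics(
    x: np.ndarray, m: int = APEN_M, r_factor: float = APEN_R_FACTOR
) -> np.ndarray:
    """All 12 statistics of one channel, in STATISTIC_NAMES order."""
    x = np.asarray(x, dtype=np.float64)
    stats = basic_stats(x)
    zcr = zero_crossing_rate(x)
    std = x.std()
    apen = 0.0 if std == 0 else approximate_entropy(x, m=m, r=r_factor * std)
    return np.array([*stats, zcr, apen], dtype=np.float64)


def peripheral_feature_vector(
    window: Window, m: int = APEN_M, r_factor: float = APEN_R_FACTOR
) -> PeripheralFeatureBlock:
    """12 statistics for every peripheral channel of a window.

    With 8 peripheral channels the block has 96 entries.  Names are
    ``<channel>__<statistic>``.
    """
    if len(window.peripheral_channels) < 1:
        raise ValueError("window has no peripheral channels")
    values: list[np.ndarray] = []
    names: list[str] = []
    for ch, row in zip(window.peripheral_channels, window.peripheral):
        try:
            values.append(channel_statistics(row, m=m, r_factor=r_factor))
        except ValueError as exc:
            raise ValueError(f"channel {ch!r}: {exc}") from exc
        names.extend(f"{ch}__{stat}" for stat in STATISTIC_NAMES)
    return PeripheralFeatureBlock(values=np.concatenate(values), names=names)
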