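"""Time-series preparation: normalization and time-lagged Spearman correlation.

Expression series are uniformly sampled per-gene measurements.  Before any
information-theoretic estimation each series is mean-centered and rescaled so
that its values lie in [-1, 1]; the kernel-density grid used by the transfer
entropy estimator spans exactly that cube.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "normalize_series",
    "lagged_spearman",
    "DegenerateSeriesError",
]

DEFAULT_LAGS: Tuple[int, ...] = (0, 1, 2, 3, 4, 5)


class DegenerateSeriesError(ValueError):
    """Raised when a series carries no usable variation (e.g. constant)."""


def normalize_series(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Mean-center a series and scale it into [-1, 1].

    The centered values are divided by the maximum absolute centered value,
    so at least one output entry equals +1 or -1.

    Parameters
    ----------
    values:
        Ordered real measurements, uniform sampling interval assumed.

    Returns
    -------
    numpy.ndarray of the same length, max absolute value exactly 1.

    Raises
    ------
    DegenerateSeriesError
        If the series is constant (no scale exists).
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D series")
    if arr.size < 2:
        raise DegenerateSeriesError("series must contain at least 2 values")
    if not np.all(np.isfinite(arr)):
        raise ValueError("series contains non-finite values")
    centered = arr - arr.mean()
    scale = np.max(np.abs(centered))
    if scale == 0.0:
        raise DegenerateSeriesError("constant series cannot be normalized")
    return centered / scale


def lagged_spearman(
    x: np.ndarray,
    y: np.ndarray,
    lags: Iterable[int] = DEFAULT_LAGS,
) -> Tuple[Mapping[int, float], int, float]:
    """Spearman rank correlation of ``x`` against ``y`` across time lags.

    For lag ``k`` the regulator series ``x`` is shifted forward in time so
    that ``x[t - k]`` is paired with ``y[t]``: the correlation is computed on
    ``x[: n - k]`` versus ``y[k:]``.  A positive lag therefore models delayed
    regulation of the target by the regulator.

    Ties are handled by the midrank convention (scipy's default).  The best
    lag maximizes the signed correlation; exact ties between lags are broken
    by the smallest lag.

    Returns
    -------
    (rho_by_lag, best_lag, best_rho)
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D series of equal length")
    n = x.size
    lags = sorted(set(int(k) for k in lags))
    if any(k < 0 for k in lags):
        raise ValueError("lags must be nonnegative")
    if max(lags) >= n - 2:
        raise ValueError(f"max lag {max(lags)} too large for series of length {n}")

    rho_by_lag: dict[int, float] = {}
    for k in lags:
        xs = x[: n - k] if k > 0 else x
        ys = y[k:]
        if np.ptp(xs) == 0 or np.ptp(ys) == 0:
            raise DegenerateSeriesError(f"all-tied subsequence at lag {k}")
        rho = stats.spearmanr(xs, ys).statistic
        rho_by_lag[k] = float(rho)

    best_lag = max(rho_by_lag, key=lambda k: (rho_by_lag[k], -k))
    return rho_by_lag, best_lag, rho_by_lag[best_lag]


def lagged_spearman_abs(
    x: np.ndarray, y: np.ndarray, lags: Iterable[int] = DEFAULT_LAGS
) -> Tuple[Mapping[int, float], int, float]:
    """Variant of :func:`lagged_spearman` selecting the lag with maximal |rho|.

    Useful for networks where repression (negative correlation) should rank
    as strongly as activation.  ``best_rho`` keeps its sign.
    """
    rho_by_lag, _, _ = lagged_spearman(x, y, lags)
    best_lag = max(rho_by_lag, key=lambda k: (abs(rho_by_lag[k]), -k))
    return rho_by_lag, best_lag, rho_by_lag[best_lag]
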