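"""Shared statistical primitives.

Small closed-form routines used by several analysis modules: the Pearson
correlation p-value via the exact t transform, and a vectorised two-sided
one-sample t test with explicit handling of zero-variance degeneracies.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

#: Smallest representable positive p-value used for zero-variance,
#: nonzero-mean degeneracies.
MIN_P = float(np.nextafter(0.0, 1.0))


def pearson_r_p(x, y) -> tuple[float, float]:
    """Pearson correlation with its two-sided p-value.

    The p-value comes from the exact transform ``t = r * sqrt((n-2)/(1-r^2))``
    referred to a t distribution with ``n - 2`` degrees of freedom.

    Returns ``(nan, nan)`` when fewer than 3 paired observations remain or
    either vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = x.size
    if n < 3 or np.std(x) == 0.0 or np.std(y) == 0.0:
        return float("nan"), float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    return r, pearson_p_from_r(r, n)


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-sided p for a Pearson coefficient ``r`` computed on ``n`` pairs."""
    if n < 3:
        raise ValueError("Pearson p-value requires n >= 3")
    if abs(r) >= 1.0:
        return MIN_P
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def one_sample_t_pvalues(values: np.ndarray, warn_degenerate: bool = True) -> np.ndarray:
    """Row-wise two-sided one-sample t test of mean 0.

    Parameters
    ----------
    values
        2-D array, one row per feature, columns are replicate-level
        observations. NaNs are not allowed.

    Degenerate rows (zero variance) get p = 1 when the mean is also 0 and
    the smallest positive float (with a warning) when it is not: a constant
    nonzero shift is unambiguous evidence against the null but carries no
    variance estimate.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a 2-D array of replicate-level values")
    n = values.shape[1]
    if n < 2:
        raise ValueError("need at least 2 replicate-level values per feature")
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    p = np.ones(values.shape[0])
    ok = sd > 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean[ok] / (sd[ok] / np.sqrt(n))
    p[ok] = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    degenerate = (~ok) & (mean != 0.0)
    if degenerate.any():
        if warn_degenerate:
            warnings.warn(
                f"{int(degenerate.sum())} feature(s) with zero variance and "
                "nonzero mean; p set to smallest positive float",
                stacklevel=2,
            )
        p[degenerate] = MIN_P
    return np.clip(p, MIN_P, 1.0)
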