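"""Sample moment estimators.

Raw moments (means of powers), central moments, skewness and excess
kurtosis, plus the raw-to-central transformations the moment-vector test
relies on.

Conventions
-----------
Skewness and kurtosis use the plain moment ("g-type") definitions, i.e.
central moments with divisor ``n`` (not ``n - 1``) and no small-sample
bias factors.  Under normality these estimators are asymptotically
normal with variances ``6/n`` (skewness) and ``24/n`` (excess kurtosis),
which is the calibration the downstream test assumes.  The classical
pooled-variance baselines use the conventional ``n - 1`` divisor; that
choice is documented in :mod:`swangtest.baselines`.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "UndefinedMomentError",
    "raw_moment",
    "central_moment",
    "central_from_raw",
    "sample_skewness",
    "sample_kurtosis",
    "moment_vector",
]


class UndefinedMomentError(ValueError):
    """A moment estimate does not exist (empty sample or zero variance)."""

    def __init__(self, message: str, gene_id: str | None = None):
        if gene_id is not None:
            message = f"{message} (gene {gene_id!r})"
        super().__init__(message)
        self.gene_id = gene_id


def _as_clean_array(values, min_len: int = 1, gene_id: str | None = None) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise UndefinedMomentError("expected a 1-D sample vector", gene_id)
    if x.size < min_len:
        raise UndefinedMomentError(
            f"sample of length {x.size} is too short (need >= {min_len})", gene_id
        )
    if not np.all(np.isfinite(x)):
        raise UndefinedMomentError("sample contains non-finite values", gene_id)
    return x


def raw_moment(values, r: int, gene_id: str | None = None) -> float:
    """Sample raw moment of order ``r``: mean of the r-th powers.

    ``raw_moment(x, 1)`` is the sample mean; ``raw_moment(x, 0)`` is 1.
    """
    if r < 0 or int(r) != r:
        raise ValueError(f"moment order must be a nonnegative integer, got {r}")
    x = _as_clean_array(values, 1, gene_id)
    return float(np.mean(x ** int(r)))


def central_moment(values, r: int, gene_id: str | None = None) -> float:
    """Sample central moment of order ``r`` with divisor ``n``."""
    if r < 0 or int(r) != r:
        raise ValueError(f"moment order must be a nonnegative integer, got {r}")
    x = _as_clean_array(values, 1, gene_id)
    return float(np.mean((x - x.mean()) ** int(r)))


def central_from_raw(raw: "list[float] | np.ndarray") -> np.ndarray:
    """Central moments 1..k from raw moments 1..k (k <= 4).

    Input is ``[mu'_1, mu'_2, ...]``; output ``[0, m_2, m_3, m_4][:k]``
    using the standard binomial expansion about the mean.
    """
    mu = np.asarray(raw, dtype=float)
    k = mu.size
    if k < 1 or k > 4:
        raise ValueError("central_from_raw supports orders 1 through 4")
    out = np.zeros(k)
    if k >= 2:
        out[1] = mu[1] - mu[0] ** 2
    if k >= 3:
        out[2] = mu[2] - 3.0 * mu[0] * mu[1] + 2.0 * mu[0] ** 3
    if k >= 4:
        out[3] = mu[3] - 4.0 * mu[0] * mu[2] + 6.0 * mu[0] ** 2 * mu[1] - 3.0 * mu[0] ** 4
    return out


def sample_skewness(values, gene_id: str | None = None) -> float:
    """Standardized third central moment m3 / m2**1.5 (moment definition)."""
    x = _as_clean_array(values, 3, gene_id)
    d = x - x.mean()
    m2 = np.mean(d ** 2)
    if m2 <= 0.0:
        raise UndefinedMomentError("zero variance: skewness undefined", gene_id)
    m3 = np.mean(d ** 3)
    return float(m3 / m2 ** 1.5)


def sample_kurtosis(values, gene_id: str | None = None) -> float:
    """Excess kurtosis m4 / m2**2 - 3 (moment definition)."""
    x = _as_clean_array(values, 4, gene_id)
    d = x - x.mean()
    m2 = np.mean(d ** 2)
    if m2 <= 0.0:
        raise UndefinedMomentError("zero variance: kurtosis undefined", gene_id)
    m4 = np.mean(d ** 4)
    return float(m4 / m2 ** 2 - 3.0)


def moment_vector(values, orders, gene_id: str | None = None) -> np.ndarray:
    """Vector of raw moments for each order, in the order given.

    ``orders`` may be any iterable of nonnegative integer orders; the
    design objects in :mod:`swangtest.core` supply them ascending.
    """
    x = _as_clean_array(values, 1, gene_id)
    orders = tuple(int(r) for r in orders)
    return np.array([np.mean(x ** r) for r in orders], dtype=float)
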