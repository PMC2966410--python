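"""The SWang(h, k) moment-vector test.

Two samples are compared through their vectors of raw moments.  For a
design with orders r_1 < ... < r_d, each observation x_j contributes the
power column (x_j**r_1, ..., x_j**r_d); the per-group mean columns are
the sample raw-moment vectors.  The null hypothesis is that the
population raw moments of the two groups agree for every order in the
design, which (for orders 1..4 on a Pearson-family distribution) is
equivalent to equality of mean, variance, skewness and kurtosis.

The statistic is the two-sample Hotelling quadratic form on the moment
vectors, with the pooled scatter inverted by a Moore-Penrose
pseudo-inverse because the scatter can be singular at small sample
sizes.  Scaled by (n + m - d - 1) / ((n + m - 2) d) it is calibrated
against an F distribution with (d, n + m - d - 1) degrees of freedom.
With the single order (1,) the statistic is exactly the square of the
pooled two-sample t statistic.

Sample-size validity rule: n + m must exceed d + 1 (so the second F
degree of freedom is at least 1) and each group must have at least 2
samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .moments import UndefinedMomentError

__all__ = [
    "MomentDesign",
    "SwangResult",
    "InvalidDesignError",
    "power_matrix",
    "deviation_matrix",
    "generalized_inverse",
    "swang_pvalue",
    "swang_statistic",
    "swang_statistic_stack",
    "run_swang",
]

#: Recommended cap on the highest moment order: the Pearson family is
#: characterised by its first four moments, and higher orders are
#: unstable at microarray-scale sample sizes.
DEFAULT_MAX_ORDER = 4

SIZE_RULE = (
    "the sum of sample sizes from both case and control must be greater "
    "than k+1 and each group must have at least 2 samples"
)


class InvalidDesignError(ValueError):
    """Moment design incompatible with the data (size rule or orders)."""


@dataclass(frozen=True)
class MomentDesign:
    """The set of raw-moment orders a test uses.

    ``MomentDesign.from_range(1, 4)`` is the recommended default
    (orders 1,2,3,4); explicit non-contiguous sets such as (1, 3, 5)
    are allowed via ``MomentDesign((1, 3, 5), max_order=5)``.
    """

    orders: tuple[int, ...] = (1, 2, 3, 4)
    max_order: int = DEFAULT_MAX_ORDER

    def __post_init__(self):
        orders = tuple(int(r) for r in self.orders)
        object.__setattr__(self, "orders", orders)
        if len(orders) == 0:
            raise InvalidDesignError("design needs at least one moment order")
        if any(r < 1 for r in orders):
            raise InvalidDesignError("moment orders must be >= 1")
        if any(b <= a for a, b in zip(orders, orders[1:])):
            raise InvalidDesignError("moment orders must be strictly increasing")
        if max(orders) > self.max_order:
            raise InvalidDesignError(
                f"order {max(orders)} exceeds the cap {self.max_order}; "
                "raise max_order explicitly to use higher moments"
            )

    @classmethod
    def from_range(cls, h: int, k: int) -> "MomentDesign":
        """SWang(h, k): contiguous orders h..k."""
        if h < 1 or k < h:
            raise InvalidDesignError(f"invalid moment range ({h}, {k})")
        return cls(tuple(range(h, k + 1)), max_order=max(k, DEFAULT_MAX_ORDER))

    @property
    def k_dim(self) -> int:
        """Dimension of the test (number of orders)."""
        return len(self.orders)

    @property
    def highest(self) -> int:
        return self.orders[-1]

    @property
    def is_contiguous_from_one(self) -> bool:
        """True for designs 1..k, where joint affine preconditioning is exact."""
        return self.orders == tuple(range(1, len(self.orders) + 1))

    def __str__(self) -> str:
        if self.orders == tuple(range(self.orders[0], self.orders[-1] + 1)):
            return f"SWang({self.orders[0]},{self.orders[-1]})"
        return f"SWang(({','.join(map(str, self.orders))}))"


@dataclass
class SwangResult:
    statistic: float
    df1: int
    df2: int
    p_value: float
    flag: str | None = None
    design: MomentDesign = field(default_factory=MomentDesign)


def power_matrix(values, design: MomentDesign, gene_id: str | None = None) -> np.ndarray:
    """Matrix of powers: row r holds each sample value raised to orders[r]."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise UndefinedMomentError("empty sample", gene_id)
    with np.errstate(over="ignore"):
        P = np.vstack([x ** r for r in design.orders])
    if not np.all(np.isfinite(P)):
        raise UndefinedMomentError(
            "power matrix overflowed to non-finite values", gene_id
        )
    return P


def deviation_matrix(P: np.ndarray) -> np.ndarray:
    """Scatter matrix of a power matrix: sums of cross-products of
    row-wise deviations from the row means (not divided by sample size)."""
    P = np.atleast_2d(np.asarray(P, dtype=float))
    if P.shape[1] < 2:
        raise ValueError("deviation matrix needs at least 2 samples")
    D = P - P.mean(axis=1, keepdims=True)
    return D @ D.T


def generalized_inverse(M: np.ndarray, rcond: float | None = None) -> np.ndarray:
    """Moore-Penrose pseudo-inverse with the standard singular-value cutoff.

    Agrees with the true inverse for nonsingular input; singular values
    below ``rcond * largest`` (default: dim * machine epsilon) are
    truncated.
    """
    M = np.asarray(M, dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValueError("matrix contains non-finite entries")
    if rcond is None:
        rcond = max(M.shape) * np.finfo(float).eps
    return np.linalg.pinv(M, rcond=rcond)


def swang_pvalue(statistic: float, n: int, m: int, k_dim: int) -> float:
    """Upper-tail F(k_dim, n+m-k_dim-1) probability of the statistic."""
    df2 = n + m - k_dim - 1
    if df2 < 1:
        raise InvalidDesignError(
            f"n+m-k-1 = {df2} < 1 for n={n}, m={m}, k={k_dim}: {SIZE_RULE}"
        )
    return float(stats.f.sf(statistic, k_dim, df2))


def _check_sizes(n: int, m: int, k_dim: int) -> None:
    if n < 2 or m < 2 or n + m <= k_dim + 1:
        raise InvalidDesignError(
            f"invalid sizes n={n}, m={m} for a {k_dim}-moment design: {SIZE_RULE}"
        )


def _precondition(x: np.ndarray, y: np.ndarray):
    """Jointly center and scale both groups by the pooled mean and SD.

    For contiguous designs 1..k the statistic is exactly invariant under
    this map (the power vectors transform by a common invertible
    triangular map), so it is a pure conditioning step: log2 intensities
    raised to the 4th power otherwise produce badly scaled scatter.
    """
    pooled = np.concatenate([x, y])
    mu = pooled.mean()
    sd = pooled.std()
    if sd <= 0.0:
        return x - mu, y - mu, True
    return (x - mu) / sd, (y - mu) / sd, False


# Internal knob: the classic two-sample Hotelling weight n*m/(n+m) and
# pooled divisor n+m-2.  Exposed so the pooling convention can be
# reconciled against external worked examples without code changes.
def _hotelling_tsq(xbar, ybar, D1, D2, n, m, *, inverse="pinv", pooled_divisor=None):
    diff = xbar - ybar
    if pooled_divisor is None:
        pooled_divisor = n + m - 2
    S = (D1 + D2) / pooled_divisor
    if inverse == "pinv":
        quad = diff @ generalized_inverse(S) @ diff
    elif inverse == "solve":
        quad = diff @ np.linalg.solve(S, diff)
    else:
        raise ValueError(f"unknown inverse mode {inverse!r}")
    return (n * m / (n + m)) * quad, S


def swang_statistic(
    x,
    y,
    design: MomentDesign | tuple = (1, 4),
    *,
    precondition: bool | None = None,
    inverse: str = "pinv",
    gene_id: str | None = None,
) -> SwangResult:
    """SWang test of one case sample ``x`` against one control sample ``y``.

    Parameters
    ----------
    x, y : array-like
        Case and control log2 expression values.
    design : MomentDesign or (h, k) tuple
        Moment orders; an ``(h, k)`` pair expands to the range h..k.
    precondition : bool, optional
        Joint center/scale before raising to powers.  Default: on for
        contiguous designs 1..k (where it provably leaves the statistic
        unchanged), off otherwise.
    inverse : {"pinv", "solve"}
        Pseudo-inverse (default, handles singular scatter) or a direct
        linear solve (oracle path, requires nonsingular scatter).
    """
    if not isinstance(design, MomentDesign):
        design = MomentDesign.from_range(*design)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    k = design.k_dim
    _check_sizes(n, m, k)
    df2 = n + m - k - 1

    if precondition is None:
        precondition = design.is_contiguous_from_one
    flag = None
    if precondition:
        x, y, degenerate = _precondition(x, y)
        if degenerate:
            # both groups constant at the same value: no evidence at all
            return SwangResult(0.0, k, df2, 1.0, "degenerate_zero_variance", design)

    X = power_matrix(x, design, gene_id)
    Y = power_matrix(y, design, gene_id)
    xbar = X.mean(axis=1)
    ybar = Y.mean(axis=1)
    D1 = deviation_matrix(X)
    D2 = deviation_matrix(Y)

    if np.allclose(xbar, ybar) and np.allclose(D1 + D2, 0.0):
        return SwangResult(0.0, k, df2, 1.0, "degenerate_zero_scatter", design)

    tsq, S = _hotelling_tsq(xbar, ybar, D1, D2, n, m, inverse=inverse)
    if np.allclose(S, 0.0):
        flag = "degenerate_zero_scatter"
    statistic = float((df2 / ((n + m - 2) * k)) * tsq)
    statistic = max(statistic, 0.0)
    return SwangResult(statistic, k, df2, swang_pvalue(statistic, n, m, k), flag, design)


def swang_statistic_stack(
    X: np.ndarray,
    Y: np.ndarray,
    design: MomentDesign | tuple = (1, 4),
    *,
    precondition: bool | None = None,
):
    """Vectorized SWang over a stack of genes.

    ``X`` is (genes, n) case values, ``Y`` (genes, m) control values.
    Returns ``(statistic, p_value, flags)`` arrays of length genes.
    Genes whose pooled scatter is (numerically) zero are reported with
    statistic 0 and p 1 rather than aborting the run.
    """
    if not isinstance(design, MomentDesign):
        design = MomentDesign.from_range(*design)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    G, n = X.shape
    G2, m = Y.shape
    if G != G2:
        raise ValueError("case and control stacks disagree on gene count")
    k = design.k_dim
    _check_sizes(n, m, k)
    df2 = n + m - k - 1

    if precondition is None:
        precondition = design.is_contiguous_from_one
    flags = np.zeros(G, dtype=bool)
    if precondition:
        pooled = np.concatenate([X, Y], axis=1)
        mu = pooled.mean(axis=1, keepdims=True)
        sd = pooled.std(axis=1, keepdims=True)
        zero = sd[:, 0] <= 0.0
        flags |= zero
        sd[zero] = 1.0
        X = (X - mu) / sd
        Y = (Y - mu) / sd

    orders = np.array(design.orders)
    PX = X[:, None, :] ** orders[None, :, None]  # (G, k, n)
    PY = Y[:, None, :] ** orders[None, :, None]
    xbar = PX.mean(axis=2)
    ybar = PY.mean(axis=2)
    DX = PX - xbar[:, :, None]
    DY = PY - ybar[:, :, None]
    D1 = np.einsum("gik,gjk->gij", DX, DX)
    D2 = np.einsum("gik,gjk->gij", DY, DY)
    S = (D1 + D2) / (n + m - 2)

    diff = xbar - ybar
    scatter_scale = np.abs(S).max(axis=(1, 2))
    zero_scatter = scatter_scale <= 0.0
    flags |= zero_scatter

    Sinv = np.linalg.pinv(S, rcond=k * np.finfo(float).eps)
    quad = np.einsum("gi,gij,gj->g", diff, Sinv, diff)
    tsq = (n * m / (n + m)) * quad
    statistic = np.maximum((df2 / ((n + m - 2) * k)) * tsq, 0.0)
    statistic[zero_scatter] = 0.0
    p = stats.f.sf(statistic, k, df2)
    p[zero_scatter] = 1.0
    return statistic, p, flags


def run_swang(
    matrix,
    design: MomentDesign | tuple = (1, 4),
    alpha: float = 0.05,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Apply the SWang test to every gene of an expression matrix.

    Parameters
    ----------
    matrix : swangtest.io.ExpressionMatrix
        Genes x samples log2 values with case/control labels.
    design : MomentDesign or (h, k)
    alpha : float
        Significance cutoff for the ``call`` column (raw p by default,
        mirroring common practice of filtering at raw p <= 0.05).
    adjust : {"bh", None}
        Optional Benjamini-Hochberg adjusted p column; the call column
        uses adjusted p when adjustment is requested.

    Returns
    -------
    DataFrame with columns gene_id, statistic, df1, df2, p_value,
    [adj_p,] call, flag.
    """
    if not isinstance(design, MomentDesign):
        design = MomentDesign.from_range(*design)
    X, Y = matrix.group_arrays()
    statistic, p, flags = swang_statistic_stack(X, Y, design)
    out = pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "statistic": statistic,
            "df1": design.k_dim,
            "df2": X.shape[1] + Y.shape[1] - design.k_dim - 1,
            "p_value": p,
        }
    )
    pcol = "p_value"
    if adjust == "bh":
        out["adj_p"] = stats.false_discovery_control(p, method="bh")
        pcol = "adj_p"
    elif adjust not in (None, "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    out["call"] = out[pcol] <= alpha
    out["flag"] = np.where(flags, "degenerate", "")
    return out
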