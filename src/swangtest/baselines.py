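"""Classical comparison methods: pooled t-test, variance-ratio F-test,
SAM with offset s0, and log2 fold-change.

The t-test is the pooled (equal-variance) form, because the one-moment
version of the moment-vector test equals its square only under that
convention.  Pooled variances here use the conventional n-1 divisor;
the moment estimators in :mod:`swangtest.moments` use divisor n.

SAM's score is d = (mean(x) - mean(y)) / (s + s0) where s is the pooled
standard error of the mean difference and s0 is the "fudge" offset
(default 0.3) that tames genes with tiny variance.  Its p-value comes
from label permutation: exhaustive when C(n+m, n) <= 20,000, otherwise
a seeded random sample of relabellings.

Fold-change is the difference of group means on the log2 scale, called
at |difference| >= 1 (a 2-fold change).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BaselineResult",
    "t_test",
    "f_test",
    "sam_statistic",
    "fold_change",
    "run_baselines",
    "t_test_stack",
    "f_test_stack",
    "sam_stack",
    "fold_change_stack",
]

EXHAUSTIVE_LIMIT = 20_000
FOLD_CHANGE_THRESHOLD = 1.0  # log2 scale: 2-fold


@dataclass
class BaselineResult:
    method: str
    score: float
    p_value: float | None
    call: bool
    flag: str | None = None


def _arrays(x, y, min_len=2):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < min_len or y.size < min_len:
        raise ValueError(f"both groups need at least {min_len} samples")
    return x, y


def _pooled_se(x, y):
    """Pooled standard error of the mean difference (n-1 variances)."""
    n, m = x.size, y.size
    sp2 = ((n - 1) * x.var(ddof=1) + (m - 1) * y.var(ddof=1)) / (n + m - 2)
    return np.sqrt(sp2 * (1.0 / n + 1.0 / m))


def t_test(x, y, alpha: float = 0.05) -> BaselineResult:
    """Pooled two-sample t with two-sided p on n+m-2 df."""
    x, y = _arrays(x, y)
    se = _pooled_se(x, y)
    if se <= 0.0:
        equal = np.isclose(x.mean(), y.mean())
        return BaselineResult("t", 0.0 if equal else np.inf,
                              1.0 if equal else 0.0, not equal,
                              "degenerate_zero_variance")
    t = (x.mean() - y.mean()) / se
    p = 2.0 * stats.t.sf(abs(t), x.size + y.size - 2)
    return BaselineResult("t", float(t), float(p), p <= alpha)


def f_test(x, y, alpha: float = 0.05) -> BaselineResult:
    """Variance ratio s_x^2 / s_y^2 with two-sided F(n-1, m-1) p."""
    x, y = _arrays(x, y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vy <= 0.0:
        return BaselineResult("f", np.inf, 0.0 if vx > 0 else 1.0, vx > 0,
                              "degenerate_zero_variance")
    ratio = vx / vy
    dist = stats.f(x.size - 1, y.size - 1)
    p = 2.0 * min(dist.sf(ratio), dist.cdf(ratio))
    return BaselineResult("f", float(ratio), float(min(p, 1.0)), p <= alpha)


def sam_statistic(
    x,
    y,
    s0: float = 0.3,
    *,
    n_permutations: int = 1000,
    seed: int | np.random.Generator | None = 0,
    alpha: float = 0.05,
) -> BaselineResult:
    """SAM score with permutation p-value.

    Exhaustive enumeration of label splits when the total count is at
    most 20,000 (then p = fraction of splits with |d| >= |observed|);
    otherwise ``n_permutations`` seeded random relabellings with the
    (1 + c) / (1 + B) convention.
    """
    x, y = _arrays(x, y)
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])

    def d_of(xs, ys):
        se = _pooled_se(xs, ys)
        return (xs.mean() - ys.mean()) / (se + s0)

    d_obs = d_of(x, y)
    total = comb(n + m, n)
    if total <= EXHAUSTIVE_LIMIT:
        idx = np.arange(n + m)
        count = 0
        for case_idx in combinations(idx, n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(case_idx)] = True
            if abs(d_of(pooled[mask], pooled[~mask])) >= abs(d_obs) - 1e-12:
                count += 1
        p = count / total
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            if abs(d_of(perm[:n], perm[n:])) >= abs(d_obs) - 1e-12:
                count += 1
        p = (1 + count) / (1 + n_permutations)
    return BaselineResult(f"sam({s0:g})", float(d_obs), float(p), p <= alpha)


def fold_change(x, y) -> BaselineResult:
    """Difference of group means on the log2 scale; call at 2-fold."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    fc = float(x.mean() - y.mean())
    return BaselineResult("fc", fc, None, abs(fc) >= FOLD_CHANGE_THRESHOLD)


# ---------------------------------------------------------------------------
# Vectorized versions over gene stacks (G, n) / (G, m), used by the
# simulation engine and the genome-wide runner.
# ---------------------------------------------------------------------------

def _pooled_se_stack(X, Y):
    n, m = X.shape[1], Y.shape[1]
    sp2 = ((n - 1) * X.var(axis=1, ddof=1) + (m - 1) * Y.var(axis=1, ddof=1)) / (n + m - 2)
    return np.sqrt(sp2 * (1.0 / n + 1.0 / m))


def t_test_stack(X, Y):
    n, m = X.shape[1], Y.shape[1]
    se = _pooled_se_stack(X, Y)
    diff = X.mean(axis=1) - Y.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    zero = se <= 0.0
    t[zero] = np.where(np.isclose(diff[zero], 0.0), 0.0, np.inf)
    p = 2.0 * stats.t.sf(np.abs(t), n + m - 2)
    return t, p


def f_test_stack(X, Y):
    n, m = X.shape[1], Y.shape[1]
    vx = X.var(axis=1, ddof=1)
    vy = Y.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = vx / vy
    ratio[vy <= 0.0] = np.inf
    dist = stats.f(n - 1, m - 1)
    p = np.minimum(2.0 * np.minimum(dist.sf(ratio), dist.cdf(ratio)), 1.0)
    p[(vy <= 0.0) & (vx <= 0.0)] = 1.0
    return ratio, p


def sam_stack(X, Y, s0: float = 0.3, *, n_permutations: int = 1000, rng=None):
    """Vectorized SAM scores and permutation p-values for a gene stack.

    One set of label permutations is shared across all genes (standard
    practice and what keeps genome-wide runs tractable).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    X = np.atleast_2d(X)
    Y = np.atleast_2d(Y)
    n, m = X.shape[1], Y.shape[1]
    pooled = np.concatenate([X, Y], axis=1)  # (G, n+m)
    d_obs = (X.mean(axis=1) - Y.mean(axis=1)) / (_pooled_se_stack(X, Y) + s0)

    total = comb(n + m, n)
    if total <= EXHAUSTIVE_LIMIT:
        masks = np.zeros((total, n + m), dtype=bool)
        for i, case_idx in enumerate(combinations(range(n + m), n)):
            masks[i, list(case_idx)] = True
        random_perms = False
    else:
        masks = np.zeros((n_permutations, n + m), dtype=bool)
        for i in range(n_permutations):
            masks[i, rng.choice(n + m, size=n, replace=False)] = True
        random_perms = True

    W = masks.astype(float)
    sums = pooled @ W.T                      # (G, P) case sums
    sq = (pooled ** 2) @ W.T
    tot = pooled.sum(axis=1, keepdims=True)
    tot_sq = (pooled ** 2).sum(axis=1, keepdims=True)
    mean_x = sums / n
    mean_y = (tot - sums) / m
    ssx = sq - n * mean_x ** 2
    ssy = (tot_sq - sq) - m * mean_y ** 2
    sp2 = (ssx + ssy) / (n + m - 2)
    se = np.sqrt(np.maximum(sp2, 0.0) * (1.0 / n + 1.0 / m))
    d_perm = (mean_x - mean_y) / (se + s0)

    exceed = (np.abs(d_perm) >= np.abs(d_obs)[:, None] - 1e-12).sum(axis=1)
    if random_perms:
        p = (1 + exceed) / (1 + masks.shape[0])
    else:
        p = exceed / total
    return d_obs, p


def fold_change_stack(X, Y):
    fc = X.mean(axis=1) - Y.mean(axis=1)
    return fc, np.abs(fc) >= FOLD_CHANGE_THRESHOLD


def run_baselines(
    matrix,
    s0: float = 0.3,
    alpha: float = 0.05,
    *,
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """All four baselines on every gene; long-format result table."""
    X, Y = matrix.group_arrays()
    t, pt = t_test_stack(X, Y)
    f, pf = f_test_stack(X, Y)
    d, psam = sam_stack(X, Y, s0, n_permutations=n_permutations,
                        rng=np.random.default_rng(seed))
    fc, fc_call = fold_change_stack(X, Y)
    frames = []
    for method, score, p, call in [
        ("t", t, pt, pt <= alpha),
        ("f", f, pf, pf <= alpha),
        (f"sam({s0:g})", d, psam, psam <= alpha),
        ("fc", fc, np.full(len(fc), np.nan), fc_call),
    ]:
        frames.append(pd.DataFrame({
            "gene_id": matrix.gene_ids,
            "method": method,
            "score": score,
            "p_value": p,
            "call": call,
        }))
    return pd.concat(frames, ignore_index=True)
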