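"""False-positive-rate and power simulations for the five methods.

Two study designs:

* **Null / FPR**: case and control drawn from the same distribution; the
  empirical false positive rate at each p-value cutoff is the fraction
  of (truly null) genes called significant.  A calibrated test's curve
  lies on the diagonal; a conservative one below it.
* **Power**: a fraction of genes (default 20%) are true DEGs whose case
  group follows a different distribution; power is the fraction of true
  DEGs called at p <= 0.05 (fold-change at 2-fold).  Curves are keyed by
  size = n * m, the product of the group sample sizes.

Distributions cover the Pearson family and mixtures: normal,
(shiftable) exponential, uniform, Cauchy, gamma, triangular, plus an
equal-weight "complex" mixture of triangular, normal and exponential
components and a two-component normal mixture.  The control default is
normal(mean 1, sd 1.5).  Cauchy has no moments; sample moments are
still computed and only relative comparisons are meaningful there.

Everything is driven by a single integer seed and fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .baselines import (
    f_test_stack,
    fold_change_stack,
    sam_stack,
    t_test_stack,
)
from .core import MomentDesign, swang_statistic_stack

__all__ = [
    "DistributionSpec",
    "SimulationConfig",
    "CurveTable",
    "draw_group",
    "simulate_fpr",
    "simulate_power",
    "write_curves",
    "read_curves",
    "plot_curves",
]

DEFAULT_CUTOFFS = tuple(np.round(np.arange(0.01, 0.101, 0.01), 3))


@dataclass(frozen=True)
class DistributionSpec:
    """A sampling distribution for one group.

    ``family`` is one of normal, exponential, uniform, cauchy, gamma,
    triangular, mixture; ``params`` are family-specific.  Mixtures carry
    component specs and weights summing to 1.
    """

    family: str
    params: tuple[tuple[str, float], ...] = ()
    components: tuple["DistributionSpec", ...] = ()
    weights: tuple[float, ...] = ()

    def __post_init__(self):
        if self.family == "mixture":
            if not self.components:
                raise ValueError("mixture needs components")
            if len(self.weights) != len(self.components):
                raise ValueError("one weight per mixture component")
            if not np.isclose(sum(self.weights), 1.0):
                raise ValueError("mixture weights must sum to 1")
        elif self.family not in _FAMILIES:
            raise ValueError(f"unknown distribution family {self.family!r}")

    @property
    def p(self) -> dict[str, float]:
        return dict(self.params)

    # -- constructors -------------------------------------------------
    @classmethod
    def normal(cls, mean: float = 1.0, sd: float = 1.5) -> "DistributionSpec":
        """Default control distribution: normal(1, 1.5)."""
        return cls("normal", (("mean", mean), ("sd", sd)))

    @classmethod
    def exponential(cls, scale: float = 1.0, loc: float = 0.0) -> "DistributionSpec":
        return cls("exponential", (("scale", scale), ("loc", loc)))

    @classmethod
    def exponential_matched(cls, mean: float = 1.0, sd: float = 1.5) -> "DistributionSpec":
        """Location-shifted exponential with the given mean and sd.

        Matches the first two moments of a normal control so that only
        skewness/kurtosis carry signal (an exponential has skewness 2,
        excess kurtosis 6, whatever its scale).
        """
        return cls.exponential(scale=sd, loc=mean - sd)

    @classmethod
    def uniform(cls, low: float = 0.0, high: float = 1.0) -> "DistributionSpec":
        return cls("uniform", (("low", low), ("high", high)))

    @classmethod
    def cauchy(cls, loc: float = 0.0, scale: float = 1.0) -> "DistributionSpec":
        return cls("cauchy", (("loc", loc), ("scale", scale)))

    @classmethod
    def gamma(cls, shape: float = 2.0, scale: float = 1.0, loc: float = 0.0) -> "DistributionSpec":
        return cls("gamma", (("shape", shape), ("scale", scale), ("loc", loc)))

    @classmethod
    def triangular(cls, left: float = 0.0, mode: float = 1.0, right: float = 2.0) -> "DistributionSpec":
        return cls("triangular", (("left", left), ("mode", mode), ("right", right)))

    @classmethod
    def mixture(cls, components, weights) -> "DistributionSpec":
        return cls("mixture", (), tuple(components), tuple(float(w) for w in weights))

    @classmethod
    def complex_mixture(cls) -> "DistributionSpec":
        """Equal-weight triangular(0,1,2) + normal(1,1.5) + exponential(1)."""
        return cls.mixture(
            [cls.triangular(0, 1, 2), cls.normal(1, 1.5), cls.exponential(1.0)],
            [1 / 3, 1 / 3, 1 / 3],
        )

    @classmethod
    def normal_mixture(cls) -> "DistributionSpec":
        """0.5 N(0,1) + 0.5 N(3,1)."""
        return cls.mixture([cls.normal(0, 1), cls.normal(3, 1)], [0.5, 0.5])

    def sample(self, size, rng: np.random.Generator) -> np.ndarray:
        """i.i.d. draws of the given shape (int or tuple)."""
        if self.family == "mixture":
            size_t = (size,) if np.isscalar(size) else tuple(size)
            choice = rng.choice(len(self.components), size=size_t, p=self.weights)
            out = np.empty(size_t)
            for i, comp in enumerate(self.components):
                mask = choice == i
                out[mask] = comp.sample(int(mask.sum()), rng)
            return out
        return _FAMILIES[self.family](self.p, size, rng)

    def label(self) -> str:
        if self.family == "mixture":
            return "mixture(" + "+".join(c.label() for c in self.components) + ")"
        inner = ",".join(f"{v:g}" for _, v in self.params)
        return f"{self.family}({inner})"


_FAMILIES = {
    "normal": lambda p, size, rng: rng.normal(p["mean"], p["sd"], size),
    "exponential": lambda p, size, rng: p.get("loc", 0.0) + rng.exponential(p["scale"], size),
    "uniform": lambda p, size, rng: rng.uniform(p["low"], p["high"], size),
    "cauchy": lambda p, size, rng: p["loc"] + p["scale"] * rng.standard_cauchy(size),
    "gamma": lambda p, size, rng: p.get("loc", 0.0) + rng.gamma(p["shape"], p["scale"], size),
    "triangular": lambda p, size, rng: rng.triangular(p["left"], p["mode"], p["right"], size),
}


def draw_group(spec: DistributionSpec, size: int, rng: np.random.Generator) -> np.ndarray:
    """One group's expression values for a single gene."""
    if size < 1:
        raise ValueError("group size must be >= 1")
    return spec.sample(size, rng)


DEFAULT_METHODS = ("swang(1,4)", "t", "f", "sam(0.3)", "fc")


@dataclass
class SimulationConfig:
    case_dist: DistributionSpec = field(default_factory=DistributionSpec.normal)
    control_dist: DistributionSpec = field(default_factory=DistributionSpec.normal)
    n_genes: int = 10_000
    deg_fraction: float = 0.20
    sample_sizes: tuple[tuple[int, int], ...] = ((5, 5),)
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS
    seed: int = 0
    methods: tuple[str, ...] = DEFAULT_METHODS
    s0: float = 0.3
    sam_permutations: int = 1000

    def __post_init__(self):
        if not (0.0 < self.deg_fraction <= 1.0):
            raise ValueError("deg_fraction must be in (0, 1]")
        for n, m in self.sample_sizes:
            if n < 2 or m < 2:
                raise ValueError("each group needs at least 2 samples")
        if not self.methods:
            raise ValueError("at least one method must be selected")
        if any(c <= 0 or c > 1 for c in self.cutoffs):
            raise ValueError("cutoffs must lie in (0, 1]")


#: Result tables are plain DataFrames with these columns.
CurveTable = pd.DataFrame
FPR_COLUMNS = ["method", "n", "m", "cutoff", "fpr", "n_genes", "mc_stderr"]
POWER_COLUMNS = ["method", "n", "m", "size", "power", "n_deg", "mc_stderr"]


def _parse_method(name: str):
    name = name.strip().lower()
    if name.startswith("swang"):
        spec = name[len("swang"):].strip("() ")
        parts = tuple(int(v) for v in spec.split(","))
        if len(parts) == 2 and parts[1] >= parts[0]:
            return ("swang", MomentDesign.from_range(*parts))
        return ("swang", MomentDesign(parts, max_order=max(parts)))
    if name.startswith("sam"):
        spec = name[len("sam"):].strip("() ")
        return ("sam", float(spec) if spec else 0.3)
    if name in ("t", "f", "fc"):
        return (name, None)
    raise ValueError(f"unknown method {name!r}")


def _method_pvalues(method: str, X, Y, cfg: SimulationConfig, rng):
    """p-values (or, for fold-change, the call mask) for one method."""
    kind, arg = _parse_method(method)
    if kind == "swang":
        _, p, _ = swang_statistic_stack(X, Y, arg)
        return p, None
    if kind == "t":
        return t_test_stack(X, Y)[1], None
    if kind == "f":
        return f_test_stack(X, Y)[1], None
    if kind == "sam":
        return sam_stack(X, Y, arg, n_permutations=cfg.sam_permutations, rng=rng)[1], None
    if kind == "fc":
        return None, fold_change_stack(X, Y)[1]
    raise AssertionError(kind)


def _binom_se(p_hat: float, n: int) -> float:
    return float(np.sqrt(max(p_hat * (1 - p_hat), 0.0) / n))


def simulate_fpr(config: SimulationConfig) -> CurveTable:
    """Empirical FPR-vs-cutoff curves under the null.

    Requires ``case_dist == control_dist``; every gene is truly null and
    the FPR at cutoff c is the fraction of genes with p <= c.
    Fold-change has no p-value and is reported once per (n, m) at its
    2-fold operating point with cutoff = NaN.
    """
    if config.case_dist != config.control_dist:
        raise ValueError("FPR simulation requires identical case and control distributions")
    rng = np.random.default_rng(config.seed)
    rows = []
    for n, m in config.sample_sizes:
        X = config.control_dist.sample((config.n_genes, n), rng)
        Y = config.control_dist.sample((config.n_genes, m), rng)
        for method in config.methods:
            p, call = _method_pvalues(method, X, Y, config, rng)
            if p is None:  # fold-change: single operating point
                fpr = float(np.mean(call))
                rows.append((method, n, m, np.nan, fpr, config.n_genes,
                             _binom_se(fpr, config.n_genes)))
                continue
            for c in config.cutoffs:
                fpr = float(np.mean(p <= c))
                rows.append((method, n, m, c, fpr, config.n_genes,
                             _binom_se(fpr, config.n_genes)))
    return pd.DataFrame(rows, columns=FPR_COLUMNS)


def simulate_power(config: SimulationConfig, alpha: float = 0.05) -> CurveTable:
    """Empirical power per method across the sample-size grid.

    A ``deg_fraction`` of genes draw their case group from ``case_dist``
    (true DEGs); the rest are null.  Power is the fraction of true DEGs
    with p <= alpha (fold-change: 2-fold call); curves are keyed by
    size = n * m.
    """
    if config.case_dist == config.control_dist:
        raise ValueError("power simulation requires case_dist != control_dist")
    rng = np.random.default_rng(config.seed)
    n_deg = max(int(round(config.deg_fraction * config.n_genes)), 1)
    rows = []
    for n, m in config.sample_sizes:
        # first n_deg genes are the true DEGs; order carries no information
        X = np.empty((config.n_genes, n))
        X[:n_deg] = config.case_dist.sample((n_deg, n), rng)
        X[n_deg:] = config.control_dist.sample((config.n_genes - n_deg, n), rng)
        Y = config.control_dist.sample((config.n_genes, m), rng)
        for method in config.methods:
            p, call = _method_pvalues(method, X, Y, config, rng)
            called = call[:n_deg] if p is None else (p[:n_deg] <= alpha)
            power = float(np.mean(called))
            rows.append((method, n, m, n * m, power, n_deg, _binom_se(power, n_deg)))
    return pd.DataFrame(rows, columns=POWER_COLUMNS)


def write_curves(table: CurveTable, path: str | Path, *, provenance: str | None = None) -> None:
    """CSV serialization of a curve table (byte-stable under fixed seed)."""
    if table.empty:
        raise ValueError("refusing to write an empty curve table")
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        table.to_csv(fh, index=False, float_format="%.10g")


def read_curves(path: str | Path) -> CurveTable:
    return pd.read_csv(path, comment="#")


def plot_curves(table: CurveTable, path: str | Path, *, kind: str = "fpr") -> None:
    """One line per method: FPR vs cutoff (with the diagonal reference)
    or power vs size = n * m."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    if kind == "fpr":
        sub = table.dropna(subset=["cutoff"])
        for method, grp in sub.groupby("method"):
            g = grp.sort_values("cutoff")
            ax.plot(g["cutoff"], g["fpr"], marker="o", label=method)
        hi = float(sub["cutoff"].max())
        ax.plot([0.0, hi], [0.0, hi], "k--", lw=1, label="diagonal")
        ax.set_xlabel("p-value cutoff")
        ax.set_ylabel("empirical false positive rate")
    elif kind == "power":
        for method, grp in table.groupby("method"):
            g = grp.sort_values("size")
            ax.plot(g["size"], g["power"], marker="o", label=method)
        ax.set_xlabel("size (n_case x n_control)")
        ax.set_ylabel("empirical power")
    else:
        raise ValueError(f"unknown plot kind {kind!r}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
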