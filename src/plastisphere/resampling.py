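"""Resampling statistics for small physicochemical samples.

Replicate counts in bead-characterisation experiments are tiny (3-6 per
cell), so parametric tests are avoided in favour of:

* a two-sample bootstrap difference-of-means test (10 000 resamples,
  percentile 95% CI; significant when the CI excludes zero),
* the classical F-test for equality of variances,
* Monte-Carlo pairing: variables measured on *different* beads are
  paired by simulating normal draws from each cell's (mean, sd) and
  pairing by draw index, then
* a bootstrap Pearson correlation (row resampling, percentile CI) on
  the paired table, and Spearman's rho (mid-ranks, exact permutation
  p-value for n <= 9).

The bootstrap p-value is the two-sided tail proportion
``2 * min(P(diff* <= 0), P(diff* >= 0))`` clipped to [2/n_boot, 1], so
that p < 0.05 coincides with the 95% percentile CI excluding zero up to
resampling discreteness.
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BootstrapResult",
    "CorrelationResult",
    "bootstrap_mean_diff_test",
    "variance_f_test",
    "mc_pair_simulate",
    "bootstrap_pearson",
    "spearman",
]

EXACT_PERMUTATION_MAX_N = 9


@dataclass(frozen=True)
class BootstrapResult:
    mean_diff: float
    ci_low: float
    ci_high: float
    p_two_sided: float
    n_boot: int
    seed: Optional[int]

    @property
    def significant(self) -> bool:
        """CI excludes zero (equivalently p < 0.05 up to discreteness)."""
        return not (self.ci_low <= 0.0 <= self.ci_high)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    method: str  # "pearson_bootstrap" or "spearman"
    p: Optional[float] = None
    n_dropped: int = 0  # degenerate bootstrap resamples discarded


def _as_finite(values: Sequence[float], name: str, min_size: int = 1) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size < min_size:
        raise ValueError(f"{name} needs at least {min_size} observations")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must contain only finite values")
    return arr


def bootstrap_mean_diff_test(
    a: Sequence[float],
    b: Sequence[float],
    n_boot: int = 10_000,
    alpha: float = 0.05,
    seed: Optional[int] = None,
) -> BootstrapResult:
    """Two-sample bootstrap hypothesis test for a difference of means.

    Each replicate resamples ``a`` and ``b`` independently with
    replacement at their own sizes and records ``mean(a*) - mean(b*)``.
    The CI is the percentile interval at level ``1 - alpha``; the
    two-sided p is the clipped tail proportion (module docstring).
    Reproducible for a fixed ``seed``.
    """
    av = _as_finite(a, "a", 2)
    bv = _as_finite(b, "b", 2)
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000")
    rng = np.random.default_rng(seed)
    ia = rng.integers(0, av.size, size=(n_boot, av.size))
    ib = rng.integers(0, bv.size, size=(n_boot, bv.size))
    diffs = av[ia].mean(axis=1) - bv[ib].mean(axis=1)
    lo, hi = np.quantile(diffs, [alpha / 2, 1 - alpha / 2])
    p = 2.0 * min(float(np.mean(diffs <= 0)), float(np.mean(diffs >= 0)))
    p = float(np.clip(p, 2.0 / n_boot, 1.0))
    return BootstrapResult(
        mean_diff=float(av.mean() - bv.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        p_two_sided=p,
        n_boot=n_boot,
        seed=seed,
    )


def variance_f_test(a: Sequence[float], b: Sequence[float]):
    """F-test for equality of variances.

    Returns ``(F, df1, df2, p_two_sided)`` with ``F = s_a^2 / s_b^2``
    (sample variances, n-1 denominator) and the two-sided p-value
    ``2 * min(P(F' <= F), P(F' >= F))`` under F(df1, df2).
    """
    av = _as_finite(a, "a", 2)
    bv = _as_finite(b, "b", 2)
    var_a = av.var(ddof=1)
    var_b = bv.var(ddof=1)
    if var_b == 0.0:
        raise ValueError("denominator group has zero variance")
    f = float(var_a / var_b)
    df1, df2 = av.size - 1, bv.size - 1
    dist = stats.f(df1, df2)
    p = float(min(1.0, 2.0 * min(dist.cdf(f), dist.sf(f))))
    return f, df1, df2, p


def mc_pair_simulate(
    summaries: pd.DataFrame,
    n_per_cell: int = 3,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Monte-Carlo pairing of variables measured on different beads.

    ``summaries`` is a long table with columns
    ``variable, polymer, treatment, mean, sd``.  For every variable and
    (polymer, treatment) cell, ``n_per_cell`` normal draws are
    generated; draws are paired by index within the cell, so pooling
    the three polymers yields ``3 * n_per_cell`` paired rows per
    treatment.  Returns a wide table with columns
    ``polymer, treatment, draw`` plus one column per variable.
    """
    required = {"variable", "polymer", "treatment", "mean", "sd"}
    missing = required - set(summaries.columns)
    if missing:
        raise ValueError(f"summaries missing columns: {sorted(missing)}")
    if n_per_cell < 2:
        raise ValueError("n_per_cell must be >= 2")
    if (summaries["sd"] < 0).any():
        raise ValueError("sd must be non-negative")
    variables = sorted(summaries["variable"].unique())
    cells = summaries[["polymer", "treatment"]].drop_duplicates().sort_values(
        ["treatment", "polymer"]
    )
    indexed = summaries.set_index(["variable", "polymer", "treatment"])
    rng = np.random.default_rng(seed)
    rows = []
    for _, cell in cells.iterrows():
        draws = {}
        for var in variables:
            key = (var, cell["polymer"], cell["treatment"])
            if key not in indexed.index:
                raise ValueError(f"missing summary for cell {key}")
            rec = indexed.loc[key]
            draws[var] = rng.normal(float(rec["mean"]), float(rec["sd"]), n_per_cell)
        for i in range(n_per_cell):
            row = {"polymer": cell["polymer"], "treatment": cell["treatment"],
                   "draw": i}
            row.update({var: draws[var][i] for var in variables})
            rows.append(row)
    return pd.DataFrame(rows)


def bootstrap_pearson(
    x: Sequence[float],
    y: Sequence[float],
    n_boot: int = 10_000,
    seed: Optional[int] = None,
    max_redraw_rounds: int = 100,
) -> CorrelationResult:
    """Pearson's r with a percentile bootstrap CI over row resampling.

    Resamples in which x or y is constant (zero variance, r undefined)
    are redrawn; after ``max_redraw_rounds`` passes any remaining
    degenerate resamples are dropped and counted in ``n_dropped``.
    """
    xv = _as_finite(x, "x", 3)
    yv = _as_finite(y, "y", 3)
    if xv.size != yv.size:
        raise ValueError("x and y must have equal length")
    if xv.std() == 0 or yv.std() == 0:
        raise ValueError("constant input: Pearson correlation undefined")
    r_obs = float(np.corrcoef(xv, yv)[0, 1])
    rng = np.random.default_rng(seed)
    n = xv.size
    rs = np.empty(0)
    dropped = 0
    need = n_boot
    for _ in range(max_redraw_rounds):
        idx = rng.integers(0, n, size=(need, n))
        xb, yb = xv[idx], yv[idx]
        ok = (xb.std(axis=1) > 0) & (yb.std(axis=1) > 0)
        xb, yb = xb[ok], yb[ok]
        xc = xb - xb.mean(axis=1, keepdims=True)
        yc = yb - yb.mean(axis=1, keepdims=True)
        num = (xc * yc).sum(axis=1)
        den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
        rs = np.concatenate([rs, num / den])
        need = n_boot - rs.size
        if need <= 0:
            break
    else:
        dropped = need
    lo, hi = np.quantile(rs[:n_boot] if rs.size >= n_boot else rs, [0.025, 0.975])
    return CorrelationResult(
        r=r_obs, ci_low=float(lo), ci_high=float(hi),
        method="pearson_bootstrap", n_dropped=dropped,
    )


@functools.lru_cache(maxsize=4)
def _permutation_indices(n: int) -> np.ndarray:
    """All n! index permutations, cached (n <= 9 => at most 362,880 rows)."""
    return np.array(list(itertools.permutations(range(n))), dtype=np.int8)


def _rank_pearson(rx: np.ndarray, ry: np.ndarray) -> float:
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    den = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
    if den == 0:
        raise ValueError("constant ranks: Spearman correlation undefined")
    return float(rxc @ ryc) / den


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman's rho with mid-ranks for ties.

    The p-value is two-sided: exact enumeration of all pairings for
    n <= 9, the t-approximation above.  Invariant to strictly monotone
    transforms of either variable.
    """
    xv = _as_finite(x, "x", 3)
    yv = _as_finite(y, "y", 3)
    if xv.size != yv.size:
        raise ValueError("x and y must have equal length")
    rx = stats.rankdata(xv)  # mid-ranks
    ry = stats.rankdata(yv)
    rho = _rank_pearson(rx, ry)
    n = xv.size
    if n <= EXACT_PERMUTATION_MAX_N:
        perms = ry[_permutation_indices(n)]
        rxc = rx - rx.mean()
        pc = perms - perms.mean(axis=1, keepdims=True)
        den = np.sqrt(float(rxc @ rxc) * (pc**2).sum(axis=1))
        rhos = pc @ rxc / den
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        t = rho * math.sqrt((n - 2) / max(1e-300, 1 - rho**2))
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(
        r=rho, ci_low=float("nan"), ci_high=float("nan"), method="spearman", p=p
    )
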