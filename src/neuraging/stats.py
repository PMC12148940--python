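"""Statistical primitives used throughout the pipeline.

The figure-level statistics of the study this package supports are
deliberately simple and are implemented here from their definitions:

* Welch's two-sample t-test with Satterthwaite (fractional) degrees of
  freedom — the workhorse comparison for imaging metrics, blot
  quantifications and per-gene fold changes.
* Grubbs's outlier test, applied iteratively until no point is a
  significant outlier, used to pre-filter replicate-level measurements.
* The 2x2 likelihood-ratio (G) test with an odds ratio, used for the
  positional binding–splicing association map.
* Benjamini–Hochberg FDR control (delegated to statsmodels).

scipy provides equivalent Welch machinery; it is used only as an
independent cross-check in the test suite, never as the implementation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "welch_t_test",
    "welch_t_test_rows",
    "grubbs_filter",
    "grubbs_critical_value",
    "g_test_2x2",
    "bh_fdr",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test.

    ``estimate`` carries the natural effect size of the test (mean
    difference for Welch, odds ratio for the G-test).  ``degenerate`` is
    set when a documented zero-variance / zero-margin convention was
    applied instead of the regular formula.
    """

    statistic: float
    df: float
    p_value: float
    estimate: Optional[float] = None
    method: str = ""
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value outside [0,1]: {self.p_value}")


def _as_sample(x: Sequence[float], name: str, min_n: int) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if arr.size < min_n:
        raise ValueError(f"{name} needs at least {min_n} values, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-tailed Welch's t-test with Satterthwaite degrees of freedom.

    t = (mean(x) - mean(y)) / sqrt(s²x/nx + s²y/ny) with n-1 sample
    variances; df by the Welch–Satterthwaite approximation; p two-sided
    from the t distribution.

    Degenerate conventions (documented, not inherited from any tool):
    both samples constant and equal raises ``ValueError``; both constant
    but unequal returns p = 0 with ``degenerate=True``.
    """
    xa = _as_sample(x, "x", 2)
    ya = _as_sample(y, "y", 2)
    nx, ny = xa.size, ya.size
    mx, my = xa.mean(), ya.mean()
    vx = xa.var(ddof=1)
    vy = ya.var(ddof=1)
    diff = mx - my
    if vx == 0.0 and vy == 0.0:
        if mx == my:
            raise ValueError(
                "Welch statistic undefined: both samples constant and equal"
            )
        return TestResult(
            statistic=math.copysign(math.inf, diff),
            df=float(nx + ny - 2),
            p_value=0.0,
            estimate=diff,
            method="welch_t",
            degenerate=True,
        )
    se2 = vx / nx + vy / ny
    t = diff / math.sqrt(se2)
    # Welch–Satterthwaite
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(
        statistic=t, df=df, p_value=min(p, 1.0), estimate=diff, method="welch_t"
    )


def welch_t_test_rows(
    x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise Welch test for many independent comparisons at once.

    ``x`` and ``y`` are (n_tests, n_replicates) arrays; returns
    (statistic, df, p) per row.  Same formulae as :func:`welch_t_test`;
    degenerate rows follow the screening conventions used by the
    per-gene/per-event pipelines: both samples constant and equal gives
    p = 1 (no evidence), both constant and unequal gives p = 0.
    """
    xa = np.atleast_2d(np.asarray(x, dtype=float))
    ya = np.atleast_2d(np.asarray(y, dtype=float))
    if xa.shape[0] != ya.shape[0]:
        raise ValueError("x and y must have the same number of rows")
    if xa.shape[1] < 2 or ya.shape[1] < 2:
        raise ValueError("need >= 2 replicates per sample")
    nx, ny = xa.shape[1], ya.shape[1]
    vx = xa.var(axis=1, ddof=1)
    vy = ya.var(axis=1, ddof=1)
    diff = xa.mean(axis=1) - ya.mean(axis=1)
    se2 = vx / nx + vy / ny
    degenerate = se2 == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, 0.0, diff / np.sqrt(np.where(degenerate, 1.0, se2)))
        df = np.where(
            degenerate,
            float(nx + ny - 2),
            se2**2
            / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1) + degenerate),
        )
    p = np.minimum(2.0 * sps.t.sf(np.abs(t), df), 1.0)
    p[degenerate & (diff != 0.0)] = 0.0
    p[degenerate & (diff == 0.0)] = 1.0
    t[degenerate & (diff != 0.0)] = np.inf * np.sign(diff[degenerate & (diff != 0.0)])
    return t, df, p


def grubbs_critical_value(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value for sample size ``n`` at ``alpha``.

    G_crit = (n-1)/sqrt(n) * sqrt(t² / (n-2+t²)) with
    t = t_(1 - alpha/(2n), n-2).
    """
    if n < 3:
        raise ValueError("Grubbs test undefined for n < 3")
    t = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t**2 / (n - 2 + t**2))


def grubbs_filter(
    values: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, list[int]]:
    """Iteratively remove significant Grubbs outliers.

    While G = max|xi - mean| / sd exceeds the two-sided critical value at
    ``alpha``, the single most extreme point is removed; repeats until no
    point is significant or fewer than 3 points remain.  Zero spread means
    no outlier by convention.  Returns the surviving values in their
    original order and the removed original indices in removal order.
    """
    vals = _as_sample(values, "values", 3)
    if not (0.0 < alpha < 0.5):
        raise ValueError("alpha must be in (0, 0.5)")
    idx = list(range(vals.size))
    removed: list[int] = []
    while len(idx) >= 3:
        cur = vals[idx]
        s = cur.std(ddof=1)
        if s == 0.0:
            break
        dev = np.abs(cur - cur.mean())
        k = int(np.argmax(dev))
        g = dev[k] / s
        if g > grubbs_critical_value(len(idx), alpha):
            removed.append(idx.pop(k))
        else:
            break
    return vals[idx], removed


def g_test_2x2(table: Sequence[Sequence[float]]) -> TestResult:
    """Likelihood-ratio (G) test of independence on a 2x2 count table.

    G = 2 * sum O * ln(O/E) on the uncorrected table, with expected counts
    from the margins and the 0*ln(0) = 0 convention; p from chi-square
    with 1 df.  The odds ratio (a*d)/(b*c) is computed on a
    Haldane–Anscombe-corrected table (0.5 added to every cell) whenever
    any cell is zero.  A zero row or column margin makes G undefined: the
    result carries p = 1, the corrected-table OR and ``degenerate=True``.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(obs < 0) or not np.all(np.isfinite(obs)):
        raise ValueError("table must contain non-negative finite counts")

    corr = obs + 0.5 if np.any(obs == 0) else obs
    odds_ratio = (corr[0, 0] * corr[1, 1]) / (corr[0, 1] * corr[1, 0])

    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    if np.any(row == 0) or np.any(col == 0) or total == 0:
        return TestResult(
            statistic=float("nan"),
            df=1.0,
            p_value=1.0,
            estimate=odds_ratio,
            method="g_test_2x2",
            degenerate=True,
        )
    expected = np.outer(row, col) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
    g = 2.0 * terms.sum()
    g = max(g, 0.0)  # guard tiny negative round-off
    p = sps.chi2.sf(g, 1)
    return TestResult(
        statistic=g, df=1.0, p_value=float(p), estimate=odds_ratio, method="g_test_2x2"
    )


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, aligned to the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D vector")
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
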