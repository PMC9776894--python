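"""Inferential primitives shared by the imaging and plate pipelines.

Welch two-sample and one-sample t-tests (two-tailed, fractional degrees of
freedom kept), Benjamini-Hochberg adjustment, and the replicate-aggregation
contract: inference runs on per-experiment means, never on pooled per-cell
values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["TestResult", "welch_t", "one_sample_t", "bh_adjust", "experiment_means"]


@dataclass
class TestResult:
    """Outcome of a t-test with everything needed to recompute the p-value."""

    statistic: float
    df: float
    pvalue: float
    means: tuple[float, ...]
    sds: tuple[float, ...]
    ns: tuple[int, ...]
    degenerate: bool = False


def _clean(x, min_n: int, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"{name} must be 1D")
    if x.size < min_n:
        raise ValueError(f"{name} needs at least {min_n} observations, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")
    return x


def welch_t(x, y) -> TestResult:
    """Unpaired two-sample t-test with Welch's correction, two-sided.

    Degenerate zero-variance cases follow the natural conventions: equal
    means give p = 1, unequal means give p = 0 (flagged degenerate).
    """
    x = _clean(x, 2, "x")
    y = _clean(y, 2, "y")
    mx, my = x.mean(), y.mean()
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    base = dict(means=(mx, my), sds=(sx, sy), ns=(x.size, y.size))
    if sx == 0 and sy == 0:
        if mx == my:
            return TestResult(0.0, float(x.size + y.size - 2), 1.0, **base)
        sign = np.sign(mx - my)
        return TestResult(
            sign * np.inf, float(x.size + y.size - 2), 0.0, degenerate=True, **base
        )
    res = sps.ttest_ind(x, y, equal_var=False)
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue), **base)


def one_sample_t(x, mu0: float) -> TestResult:
    """One-sample t-test of mean(x) against the baseline ``mu0``, two-sided."""
    x = _clean(x, 2, "x")
    m, s = x.mean(), x.std(ddof=1)
    base = dict(means=(m, float(mu0)), sds=(s,), ns=(x.size,))
    if s == 0:
        if m == mu0:
            return TestResult(0.0, float(x.size - 1), 1.0, **base)
        return TestResult(
            np.sign(m - mu0) * np.inf, float(x.size - 1), 0.0, degenerate=True, **base
        )
    res = sps.ttest_1samp(x, mu0)
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue), **base)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    NaN p-values propagate to NaN q-values and do not enter the correction.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1D")
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    if finite.any():
        q[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return q


def experiment_means(values, experiments) -> pd.Series:
    """Collapse per-unit values (cells, lysosomes, wells) to one mean per
    experiment — the replication unit for all downstream tests."""
    s = pd.Series(np.asarray(values, dtype=float))
    labels = pd.Series(list(experiments))
    if len(s) != len(labels):
        raise ValueError("values and experiment labels differ in length")
    if len(s) == 0:
        raise ValueError("no values supplied")
    out = s.groupby(labels.to_numpy()).mean()
    out.index.name = "experiment"
    return out
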