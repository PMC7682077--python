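"""Shared statistical primitives used by every analysis stage.

Thin, uniform wrappers around scipy.stats, statsmodels and lifelines that
return :class:`TestResult` records and handle degenerate inputs (constant
vectors, no events, too-few observations) by flagging rather than raising,
so cohort-wide scans never abort mid-run.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "spearman",
    "bh_adjust",
    "t_test",
    "anova_oneway",
    "chi_square_gof",
    "logrank",
    "cox_ph",
]


@dataclass
class TestResult:
    """One test outcome: statistic, two-sided p, size, and an effect estimate.

    ``estimate`` carries the natural effect measure for the test (Rs for
    correlations, mean difference for t-tests, hazard ratio for Cox).
    ``degenerate`` marks results produced from inputs on which the test is
    not defined (these carry conventional p-values and are excluded from
    downstream significance calls where appropriate).
    """

    statistic: float
    p_value: float
    n: int
    estimate: float = np.nan
    degenerate: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value out of range: {self.p_value}")


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError(f"{name} contains non-finite values")
    return arr


def spearman(x, y, exact: bool = False) -> TestResult:
    """Spearman rank correlation with a two-sided t-approximation p-value.

    Ranks use midranks for ties; p comes from t = Rs*sqrt((n-2)/(1-Rs^2))
    on n-2 df. ``exact=True`` enumerates all permutations (only feasible
    for n <= 10) and is intended for very small samples.
    """
    x = _as_float_array(x, "x")
    y = _as_float_array(y, "y")
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult(np.nan, 1.0, n, estimate=0.0, degenerate=True,
                          note="n<3 or zero variance")
    if exact:
        if n > 10:
            raise ValueError("exact mode only supported for n <= 10")
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        obs = np.corrcoef(rx, ry)[0, 1]
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, np.asarray(perm))[0, 1]
            count += abs(r) >= abs(obs) - 1e-12
            total += 1
        return TestResult(obs, count / total, n, estimate=obs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rs, p = sps.spearmanr(x, y)
    if np.isnan(rs):
        return TestResult(np.nan, 1.0, n, estimate=0.0, degenerate=True,
                          note="undefined correlation")
    if abs(rs) > 1.0 - 1e-12:  # rank correlations are rational; snap +-1
        rs, p = float(np.sign(rs)), 0.0
    return TestResult(rs, float(p), n, estimate=float(rs))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def t_test(a, b, paired: bool = False, pooled: bool = True) -> TestResult:
    """Two-sided Student's t-test (paired, or unpaired pooled-variance).

    ``pooled=False`` switches the unpaired test to Welch. Zero-variance
    inputs give flagged degenerate results: p = 1 when the mean difference
    is zero, p = 0 (limit) otherwise.
    """
    a = _as_float_array(a, "a")
    b = _as_float_array(b, "b")
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired test needs equal-length vectors")
        if len(a) < 2:
            raise ValueError("paired test needs n >= 2")
        d = a - b
        est = float(np.mean(d))
        if np.ptp(d) == 0:
            p = 1.0 if est == 0 else 0.0
            return TestResult(np.nan, p, len(a), estimate=est, degenerate=True,
                              note="zero variance of differences")
        t, p = sps.ttest_rel(a, b)
        return TestResult(float(t), float(p), len(a), estimate=est)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("unpaired test needs n >= 2 per group")
    est = float(np.mean(a) - np.mean(b))
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        p = 1.0 if est == 0 else 0.0
        return TestResult(np.nan, p, len(a) + len(b), estimate=est,
                          degenerate=True, note="zero variance in both groups")
    t, p = sps.ttest_ind(a, b, equal_var=pooled)
    return TestResult(float(t), float(p), len(a) + len(b), estimate=est)


def anova_oneway(groups) -> TestResult:
    """One-way fixed-effects ANOVA F-test across >= 2 groups."""
    groups = [_as_float_array(g, "group") for g in groups]
    if len(groups) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    pooled = np.concatenate(groups)
    n = len(pooled)
    if np.ptp(pooled) == 0:
        return TestResult(0.0, 1.0, n, estimate=0.0, degenerate=True,
                          note="all values identical")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = sps.f_oneway(*groups)
    if np.isnan(f):
        return TestResult(np.nan, 1.0, n, estimate=0.0, degenerate=True,
                          note="zero within-group variance")
    return TestResult(float(f), float(p), n, estimate=float(f))


def chi_square_gof(counts, expected_proportions=None) -> TestResult:
    """Chi-square goodness-of-fit, df = k-1, no continuity correction.

    ``expected_proportions`` defaults to equal expectation across cells.
    """
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    total = counts.sum()
    if total == 0:
        raise ValueError("counts sum to zero")
    k = len(counts)
    if expected_proportions is None:
        props = np.full(k, 1.0 / k)
    else:
        props = np.asarray(expected_proportions, dtype=float)
        if len(props) != k:
            raise ValueError("expected_proportions length mismatch")
        if not np.isclose(props.sum(), 1.0):
            raise ValueError("expected_proportions must sum to 1")
    expected = props * total
    if (expected <= 0).any():
        raise ValueError("zero expected cell")
    stat = float(((counts - expected) ** 2 / expected).sum())
    p = float(sps.chi2.sf(stat, df=k - 1))
    return TestResult(stat, p, int(total), estimate=stat)


def logrank(time_a, event_a, time_b, event_b) -> TestResult:
    """Two-group log-rank test (chi-square with 1 df)."""
    from lifelines.statistics import logrank_test

    time_a = _as_float_array(time_a, "time_a")
    time_b = _as_float_array(time_b, "time_b")
    event_a = np.asarray(event_a, dtype=int)
    event_b = np.asarray(event_b, dtype=int)
    if len(time_a) == 0 or len(time_b) == 0:
        raise ValueError("both groups must be non-empty")
    if not (np.isin(event_a, (0, 1)).all() and np.isin(event_b, (0, 1)).all()):
        raise ValueError("events must be binary")
    n = len(time_a) + len(time_b)
    if event_a.sum() + event_b.sum() == 0:
        return TestResult(0.0, 1.0, n, degenerate=True, note="no events")
    res = logrank_test(time_a, time_b, event_observed_A=event_a,
                       event_observed_B=event_b)
    stat, p = float(res.test_statistic), float(res.p_value)
    if np.isnan(stat):
        return TestResult(0.0, 1.0, n, degenerate=True, note="degenerate risk sets")
    return TestResult(stat, p, n)


def cox_ph(time, event, covariate) -> TestResult:
    """Univariate Cox proportional-hazards fit (Breslow ties), Wald p.

    ``estimate`` is the hazard ratio exp(beta) per unit of the covariate.
    Non-convergent or constant-covariate fits return flagged degenerate
    results (HR = 1, p = 1) so scans can skip them.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    time = _as_float_array(time, "time")
    event = np.asarray(event, dtype=int)
    cov = _as_float_array(covariate, "covariate")
    n = len(time)
    if event.sum() < 2:
        return TestResult(np.nan, 1.0, n, estimate=1.0, degenerate=True,
                          note="fewer than 2 events")
    if np.ptp(cov) == 0:
        return TestResult(np.nan, 1.0, n, estimate=1.0, degenerate=True,
                          note="constant covariate")
    df = pd.DataFrame({"time": time, "event": event, "x": cov})
    fitter = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(df, duration_col="time", event_col="event")
    except (ConvergenceError, ValueError) as exc:
        return TestResult(np.nan, 1.0, n, estimate=1.0, degenerate=True,
                          note=f"non-convergence: {exc}")
    hr = float(np.exp(fitter.params_["x"]))
    p = float(fitter.summary.loc["x", "p"])
    z = float(fitter.summary.loc["x", "z"])
    return TestResult(z, p, n, estimate=hr)
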