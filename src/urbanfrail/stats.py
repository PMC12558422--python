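"""Classical two-group, proportion, correlation and regression machinery.

Thin, opinionated wrappers over scipy/statsmodels that standardise the
results into serialisable records: Welch t or Mann-Whitney (with an ``auto``
normality-screened choice), Yates-corrected chi-square for 2x2 proportions
with Wilson intervals, Spearman/Pearson correlation and ordinary least
squares. All p-values are two-sided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

logger = logging.getLogger(__name__)


@dataclass
class StatResult:
    test: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    estimates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1 or np.isnan(self.p_value)):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


@dataclass
class CorrelationResult:
    method: Literal["spearman", "pearson"]
    coefficient: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.coefficient) > 1 + 1e-12:
            raise ValueError(f"|coefficient| > 1: {self.coefficient}")


def _clean(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[np.isfinite(x)]


def two_group_compare(
    x,
    y,
    method: Literal["t", "mann_whitney", "auto"] = "auto",
    normality_alpha: float = 0.05,
) -> StatResult:
    """Compare two independent samples.

    ``t`` is Welch's unequal-variance t test; ``mann_whitney`` uses the exact
    null distribution for small tie-free samples and the tie-corrected normal
    approximation otherwise. ``auto`` picks Mann-Whitney when either group
    fails a Shapiro normality screen at ``normality_alpha``, else Welch t;
    the choice is logged.
    """
    x, y = _clean(x), _clean(y)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    if method == "auto":
        px = sps.shapiro(x).pvalue if len(x) >= 3 else 1.0
        py = sps.shapiro(y).pvalue if len(y) >= 3 else 1.0
        method = "mann_whitney" if min(px, py) < normality_alpha else "t"
        logger.info("auto test choice: %s (shapiro p=%.3g/%.3g)", method, px, py)
    if method == "t":
        res = sps.ttest_ind(x, y, equal_var=False)
        est = {
            "mean_1": float(np.mean(x)),
            "sd_1": float(np.std(x, ddof=1)),
            "mean_2": float(np.mean(y)),
            "sd_2": float(np.std(y, ddof=1)),
        }
        return StatResult("welch_t", float(res.statistic), float(res.pvalue), (len(x), len(y)), est)
    if method == "mann_whitney":
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
        est = {"median_1": float(np.median(x)), "median_2": float(np.median(y))}
        return StatResult(
            "mann_whitney", float(res.statistic), float(res.pvalue), (len(x), len(y)), est
        )
    raise ValueError(f"unknown method {method!r}")


def proportion_compare(
    k1: int, n1: int, k2: int, n2: int, ci_method: str = "wilson"
) -> StatResult:
    """2x2 chi-square with Yates continuity correction; Wilson 95% CIs."""
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0 or not (0 <= k <= n):
            raise ValueError(f"invalid counts k={k}, n={n}")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    if np.any(table.sum(axis=0) == 0) or np.array_equal(table[0] * n2, table[1] * n1):
        # identical proportions (or degenerate margin): corrected chi2 clips at 0
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = sps.chi2_contingency(table, correction=True)
    est = {}
    for i, (k, n) in enumerate(((k1, n1), (k2, n2)), start=1):
        lo, hi = proportion_confint(k, n, alpha=0.05, method=ci_method)
        est[f"prop_{i}"] = k / n
        est[f"ci_low_{i}"] = float(lo)
        est[f"ci_high_{i}"] = float(hi)
    return StatResult("chi2_yates", float(chi2), float(p), (n1, n2), est)


def correlate(x, y, method: Literal["spearman", "pearson"] = "spearman") -> CorrelationResult:
    """Correlation with two-sided p.

    Spearman uses average ranks for ties (equal to Pearson on the rank
    vectors); p from the t approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need n >= 3 finite pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate input: zero variance")
    if method == "spearman":
        rho, p = sps.spearmanr(x, y)
    elif method == "pearson":
        rho, p = sps.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(method, float(rho), float(p), len(x))


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r: float
    p_value: float
    n: int


def linear_fit(x, y) -> LinearFit:
    """Ordinary least squares of y on x; p is the two-sided slope test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need n >= 3 finite pairs")
    if np.ptp(x) == 0:
        raise ValueError("var(x) = 0")
    res = sps.linregress(x, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p_value=float(res.pvalue),
        n=len(x),
    )
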