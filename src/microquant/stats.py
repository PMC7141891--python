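"""Correlation, dependent-correlation comparison, heteroskedasticity and t tests.

Statistical machinery used across the validation: Pearson correlation with
t-distribution p values; the Hittner back-transformed-average Fisher-z test
for two overlapping dependent correlations (r(1,2) vs r(1,3) sharing
variable 1); the Breusch-Pagan heteroskedasticity screen in its studentized
(Koenker, n.R^2) and original forms; paired / one-sided / Welch mean tests;
and simple per-species linear regressions on log10 scales.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "pearson", "CorrelationComparison", "compare_overlapping_correlations",
    "breusch_pagan", "mean_tests", "RegressionFit", "linear_fit", "format_p",
]


def pearson(x, y):
    """Sample Pearson r with a two-sided p from the t distribution (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class CorrelationComparison:
    """Two overlapping dependent correlations sharing variable 1, compared."""

    r12: float
    r13: float
    r23: float
    n: int
    z: float
    p: float


def compare_overlapping_correlations(r12, r13, r23, n) -> CorrelationComparison:
    """Hittner test for H0: rho(1,2) = rho(1,3) with variable 1 shared.

    Dunn & Clark's z with the correlation between the two dependent r's
    evaluated at the back-transformed average of the Fisher transforms of
    r12 and r13 (Hittner, May & Silver's modification). Two-sided normal p.
    Positive z means r12 > r13.
    """
    for r in (r12, r13, r23):
        if not -1 <= r <= 1:
            raise ValueError("correlations must lie in [-1, 1]")
    if abs(r12) == 1 or abs(r13) == 1:
        raise ValueError("Fisher z diverges at |r| = 1")
    if n < 4:
        raise ValueError("need n >= 4")
    z12 = np.arctanh(r12)
    z13 = np.arctanh(r13)
    rbar = np.tanh((z12 + z13) / 2.0)        # back-transformed average
    num = (r23 * (1.0 - 2.0 * rbar ** 2)
           - 0.5 * rbar ** 2 * (1.0 - 2.0 * rbar ** 2 - r23 ** 2))
    c = num / (1.0 - rbar ** 2) ** 2
    if c >= 1.0:
        # near-collinear triple: the asymptotic variance degenerates
        z = 0.0 if z12 == z13 else np.nan
    else:
        z = (z12 - z13) * np.sqrt((n - 3.0) / (2.0 - 2.0 * c))
    p = 2.0 * sps.norm.sf(abs(z))
    return CorrelationComparison(float(r12), float(r13), float(r23), int(n),
                                 float(z), float(min(p, 1.0)) if p > 0 else float(p))


def breusch_pagan(y, X, studentized=True):
    """Breusch-Pagan heteroskedasticity test of an OLS fit of y on X.

    Fits y on X (a constant column is added), regresses the squared
    residuals on the same design, and forms the Lagrange-multiplier
    statistic: ``n * R^2`` of the auxiliary regression in the studentized
    (Koenker) form, or the original ESS/2 form on normalised squared
    residuals when ``studentized=False``. p from chi^2 with k regressors df.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if n <= k + 1:
        raise ValueError("need n > k + 1 observations")
    design = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("singular design matrix")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    u2 = resid ** 2
    gamma, *_ = np.linalg.lstsq(design, u2, rcond=None)
    fitted = design @ gamma
    ss_res = float(np.sum((u2 - fitted) ** 2))
    ss_tot = float(np.sum((u2 - u2.mean()) ** 2))
    if ss_tot == 0:
        return 0.0, 1.0
    r2 = 1.0 - ss_res / ss_tot
    if studentized:
        lm = n * r2
    else:
        # original form assumes Gaussian errors: ESS/2 of g = u^2 / sigma_hat^2
        sigma2 = float(u2.mean())
        g = u2 / sigma2
        gam2, *_ = np.linalg.lstsq(design, g, rcond=None)
        fit_g = design @ gam2
        lm = 0.5 * float(np.sum((fit_g - g.mean()) ** 2))
    p = float(sps.chi2.sf(lm, k))
    return float(lm), p


def mean_tests(a, b=None, mode="welch"):
    """t statistics for the comparisons used in the validation summaries.

    ``paired``: paired two-sided t test (equal lengths). ``welch``:
    two-sided Welch test. ``one_sided``: Welch test of mean(a) > mean(b),
    or of mean(a) > 0 when ``b`` is None.
    """
    a = np.asarray(a, dtype=float)
    if len(a) < 2:
        raise ValueError("need at least 2 observations")
    if mode == "one_sided" and b is None:
        t, p = sps.ttest_1samp(a, 0.0, alternative="greater")
        return float(t), float(p)
    b = np.asarray(b, dtype=float)
    if len(b) < 2:
        raise ValueError("need at least 2 observations")
    if mode == "paired":
        if len(a) != len(b):
            raise ValueError("paired test requires equal lengths")
        t, p = sps.ttest_rel(a, b)
    elif mode == "welch":
        t, p = sps.ttest_ind(a, b, equal_var=False)
    elif mode == "one_sided":
        t, p = sps.ttest_ind(a, b, equal_var=False, alternative="greater")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(t), float(p)


@dataclass
class RegressionFit:
    """Simple linear fit y = intercept + slope * x on log10 scales."""

    intercept: float
    slope: float
    r: float
    p: float
    n: int


def linear_fit(x, y) -> RegressionFit:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("regression undefined: predictor has zero variance")
    res = sps.linregress(x, y)
    return RegressionFit(float(res.intercept), float(res.slope),
                         float(res.rvalue), float(res.pvalue), len(x))


def format_p(p, tick=2.2e-16) -> str:
    """Report-style p value; values below the machine tick print as a bound."""
    if p < tick:
        return f"< {tick:.1e}"
    return f"{p:.3g}"
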