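"""Linear comparison of a derived view against the complete view.

Every robustness question in this package reduces to the same regression:
take a statistic computed from a truncated or derived view (x) and from the
complete dataset (y), fit ordinary least squares ``y = a + b·x``, and report
the adjusted R², the slope with its 95% confidence interval, whether the
slope differs from 1 (the y = x line of perfect agreement), and a
permutation p-value for the fit (response-vector permutation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .beta import PairwiseMatrix


@dataclass(frozen=True)
class RegressionComparison:
    n_points: int
    r2_adj: float
    slope: float
    intercept: float
    slope_ci95: tuple
    slope_differs_from_1: bool
    perm_p: float
    n_perm: int


def linear_comparison(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 5000,
    seed: int = 0,
) -> RegressionComparison:
    """OLS of ``y`` on ``x`` with slope CI and permutation significance.

    The permutation p-value shuffles the response vector ``n_perm`` times
    and counts permuted R² at least as large as observed (add-one
    corrected). ``n_perm = 0`` skips the permutation test (``perm_p`` NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matched 1-D arrays")
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 points, got {n}")
    xbar = x.mean()
    ybar = y.mean()
    xc = x - xbar
    yc = y - ybar
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise ValueError("x has zero variance")
    sxy = float(xc @ yc)
    syy = float(yc @ yc)
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - (intercept + slope * x)
    sse = float(resid @ resid)
    r2 = 1.0 - sse / syy if syy > 0 else float("nan")
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    se_slope = np.sqrt(sse / (n - 2) / sxx)
    tcrit = stats.t.ppf(0.975, n - 2)
    ci = (slope - tcrit * se_slope, slope + tcrit * se_slope)
    differs = not (ci[0] <= 1.0 <= ci[1])

    if n_perm > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 8]))
        count = 0
        if syy > 0:
            for _ in range(n_perm):
                yp = yc[rng.permutation(n)]
                r2p = (xc @ yp) ** 2 / (sxx * syy)
                if r2p >= r2 - 1e-12:
                    count += 1
        perm_p = (1 + count) / (1 + n_perm)
    else:
        perm_p = float("nan")
    return RegressionComparison(
        n_points=n,
        r2_adj=float(r2_adj),
        slope=float(slope),
        intercept=float(intercept),
        slope_ci95=(float(ci[0]), float(ci[1])),
        slope_differs_from_1=bool(differs),
        perm_p=float(perm_p),
        n_perm=int(n_perm),
    )


def similarity_regression(
    x: PairwiseMatrix,
    y: PairwiseMatrix,
    n_perm: int = 5000,
    seed: int = 0,
) -> RegressionComparison:
    """Regress the complete view's pairwise values (``y``) on the derived
    view's (``x``), over the strictly-lower-triangle entries."""
    if x.labels != y.labels:
        raise ValueError("pairwise matrices must share labels in the same order")
    return linear_comparison(x.condensed(), y.condensed(), n_perm=n_perm, seed=seed)
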