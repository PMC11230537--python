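"""Independent brute-force oracles used only by the test suite.

Deliberately naive implementations (explicit loops, grid searches) kept
separate from the package code paths they check.
"""
from __future__ import annotations

import math

import numpy as np
from scipy import stats


def anova_mean_squares_loops(x: np.ndarray) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares via explicit element loops."""
    n, k = x.shape
    grand = sum(x[i, j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(x[i, j] for j in range(k)) / k for i in range(n)]
    col_means = [sum(x[i, j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((rm - grand) ** 2 for rm in row_means)
    ss_cols = n * sum((cm - grand) ** 2 for cm in col_means)
    ss_err = sum(
        (x[i, j] - row_means[i] - col_means[j] + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    return ss_rows / (n - 1), ss_cols / (k - 1), ss_err / ((n - 1) * (k - 1))


def icc_oracle(x: np.ndarray, form: str) -> float:
    """All four ICC forms assembled from the loop-based ANOVA."""
    n, k = x.shape
    msr, msc, mse = anova_mean_squares_loops(x)
    if form == "oneway_1":
        grand = x.mean()
        ss_total = sum(
            (x[i, j] - grand) ** 2 for i in range(n) for j in range(k)
        )
        msw = (ss_total - msr * (n - 1)) / (n * (k - 1))
        num, den = msr - msw, msr + (k - 1) * msw
    elif form == "twoway_random_single":
        num, den = msr - mse, msr + (k - 1) * mse + k * (msc - mse) / n
    elif form == "twoway_mixed_single":
        num, den = msr - mse, msr + (k - 1) * mse
    elif form == "twoway_random_avg":
        num, den = msr - mse, msr + (msc - mse) / n
    else:
        raise ValueError(form)
    return 1.0 if den == 0 else num / den


def smd_oracle(nt, mt, st, nc, mc, sc, hedges=True):
    """Hand evaluation of the standardized-mean-difference formulas."""
    df = nt + nc - 2
    sp = math.sqrt(((nt - 1) * st**2 + (nc - 1) * sc**2) / df)
    d = (mt - mc) / sp
    j = 1 - 3 / (4 * df - 1)
    g = j * d if hedges else d
    vi = (nt + nc) / (nt * nc) + g**2 / (2 * (nt + nc))
    return g, vi


def log_rr_oracle(a, n1, c, n2, correct=False):
    if correct:
        a, c, n1, n2 = a + 0.5, c + 0.5, n1 + 1, n2 + 1
    yi = math.log((a / n1) / (c / n2))
    vi = 1 / a - 1 / n1 + 1 / c - 1 / n2
    return yi, vi


def tau2_dl_oracle(yi, vi):
    """Intercept-only DerSimonian-Laird moment formula, summed by loop."""
    k = len(yi)
    w = [1 / v for v in vi]
    sw = sum(w)
    ybar = sum(wi * y for wi, y in zip(w, yi)) / sw
    q = sum(wi * (y - ybar) ** 2 for wi, y in zip(w, yi))
    c = sw - sum(wi**2 for wi in w) / sw
    return max(0.0, (q - (k - 1)) / c)


def kh_pool_oracle(yi, vi, tau2):
    """Brute-force KH random-effects pooling at a given tau2."""
    k = len(yi)
    w = [1 / (v + tau2) for v in vi]
    sw = sum(w)
    mu = sum(wi * y for wi, y in zip(w, yi)) / sw
    se2 = (sum(wi * (y - mu) ** 2 for wi, y in zip(w, yi)) / (k - 1)) / sw
    se = math.sqrt(se2)
    tq = stats.t.ppf(0.975, k - 1)
    p = 2 * stats.t.sf(abs(mu) / se, k - 1)
    return mu, se, (mu - tq * se, mu + tq * se), p


def heterogeneity_oracle(yi, vi):
    k = len(yi)
    w = [1 / v for v in vi]
    ybar = sum(wi * y for wi, y in zip(w, yi)) / sum(w)
    q = sum(wi * (y - ybar) ** 2 for wi, y in zip(w, yi))
    i2 = max(0.0, (q - (k - 1)) / q) if q > 0 else 0.0
    return q, stats.chi2.sf(q, k - 1), i2


def reml_loglik(tau2, yi, vi, X=None):
    """Restricted log-likelihood of the normal-normal model at tau2."""
    yi = np.asarray(yi, float)
    vi = np.asarray(vi, float)
    k = yi.size
    if X is None:
        X = np.ones((k, 1))
    V = np.diag(vi + tau2)
    Vinv = np.linalg.inv(V)
    XtVX = X.T @ Vinv @ X
    beta = np.linalg.solve(XtVX, X.T @ Vinv @ yi)
    resid = yi - X @ beta
    return float(
        -0.5 * np.log(np.linalg.det(V))
        - 0.5 * np.log(np.linalg.det(XtVX))
        - 0.5 * resid @ Vinv @ resid
    )


def reml_grid_oracle(yi, vi, upper=2.0, coarse=2001, refine=2001):
    """Two-stage grid-search maximizer of the restricted likelihood."""
    grid = np.linspace(0.0, upper, coarse)
    lls = [reml_loglik(t, yi, vi) for t in grid]
    best = grid[int(np.argmax(lls))]
    lo, hi = max(0.0, best - upper / (coarse - 1)), best + upper / (coarse - 1)
    grid2 = np.linspace(lo, hi, refine)
    lls2 = [reml_loglik(t, yi, vi) for t in grid2]
    return float(grid2[int(np.argmax(lls2))])


def equal_sum_level(scores):
    s = sum(scores)
    return "low" if s <= 5 else ("moderate" if s <= 7 else "high")


def tree_level(scores):
    w = 2 * scores[0] + 2 * scores[1] + scores[2]
    return "low" if w <= 7 else ("high" if w >= 13 else "moderate")
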