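"""Random-effects meta-analysis with the Knapp–Hartung adjustment.

The normal–normal model: each study i reports ``yi ~ N(theta_i, vi)`` with
known sampling variance ``vi``, and the true effects are exchangeable,
``theta_i ~ N(mu, tau2)``.  The between-study variance tau² is estimated by
REML (default), DerSimonian–Laird, or Paule–Mandel; the pooled mean uses
inverse-variance weights ``w = 1/(vi + tau2)``; and inference uses the
Knapp–Hartung (KH) variance estimator with a t reference on k-1 degrees of
freedom, which keeps small-k confidence intervals close to nominal.

Heterogeneity is summarized by Cochran's Q (fixed-effect weights) with its
chi-square p-value and by I² = max(0, (Q - (k-1))/Q); I² >= 50% is flagged
as substantial.

Moderators enter through :func:`meta_regression_kh`: a mixed-effects
(random-effects with covariates) weighted least-squares fit on dummy-coded
moderator levels, residual tau² by the configured estimator, KH-type scaling
of the coefficient covariance, and an omnibus F test for the moderator with
(m, k-p) degrees of freedom — the single "meta-regression P" reported per
moderator.

All estimators accept a list of :class:`~motivmeta.effects.EffectEstimate`
or bare (yi, vi) arrays.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .effects import EffectEstimate

__all__ = [
    "MetaResult",
    "MetaRegResult",
    "tau2_dl",
    "tau2_pm",
    "tau2_reml",
    "estimate_tau2",
    "pool_random_kh",
    "heterogeneity",
    "subgroup_analysis",
    "meta_regression_kh",
    "significance",
    "forest_data",
    "I2_SUBSTANTIAL",
]

logger = logging.getLogger(__name__)

I2_SUBSTANTIAL = 0.5
ALPHA = 0.05

TAU2_METHODS = ("REML", "DL", "PM")


def _as_arrays(effects) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(effects, tuple) and len(effects) == 2:
        yi, vi = (np.asarray(a, dtype=float) for a in effects)
    else:
        yi = np.array([e.yi for e in effects], dtype=float)
        vi = np.array([e.vi for e in effects], dtype=float)
    if yi.shape != vi.shape or yi.ndim != 1:
        raise ValueError("yi and vi must be 1-d arrays of equal length")
    if np.any(vi <= 0):
        raise ValueError("all sampling variances must be positive")
    return yi, vi


def _projection(vi: np.ndarray, tau2: float, X: np.ndarray) -> np.ndarray:
    """P = W - W X (X'WX)^-1 X'W for W = diag(1/(vi + tau2))."""
    w = 1.0 / (vi + tau2)
    WX = w[:, None] * X
    XtWX_inv = np.linalg.inv(X.T @ WX)
    return np.diag(w) - WX @ XtWX_inv @ WX.T


def _default_design(k: int) -> np.ndarray:
    return np.ones((k, 1))


def tau2_dl(effects, X: np.ndarray | None = None) -> float:
    """DerSimonian–Laird moment estimator of tau².

    Intercept-only: with w = 1/vi and Q = sum w (yi - ybar_w)²,
    tau² = max(0, (Q - (k-1)) / (sum w - sum w² / sum w)).  With a design
    matrix X the same moment identity is applied through the fixed-effect
    projection matrix, giving max(0, (y'P0 y - (k-p)) / tr(P0)).
    """
    yi, vi = _as_arrays(effects)
    k = yi.size
    if X is None:
        X = _default_design(k)
    p = X.shape[1]
    if k <= p:
        raise ValueError(f"tau2 undefined: k={k} studies for p={p} coefficients")
    P0 = _projection(vi, 0.0, X)
    q = float(yi @ P0 @ yi)
    denom = float(np.trace(P0))
    return max(0.0, (q - (k - p)) / denom)


def tau2_pm(effects, X: np.ndarray | None = None) -> float:
    """Paule–Mandel estimator: tau² solving the generalized Q equation
    y'P(tau²)y = k - p, with 0 when even tau²=0 gives Q below its expectation."""
    yi, vi = _as_arrays(effects)
    k = yi.size
    if X is None:
        X = _default_design(k)
    p = X.shape[1]
    if k <= p:
        raise ValueError(f"tau2 undefined: k={k} studies for p={p} coefficients")

    def gen_q(t2: float) -> float:
        return float(yi @ _projection(vi, t2, X) @ yi) - (k - p)

    if gen_q(0.0) <= 0:
        return 0.0
    upper = 10.0 * (np.var(yi) + vi.max()) + 1.0
    while gen_q(upper) > 0:
        upper *= 10.0
        if upper > 1e8:  # pragma: no cover - pathological scale
            return upper
    return float(optimize.brentq(gen_q, 0.0, upper, xtol=1e-12))


def tau2_reml(
    effects,
    X: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> float:
    """REML estimator of tau² by Fisher scoring on the restricted likelihood.

    Score: -tr(P)/2 + y'PPy/2; expected information: tr(PP)/2, with
    P the REML projection at the current tau².  Iterates from the DL start
    until the tau² step is below ``tol`` (non-negativity enforced); falls
    back to DL with a logged warning if ``max_iter`` is exceeded.
    """
    yi, vi = _as_arrays(effects)
    k = yi.size
    if X is None:
        X = _default_design(k)
    if k <= X.shape[1]:
        raise ValueError(f"tau2 undefined: k={k} studies for p={X.shape[1]} coefficients")
    t2 = tau2_dl((yi, vi), X)
    for _ in range(max_iter):
        P = _projection(vi, t2, X)
        Py = P @ yi
        score = -0.5 * float(np.trace(P)) + 0.5 * float(Py @ Py)
        info = 0.5 * float(np.sum(P * P))
        if info <= 0:  # flat likelihood: all variance in vi already
            return t2
        step = score / info
        t2_new = max(0.0, t2 + step)
        if abs(t2_new - t2) < tol:
            return t2_new
        t2 = t2_new
    logger.warning("REML did not converge in %d iterations; falling back to DL", max_iter)
    return tau2_dl((yi, vi), X)


def estimate_tau2(effects, method: str = "REML", X: np.ndarray | None = None) -> float:
    method = method.upper()
    if method not in TAU2_METHODS:
        raise ValueError(f"unknown tau2 method {method!r}; expected one of {TAU2_METHODS}")
    fn = {"REML": tau2_reml, "DL": tau2_dl, "PM": tau2_pm}[method]
    return fn(effects, X=X)


@dataclass(frozen=True)
class MetaResult:
    """Pooled random-effects estimate with Knapp–Hartung inference."""

    mu_hat: float
    se_kh: float
    ci: tuple[float, float]
    p: float
    tau2: float
    tau2_method: str
    Q: float
    Q_p: float
    I2: float
    k: int
    df: float

    @property
    def substantial_heterogeneity(self) -> bool:
        return bool(self.I2 >= I2_SUBSTANTIAL) if not math.isnan(self.I2) else False


def heterogeneity(effects) -> dict[str, float]:
    """Cochran's Q (fixed-effect weights), its chi-square p, and I².

    For a single study these are undefined and returned as NaN.
    """
    yi, vi = _as_arrays(effects)
    k = yi.size
    if k < 2:
        return {"Q": math.nan, "Q_p": math.nan, "I2": math.nan}
    w = 1.0 / vi
    ybar = float(np.sum(w * yi) / np.sum(w))
    q = float(np.sum(w * (yi - ybar) ** 2))
    q_p = float(stats.chi2.sf(q, k - 1))
    i2 = max(0.0, (q - (k - 1)) / q) if q > 0 else 0.0
    return {"Q": q, "Q_p": q_p, "I2": i2}


def pool_random_kh(
    effects,
    tau2_method: str = "REML",
    tau2_override: float | None = None,
    truncate_kh: bool = False,
    alpha: float = ALPHA,
) -> MetaResult:
    """Pool effects under the random-effects model with KH inference.

    mu_hat is the inverse-variance mean with weights 1/(vi + tau2_hat);
    se_kh² = [sum w (yi - mu_hat)² / (k-1)] / sum w; the CI and p use a t
    reference on k-1 df.  ``tau2_override`` fixes tau² (0 recovers the
    fixed-effect mean with KH inference).  With ``truncate_kh`` the KH
    variance is never allowed below the conventional Wald variance 1/sum w.

    A single study returns its own estimate with a normal-theory Wald
    interval and heterogeneity flagged NaN.
    """
    yi, vi = _as_arrays(effects)
    k = yi.size
    if k == 0:
        raise ValueError("cannot pool an empty set of effects")
    if k == 1:
        se = math.sqrt(vi[0])
        z = stats.norm.ppf(1 - alpha / 2)
        mu = float(yi[0])
        return MetaResult(
            mu_hat=mu,
            se_kh=se,
            ci=(mu - z * se, mu + z * se),
            p=float(2 * stats.norm.sf(abs(mu) / se)),
            tau2=math.nan,
            tau2_method="NA",
            Q=math.nan,
            Q_p=math.nan,
            I2=math.nan,
            k=1,
            df=math.nan,
        )
    if tau2_override is not None:
        t2, method_used = float(tau2_override), "fixed"
    else:
        t2, method_used = estimate_tau2((yi, vi), tau2_method), tau2_method.upper()
    w = 1.0 / (vi + t2)
    sw = float(np.sum(w))
    mu = float(np.sum(w * yi) / sw)
    var_kh = float(np.sum(w * (yi - mu) ** 2) / (k - 1)) / sw
    if truncate_kh:
        var_kh = max(var_kh, 1.0 / sw)
    se = math.sqrt(var_kh)
    df = k - 1
    tq = stats.t.ppf(1 - alpha / 2, df)
    if se > 0:
        p = float(2 * stats.t.sf(abs(mu) / se, df))
    else:
        p = 0.0 if mu != 0 else 1.0
    het = heterogeneity((yi, vi))
    return MetaResult(
        mu_hat=mu,
        se_kh=se,
        ci=(mu - tq * se, mu + tq * se),
        p=p,
        tau2=t2,
        tau2_method=method_used,
        Q=het["Q"],
        Q_p=het["Q_p"],
        I2=het["I2"],
        k=k,
        df=df,
    )


def subgroup_analysis(
    effects: Sequence[EffectEstimate],
    labels: Sequence[str],
    level_order: Sequence[str] = ("high", "moderate", "low"),
    tau2_method: str = "REML",
) -> dict[str, MetaResult | None]:
    """Independent random-effects pool per moderator level (own tau² each).

    Levels with zero studies map to None, so empty rows are still reported.
    """
    if len(labels) != len(effects):
        raise ValueError("labels must align with effects")
    labels = [str(l).strip().lower() for l in labels]
    unknown = sorted(set(labels) - set(level_order))
    if unknown:
        raise ValueError(f"unknown moderator level(s): {unknown}")
    out: dict[str, MetaResult | None] = {}
    for level in level_order:
        sub = [e for e, l in zip(effects, labels) if l == level]
        out[level] = pool_random_kh(sub, tau2_method=tau2_method) if sub else None
    return out


@dataclass(frozen=True)
class MetaRegResult:
    """Categorical mixed-effects meta-regression with KH-type inference."""

    coefficients: pd.DataFrame  # term, beta, se, t, p, ci_low, ci_high
    omnibus_stat: float
    omnibus_df: tuple[int, int]
    omnibus_p: float
    tau2_residual: float
    tau2_method: str
    k: int
    reference_level: str
    dropped_levels: list = field(default_factory=list)


def meta_regression_kh(
    effects: Sequence[EffectEstimate] | tuple,
    moderator: Sequence[str],
    reference_level: str = "high",
    level_order: Sequence[str] = ("high", "moderate", "low"),
    tau2_method: str = "REML",
    tau2_override: float | None = None,
    alpha: float = ALPHA,
) -> MetaRegResult:
    """Test whether effect sizes differ across moderator levels.

    Dummy-codes the categorical moderator against ``reference_level``,
    estimates residual tau² under the moderator model, fits weighted least
    squares with w = 1/(vi + tau²), scales the coefficient covariance by the
    KH-type factor s² = sum w e² / (k - p), and reports the omnibus F test
    of the m contrast coefficients on (m, k-p) df.  The omnibus p-value does
    not depend on the reference level.  Levels with zero studies are dropped
    from the design with a log entry.
    """
    yi, vi = _as_arrays(effects)
    k = yi.size
    labels = [str(l).strip().lower() for l in moderator]
    if len(labels) != k:
        raise ValueError("moderator labels must align with effects")
    unknown = sorted(set(labels) - set(level_order))
    if unknown:
        raise ValueError(f"unknown moderator level(s): {unknown}")
    present = [lvl for lvl in level_order if lvl in labels]
    dropped = [lvl for lvl in level_order if lvl not in labels]
    if dropped:
        logger.info("dropping empty moderator level(s) from design: %s", dropped)
    if len(present) < 2:
        raise ValueError("moderator must have at least 2 non-empty levels")
    ref = reference_level.strip().lower()
    if ref not in present:
        ref = present[0]
        logger.info("reference level not present; using %r", ref)
    contrast_levels = [lvl for lvl in present if lvl != ref]
    X = np.column_stack(
        [np.ones(k)] + [[1.0 if l == lvl else 0.0 for l in labels] for lvl in contrast_levels]
    )
    p = X.shape[1]
    m = p - 1
    if k <= p:
        raise ValueError(f"need k > p: k={k}, p={p}")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("singular moderator design")
    if tau2_override is not None:
        t2 = float(tau2_override)
    else:
        t2 = estimate_tau2((yi, vi), tau2_method, X=X)
    w = 1.0 / (vi + t2)
    WX = w[:, None] * X
    XtWX_inv = np.linalg.inv(X.T @ WX)
    beta = XtWX_inv @ (WX.T @ yi)
    resid = yi - X @ beta
    s2 = float(np.sum(w * resid**2) / (k - p))  # KH-type scale, untruncated
    cov = s2 * XtWX_inv
    se = np.sqrt(np.diag(cov))
    tq = stats.t.ppf(1 - alpha / 2, k - p)
    tvals = beta / se
    terms = ["intercept"] + [f"{lvl}_vs_{ref}" for lvl in contrast_levels]
    coef = pd.DataFrame(
        {
            "term": terms,
            "beta": beta,
            "se": se,
            "t": tvals,
            "p": 2 * stats.t.sf(np.abs(tvals), k - p),
            "ci_low": beta - tq * se,
            "ci_high": beta + tq * se,
        }
    )
    bc = beta[1:]
    covc = cov[1:, 1:]
    fstat = float(bc @ np.linalg.solve(covc, bc)) / m
    omnibus_p = float(stats.f.sf(fstat, m, k - p))
    return MetaRegResult(
        coefficients=coef,
        omnibus_stat=fstat,
        omnibus_df=(m, k - p),
        omnibus_p=omnibus_p,
        tau2_residual=t2,
        tau2_method="fixed" if tau2_override is not None else tau2_method.upper(),
        k=k,
        reference_level=ref,
        dropped_levels=dropped,
    )


def significance(p: float, alpha: float = ALPHA) -> bool:
    """Two-sided significance at the 5% level (strict inequality)."""
    if not 0 <= p <= 1:
        raise ValueError(f"p-value {p} outside [0, 1]")
    return p < alpha


def forest_data(effects: Sequence[EffectEstimate], pooled: MetaResult) -> pd.DataFrame:
    """Per-study rows (effect, variance, weight, Wald CI) plus the pooled row."""
    yi, vi = _as_arrays(effects)
    t2 = 0.0 if math.isnan(pooled.tau2) else pooled.tau2
    w = 1.0 / (vi + t2)
    w = w / w.sum()
    z = stats.norm.ppf(0.975)
    rows = pd.DataFrame(
        {
            "study_id": [e.study_id for e in effects],
            "yi": yi,
            "vi": vi,
            "weight": w,
            "ci_low": yi - z * np.sqrt(vi),
            "ci_high": yi + z * np.sqrt(vi),
        }
    )
    pooled_row = pd.DataFrame(
        {
            "study_id": ["POOLED"],
            "yi": [pooled.mu_hat],
            "vi": [pooled.se_kh**2],
            "weight": [np.nan],
            "ci_low": [pooled.ci[0]],
            "ci_high": [pooled.ci[1]],
        }
    )
    return pd.concat([rows, pooled_row], ignore_index=True)
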