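"""Inter-rater reliability for ordinal motivation ratings.

Intraclass correlation coefficients from the two-way ANOVA decomposition of
a subjects x raters score grid, the consensus-as-extra-rater variant, and
rank-based correlations between the three indicators and the overall rating.

Ordinal levels are treated as equally spaced scores 1-3 (the same scale the
equal-weight sensitivity scheme assigns), so the usual mean-square identities
apply directly.  Four ICC forms are exposed; the default is the two-way
random-effects, absolute-agreement, single-rater form ICC(2,1), appropriate
when the raters are regarded as a sample from a larger population of
potential raters.

Interpretation bands: < 0.5 poor, 0.5-0.75 moderate, 0.75-0.9 good,
>= 0.9 excellent.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .rating import INDICATORS, IndicatorProfile, Level

__all__ = [
    "RaterMatrix",
    "ICCResult",
    "ICC_FORMS",
    "anova_mean_squares",
    "icc",
    "interpret_icc",
    "icc_with_consensus",
    "indicator_correlations",
]

logger = logging.getLogger(__name__)

ICC_FORMS = (
    "oneway_1",
    "twoway_random_single",
    "twoway_random_avg",
    "twoway_mixed_single",
)


@dataclass
class RaterMatrix:
    """Subjects x raters grid of ordinal scores in {1, 2, 3}."""

    values: np.ndarray
    subject_ids: list = field(default_factory=list)
    rater_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("rater matrix must be 2-dimensional")
        n, k = self.values.shape
        if not self.subject_ids:
            self.subject_ids = list(range(n))
        if not self.rater_ids:
            self.rater_ids = list(range(k))
        # complete-case: drop subjects with any missing rating
        keep = ~np.isnan(self.values).any(axis=1)
        if not keep.all():
            dropped = [s for s, ok in zip(self.subject_ids, keep) if not ok]
            logger.info(
                "dropping %d subject(s) with missing ratings: %s",
                len(dropped), dropped,
            )
            self.values = self.values[keep]
            self.subject_ids = [s for s, ok in zip(self.subject_ids, keep) if ok]
        if self.values.shape[0] < 2 or self.values.shape[1] < 2:
            raise ValueError(
                "need at least 2 subjects and 2 raters after missing-data "
                f"handling, got shape {self.values.shape}"
            )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_raters(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_frame(cls, wide: pd.DataFrame) -> "RaterMatrix":
        """Build from a wide DataFrame indexed by subject with one column per rater."""
        return cls(
            wide.to_numpy(dtype=float),
            subject_ids=list(wide.index),
            rater_ids=list(wide.columns),
        )

    def with_extra_rater(self, scores: Sequence[float], rater_id="consensus") -> "RaterMatrix":
        scores = np.asarray(scores, dtype=float)
        if scores.shape != (self.n_subjects,):
            raise ValueError(
                f"extra rater has {scores.size} scores for {self.n_subjects} subjects"
            )
        return RaterMatrix(
            np.column_stack([self.values, scores]),
            subject_ids=list(self.subject_ids),
            rater_ids=list(self.rater_ids) + [rater_id],
        )


@dataclass(frozen=True)
class ICCResult:
    value: float
    form: str
    band: str
    mean_squares: tuple[float, float, float]  # (MSR, MSC, MSE)
    n_subjects: int
    n_raters: int


def anova_mean_squares(matrix: RaterMatrix) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares (rows = subjects, columns = raters).

    Returns (MSR, MSC, MSE).  The decomposition is exact:
    SS_total = SS_rows + SS_cols + SS_error.
    """
    x = matrix.values
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_error = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_error / ((n - 1) * (k - 1))
    return msr, msc, mse


def interpret_icc(value: float) -> str:
    """Agreement band for an ICC point estimate."""
    if value < 0.5:
        return "poor"
    if value < 0.75:
        return "moderate"
    if value < 0.9:
        return "good"
    return "excellent"


def icc(matrix: RaterMatrix, form: str = "twoway_random_single") -> ICCResult:
    """Intraclass correlation of a subjects x raters score grid.

    Forms (Shrout & Fleiss numbering):

    * ``twoway_random_single`` — ICC(2,1), absolute agreement, default:
      ``(MSR-MSE) / (MSR + (k-1)MSE + k(MSC-MSE)/n)``
    * ``twoway_mixed_single`` — ICC(3,1), consistency:
      ``(MSR-MSE) / (MSR + (k-1)MSE)``
    * ``twoway_random_avg`` — ICC(2,k): ``(MSR-MSE) / (MSR + (MSC-MSE)/n)``
    * ``oneway_1`` — ICC(1,1) from the one-way decomposition.

    A grid with no variance anywhere (every cell identical) is perfect
    agreement by construction; it is returned as 1.0 with a logged note
    rather than raising on the 0/0 form.
    """
    if form not in ICC_FORMS:
        raise ValueError(f"unknown ICC form {form!r}; expected one of {ICC_FORMS}")
    x = matrix.values
    n, k = x.shape
    msr, msc, mse = anova_mean_squares(matrix)
    if form == "oneway_1":
        ss_rows = msr * (n - 1)
        ss_total = float(((x - x.mean()) ** 2).sum())
        msw = (ss_total - ss_rows) / (n * (k - 1))
        num, den = msr - msw, msr + (k - 1) * msw
    elif form == "twoway_random_single":
        num = msr - mse
        den = msr + (k - 1) * mse + k * (msc - mse) / n
    elif form == "twoway_mixed_single":
        num = msr - mse
        den = msr + (k - 1) * mse
    else:  # twoway_random_avg
        num = msr - mse
        den = msr + (msc - mse) / n
    if den == 0.0:
        logger.info(
            "ICC denominator is zero (all %d x %d cells identical); "
            "returning 1.0 by convention", n, k,
        )
        value = 1.0
    else:
        value = num / den
    return ICCResult(
        value=value,
        form=form,
        band=interpret_icc(value),
        mean_squares=(msr, msc, mse),
        n_subjects=n,
        n_raters=k,
    )


def icc_with_consensus(
    matrix: RaterMatrix,
    consensus: Sequence[float],
    form: str = "twoway_random_single",
) -> ICCResult:
    """ICC treating the consensus rating as an additional rater column."""
    return icc(matrix.with_extra_rater(consensus), form=form)


def indicator_correlations(
    profiles: Sequence[IndicatorProfile],
    overall: Sequence[Level],
    method: str = "spearman",
) -> tuple[pd.DataFrame, pd.Series]:
    """Correlations among the three indicators and of each with the overall rating.

    Rank-based (Spearman) by default on the 1-3 scores; Pearson by flag.
    Returns the symmetric 3x3 indicator correlation matrix and a Series of the
    three indicator-vs-overall correlations.  Pairs involving a zero-variance
    dimension are reported as NaN with a logged note.
    """
    if len(profiles) < 3:
        raise ValueError("need at least 3 profiles for correlations")
    if len(overall) != len(profiles):
        raise ValueError("overall ratings must align with profiles")
    corr_fn = {"spearman": stats.spearmanr, "pearson": stats.pearsonr}[method]
    cols = {
        name: np.array([getattr(p, name) for p in profiles], dtype=float)
        for name in INDICATORS
    }
    cols["overall"] = np.array([int(Level.from_label(o)) for o in overall], dtype=float)

    def pair(a: str, b: str) -> float:
        if np.ptp(cols[a]) == 0 or np.ptp(cols[b]) == 0:
            logger.info("correlation %s~%s undefined (zero variance)", a, b)
            return np.nan
        return float(corr_fn(cols[a], cols[b])[0])

    matrix = pd.DataFrame(
        [[1.0 if a == b else pair(a, b) for b in INDICATORS] for a in INDICATORS],
        index=list(INDICATORS),
        columns=list(INDICATORS),
    )
    vs_overall = pd.Series(
        {name: pair(name, "overall") for name in INDICATORS}, name="overall"
    )
    return matrix, vs_overall
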