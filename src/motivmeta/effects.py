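"""Per-study effect estimates from arm-level summaries.

Continuous outcomes (quality of life, anxiety, depression) are expressed as
standardized mean differences — Hedges g by default, i.e. Cohen d with the
small-sample correction factor J = 1 - 3/(4*df - 1) — with the usual
large-sample variance.  Attrition is expressed as the log risk ratio of
dropout proportions (intervention over control).

This module also implements the extraction conventions applied before an
effect is computed: recovering a missing SD from a standard error or a
confidence interval, carrying a baseline SD forward when the post SD is
unrecoverable, choosing among multiple measurement tools by lowest
attrition, and choosing the first post-intervention timepoint (or the
longest follow-up when the intervention period is unclear).  Every such
decision leaves a provenance entry in the module log and in the estimate's
``detail`` dict.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

from scipy import stats

__all__ = [
    "ContinuousArm",
    "BinaryArm",
    "EffectEstimate",
    "InestimableEffect",
    "smd",
    "recover_sd",
    "carry_forward_sd",
    "resolve_sd",
    "log_rr",
    "Measurement",
    "Timepoint",
    "select_measurement",
    "select_timepoint",
]

logger = logging.getLogger(__name__)


class InestimableEffect(Exception):
    """A study whose effect cannot be computed from the available data."""


@dataclass
class ContinuousArm:
    """Arm-level summary of a continuous outcome."""

    n: int
    mean: float
    sd: float | None = None
    se: float | None = None
    ci: tuple[float, float] | None = None
    ci_level: float = 0.95
    baseline_sd: float | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"arm n must be >= 2, got {self.n}")
        if self.sd is not None and self.sd <= 0:
            raise ValueError(f"arm sd must be positive, got {self.sd}")


@dataclass
class BinaryArm:
    """Arm-level dropout count out of n randomized."""

    events: int
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("arm n must be >= 1")
        if not 0 <= self.events <= self.n:
            raise ValueError(f"events {self.events} outside [0, {self.n}]")


@dataclass
class EffectEstimate:
    """One study's effect value and sampling variance, the atom of pooling."""

    study_id: str
    yi: float
    vi: float
    measure: str  # "smd" or "log_rr"
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.vi <= 0:
            raise ValueError(f"sampling variance must be positive, got {self.vi}")
        if self.measure not in ("smd", "log_rr"):
            raise ValueError(f"unknown measure {self.measure!r}")


def recover_sd(arm: ContinuousArm) -> tuple[float, str]:
    """Recover a missing SD from the standard error or the arm-mean CI.

    From SE: ``sd = se * sqrt(n)``.  From a two-sided CI of the arm mean at
    ``arm.ci_level``: ``sd = sqrt(n) * (high - low) / (2 * z)`` with z the
    normal quantile.  Returns (sd, method); raises :class:`InestimableEffect`
    when neither field is usable.
    """
    if arm.se is not None:
        sd = arm.se * math.sqrt(arm.n)
        logger.info("recovered sd=%.6g from se=%.6g (n=%d)", sd, arm.se, arm.n)
        return sd, "from_se"
    if arm.ci is not None:
        low, high = arm.ci
        if high <= low:
            raise ValueError(f"degenerate CI ({low}, {high})")
        z = stats.norm.ppf(0.5 + arm.ci_level / 2)
        sd = math.sqrt(arm.n) * (high - low) / (2 * z)
        logger.info(
            "recovered sd=%.6g from %.0f%% CI (%.6g, %.6g), n=%d",
            sd, 100 * arm.ci_level, low, high, arm.n,
        )
        return sd, "from_ci"
    raise InestimableEffect("no se or ci available to recover sd")


def carry_forward_sd(arm: ContinuousArm) -> ContinuousArm:
    """Use the baseline SD as the post-intervention SD when the latter is missing.

    Fires only when ``sd`` is absent; an arm with a usable SD is returned
    unchanged.
    """
    if arm.sd is not None:
        return arm
    if arm.baseline_sd is None:
        raise InestimableEffect("sd missing and no baseline_sd to carry forward")
    logger.info("carrying baseline sd=%.6g forward as post sd", arm.baseline_sd)
    return replace(arm, sd=arm.baseline_sd)


def resolve_sd(arm: ContinuousArm) -> tuple[ContinuousArm, str]:
    """Full SD-recovery chain: direct -> from se -> from ci -> baseline carry-forward.

    Returns the arm with ``sd`` populated and the provenance tag of the step
    that supplied it; raises :class:`InestimableEffect` if every step fails.
    """
    if arm.sd is not None:
        return arm, "reported"
    try:
        sd, method = recover_sd(arm)
        return replace(arm, sd=sd), method
    except InestimableEffect:
        return carry_forward_sd(arm), "baseline_carry_forward"


def smd(
    treat: ContinuousArm,
    ctrl: ContinuousArm,
    hedges_correction: bool = True,
    sign_convention: int = 1,
    study_id: str = "",
) -> EffectEstimate:
    """Standardized mean difference between arms with its sampling variance.

    d = (mean_t - mean_c) / s_pooled, with the pooled SD over both arms.
    With ``hedges_correction`` (default) the estimate is g = J*d,
    J = 1 - 3/(4*(n_t+n_c-2) - 1).  Variance:
    vi = (n_t+n_c)/(n_t*n_c) + yi^2 / (2*(n_t+n_c)).
    ``sign_convention`` (+1/-1) is per-outcome metadata multiplying yi, so a
    positive pooled value can always be read as favouring the intervention.
    """
    if treat.sd is None or ctrl.sd is None:
        raise InestimableEffect(
            f"study {study_id!r}: SMD needs SDs in both arms (run resolve_sd first)"
        )
    if sign_convention not in (1, -1):
        raise ValueError("sign_convention must be +1 or -1")
    nt, nc = treat.n, ctrl.n
    df = nt + nc - 2
    s_pooled = math.sqrt(((nt - 1) * treat.sd**2 + (nc - 1) * ctrl.sd**2) / df)
    if s_pooled == 0:
        raise InestimableEffect(f"study {study_id!r}: zero pooled SD")
    d = (treat.mean - ctrl.mean) / s_pooled
    j = 1 - 3 / (4 * df - 1)
    g = j * d if hedges_correction else d
    vi = (nt + nc) / (nt * nc) + g**2 / (2 * (nt + nc))
    return EffectEstimate(
        study_id=study_id,
        yi=sign_convention * g,
        vi=vi,
        measure="smd",
        detail={"d": d, "J": j, "hedges": hedges_correction},
    )


def log_rr(
    treat: BinaryArm,
    ctrl: BinaryArm,
    zero_cell_policy: str = "add_half",
    study_id: str = "",
) -> EffectEstimate:
    """Log risk ratio of dropout proportions (intervention over control).

    yi = ln((a/n_t)/(c/n_c)); vi = 1/a - 1/n_t + 1/c - 1/n_c.  Under the
    ``add_half`` policy a single zero event cell triggers the continuity
    correction: 0.5 is added to both event counts and 1 to both denominators
    before computing.  Studies with zero events in both arms are inestimable.
    """
    a, n1, c, n2 = float(treat.events), float(treat.n), float(ctrl.events), float(ctrl.n)
    cc_applied = False
    if a == 0 and c == 0:
        raise InestimableEffect(f"study {study_id!r}: zero dropouts in both arms")
    if a == 0 or c == 0:
        if zero_cell_policy == "add_half":
            a, c, n1, n2 = a + 0.5, c + 0.5, n1 + 1, n2 + 1
            cc_applied = True
            logger.info("study %r: continuity correction applied (single zero cell)", study_id)
        else:
            raise InestimableEffect(
                f"study {study_id!r}: zero event cell under policy {zero_cell_policy!r}"
            )
    yi = math.log((a / n1) / (c / n2))
    vi = 1 / a - 1 / n1 + 1 / c - 1 / n2
    if vi <= 0:  # both arms all-events; no sampling variability on the log scale
        raise InestimableEffect(f"study {study_id!r}: degenerate risk-ratio variance")
    return EffectEstimate(
        study_id=study_id,
        yi=yi,
        vi=vi,
        measure="log_rr",
        detail={"cc_applied": cc_applied},
    )


@dataclass(frozen=True)
class Measurement:
    """One candidate measurement tool for an outcome within a study."""

    measure_name: str
    attrition_fraction: float
    data: object = None


@dataclass(frozen=True)
class Timepoint:
    """One candidate assessment timepoint within a study."""

    label: str
    post_intervention_order: int | None  # 1 = first post-intervention assessment
    followup_weeks: float


def select_measurement(candidates: Sequence[Measurement]) -> Measurement:
    """Pick the measurement tool with the lowest attrition; ties keep input order."""
    if not candidates:
        raise ValueError("no candidate measurements")
    best = min(candidates, key=lambda m: m.attrition_fraction)
    ties = [m for m in candidates if m.attrition_fraction == best.attrition_fraction]
    if len(ties) > 1:
        logger.info(
            "measurement tie at attrition %.3f among %s; keeping first-listed %r",
            best.attrition_fraction, [m.measure_name for m in ties], best.measure_name,
        )
    return best


def select_timepoint(
    timepoints: Sequence[Timepoint], intervention_period_known: bool
) -> Timepoint:
    """First post-intervention timepoint, or longest follow-up if the period is unclear."""
    if not timepoints:
        raise ValueError("no candidate timepoints")
    if intervention_period_known:
        post = [t for t in timepoints if t.post_intervention_order is not None]
        if not post:
            raise ValueError("intervention period known but no post-intervention timepoint")
        return min(post, key=lambda t: t.post_intervention_order)
    return max(timepoints, key=lambda t: t.followup_weeks)
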