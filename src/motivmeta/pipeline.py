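"""End-to-end moderator meta-analysis of a trial corpus.

Ingests the long-format studies table and the per-rater ratings table,
applies the extraction conventions (lowest-attrition measurement, first
post-intervention timepoint, SD recovery), rates each study's overall
motivation from the consensus indicator profile, and produces one outcome
table per outcome: the all-studies pooled row, subgroup rows (high /
moderate / low) for the overall rating and for each single indicator, and
the omnibus meta-regression p-value per moderator.  Attrition tables are
back-transformed to the risk-ratio scale.  A sensitivity run re-classifies
every study under the equal-weight sum scheme and repeats all tables.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import effects as eff
from . import meta
from .rating import (
    INDICATORS,
    IndicatorProfile,
    Level,
    combine_equal_sum,
    combine_tree,
    score_to_level,
)
from .reliability import ICCResult, RaterMatrix, icc, icc_with_consensus

__all__ = [
    "AnalysisConfig",
    "OutcomeTable",
    "consensus_profiles",
    "overall_levels",
    "compute_outcome_effects",
    "run_outcome_analysis",
    "analyze",
    "sensitivity_reweight",
    "run_reliability_report",
    "render_table",
]

logger = logging.getLogger(__name__)

OUTCOMES = ("qol", "anxiety", "depression", "attrition")
MODERATORS = ("overall", "expectation", "effort", "bond")
LEVELS = ("high", "moderate", "low")


@dataclass
class AnalysisConfig:
    """Knobs of the full analysis; defaults follow the primary analysis."""

    scheme: str = "tree"
    tau2_method: str = "REML"
    hedges_correction: bool = True
    zero_cell_policy: str = "add_half"
    alpha: float = 0.05
    outcomes: tuple[str, ...] = OUTCOMES
    sign_conventions: dict = field(
        default_factory=lambda: {"qol": 1, "anxiety": 1, "depression": 1}
    )
    seed: int = 0
    rule_table: Mapping | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.scheme not in ("tree", "equal_sum"):
            raise ValueError(f"unknown scheme {self.scheme!r}")


@dataclass
class OutcomeTable:
    """One outcome's pooled, subgroup and meta-regression results.

    ``data`` columns: moderator, level, k, estimate, ci_low, ci_high,
    i2, het_p, metareg_p.  For attrition the estimate and CI are on the
    risk-ratio scale (exp of the pooled log-RR).
    """

    outcome: str
    measure: str  # "smd" or "rr"
    data: pd.DataFrame
    n_inestimable: int = 0


def _combine(profile: IndicatorProfile, scheme: str, rule_table=None) -> Level:
    if scheme == "tree":
        return combine_tree(profile, rule_table).level
    return combine_equal_sum(profile).level


def consensus_profiles(ratings: pd.DataFrame) -> dict[str, IndicatorProfile]:
    """Consensus indicator profile per study.

    Uses the ``rater_id == "consensus"`` row when present; otherwise
    synthesizes one as the per-indicator median across raters with ties
    resolved toward the lower level (the low median of the sorted scores).
    The deliberative consensus of a real rating exercise is not an
    algorithm; the synthesizer is an explicit stand-in and is logged.
    """
    out: dict[str, IndicatorProfile] = {}
    for study_id, grp in ratings.groupby("study_id", sort=True):
        cons = grp[grp["rater_id"] == "consensus"]
        if len(cons):
            row = cons.iloc[0]
            out[str(study_id)] = IndicatorProfile.from_labels(
                row["expectation"], row["effort"], row["bond"]
            )
            continue
        logger.info("study %s: no consensus row; synthesizing low-median consensus", study_id)
        scores = {}
        for ind in INDICATORS:
            vals = sorted(int(Level.from_label(v)) for v in grp[ind])
            scores[ind] = vals[(len(vals) - 1) // 2]  # low median: ties go down
        out[str(study_id)] = IndicatorProfile(
            score_to_level(scores["expectation"]),
            score_to_level(scores["effort"]),
            score_to_level(scores["bond"]),
        )
    return out


def overall_levels(
    profiles: Mapping[str, IndicatorProfile], scheme: str, rule_table=None
) -> dict[str, Level]:
    return {sid: _combine(p, scheme, rule_table) for sid, p in profiles.items()}


def _arm_from_row(row: pd.Series) -> eff.ContinuousArm:
    def val(name):
        v = row.get(name)
        return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)

    ci = None
    if val("ci_low") is not None and val("ci_high") is not None:
        ci = (val("ci_low"), val("ci_high"))
    return eff.ContinuousArm(
        n=int(row["n"]),
        mean=float(row["mean"]),
        sd=val("sd"),
        se=val("se"),
        ci=ci,
        baseline_sd=val("baseline_sd"),
    )


def _select_rows(grp: pd.DataFrame) -> pd.DataFrame:
    """Apply measurement-tool and timepoint selection to one study's rows."""
    # lowest-attrition measurement tool
    measures = [
        eff.Measurement(
            measure_name=str(name),
            attrition_fraction=float(sub["attrition_fraction"].iloc[0])
            if not pd.isna(sub["attrition_fraction"].iloc[0])
            else 0.0,
        )
        for name, sub in grp.groupby("measure_name", sort=False)
    ]
    chosen = eff.select_measurement(measures)
    grp = grp[grp["measure_name"] == chosen.measure_name]
    # first post-intervention timepoint, else longest follow-up
    tps = []
    for label, sub in grp.groupby("timepoint_label", sort=False):
        order = sub["post_intervention_order"].iloc[0]
        tps.append(
            eff.Timepoint(
                label=str(label),
                post_intervention_order=None if pd.isna(order) else int(order),
                followup_weeks=float(sub["followup_weeks"].iloc[0]),
            )
        )
    known = any(t.post_intervention_order is not None for t in tps)
    chosen_tp = eff.select_timepoint(tps, intervention_period_known=known)
    return grp[grp["timepoint_label"] == chosen_tp.label]


def compute_outcome_effects(
    studies: pd.DataFrame, outcome: str, config: AnalysisConfig
) -> tuple[list[eff.EffectEstimate], list[str]]:
    """Per-study effect estimates for one outcome, with an exclusion log."""
    subset = studies[studies["outcome"] == outcome]
    estimates: list[eff.EffectEstimate] = []
    excluded: list[str] = []
    for study_id, grp in subset.groupby("study_id", sort=True):
        sid = str(study_id)
        try:
            rows = _select_rows(grp)
            tr = rows[rows["arm"] == "intervention"].iloc[0]
            ct = rows[rows["arm"] == "control"].iloc[0]
            if outcome == "attrition":
                est = eff.log_rr(
                    eff.BinaryArm(int(tr["events"]), int(tr["n"])),
                    eff.BinaryArm(int(ct["events"]), int(ct["n"])),
                    zero_cell_policy=config.zero_cell_policy,
                    study_id=sid,
                )
            else:
                arm_t, prov_t = eff.resolve_sd(_arm_from_row(tr))
                arm_c, prov_c = eff.resolve_sd(_arm_from_row(ct))
                est = eff.smd(
                    arm_t,
                    arm_c,
                    hedges_correction=config.hedges_correction,
                    sign_convention=config.sign_conventions.get(outcome, 1),
                    study_id=sid,
                )
                est.detail["sd_provenance"] = (prov_t, prov_c)
            estimates.append(est)
        except eff.InestimableEffect as exc:
            logger.info("excluding study %s from %s: %s", sid, outcome, exc)
            excluded.append(sid)
    return estimates, excluded


def _moderator_labels(
    estimates: Sequence[eff.EffectEstimate],
    profiles: Mapping[str, IndicatorProfile],
    moderator: str,
    scheme: str,
    rule_table=None,
) -> list[str]:
    missing = [e.study_id for e in estimates if e.study_id not in profiles]
    if missing:
        raise ValueError(f"no consensus rating for study id(s): {missing}")
    labels = []
    for e in estimates:
        profile = profiles[e.study_id]
        if moderator == "overall":
            labels.append(_combine(profile, scheme, rule_table).label)
        else:
            labels.append(getattr(profile, moderator).label)
    return labels


def _table_row(moderator, level, res: meta.MetaResult | None, metareg_p, k_override=None, rr=False):
    if res is None:
        return {
            "moderator": moderator, "level": level, "k": 0,
            "estimate": np.nan, "ci_low": np.nan, "ci_high": np.nan,
            "i2": np.nan, "het_p": np.nan, "metareg_p": metareg_p,
        }
    tf = math.exp if rr else (lambda x: x)
    return {
        "moderator": moderator,
        "level": level,
        "k": res.k if k_override is None else k_override,
        "estimate": tf(res.mu_hat),
        "ci_low": tf(res.ci[0]),
        "ci_high": tf(res.ci[1]),
        "i2": res.I2,
        "het_p": res.Q_p,
        "metareg_p": metareg_p,
    }


def run_outcome_analysis(
    studies: pd.DataFrame,
    ratings: pd.DataFrame,
    config: AnalysisConfig,
    outcome: str,
) -> OutcomeTable:
    """Pooled + subgroup + meta-regression table for one outcome."""
    measure = "rr" if outcome == "attrition" else "smd"
    estimates, excluded = compute_outcome_effects(studies, outcome, config)
    if not estimates:
        logger.info("outcome %s absent from all studies; emitting empty table", outcome)
        return OutcomeTable(outcome, measure, pd.DataFrame(
            columns=["moderator", "level", "k", "estimate", "ci_low", "ci_high",
                     "i2", "het_p", "metareg_p"]), n_inestimable=len(excluded))
    profiles = consensus_profiles(ratings)
    rr = measure == "rr"
    rows = [
        _table_row(
            "all", "all",
            meta.pool_random_kh(estimates, tau2_method=config.tau2_method),
            np.nan, rr=rr,
        )
    ]
    for moderator in MODERATORS:
        labels = _moderator_labels(
            estimates, profiles, moderator, config.scheme, config.rule_table
        )
        try:
            reg = meta.meta_regression_kh(
                estimates, labels, tau2_method=config.tau2_method, alpha=config.alpha
            )
            metareg_p = reg.omnibus_p
        except ValueError as exc:
            logger.info("meta-regression skipped for %s/%s: %s", outcome, moderator, exc)
            metareg_p = np.nan
        sub = meta.subgroup_analysis(estimates, labels, tau2_method=config.tau2_method)
        for level in LEVELS:
            rows.append(_table_row(moderator, level, sub[level], metareg_p, rr=rr))
    return OutcomeTable(outcome, measure, pd.DataFrame(rows), n_inestimable=len(excluded))


def analyze(
    studies: pd.DataFrame, ratings: pd.DataFrame, config: AnalysisConfig
) -> dict[str, OutcomeTable]:
    """All configured outcome tables."""
    return {
        outcome: run_outcome_analysis(studies, ratings, config, outcome)
        for outcome in config.outcomes
    }


def sensitivity_reweight(
    studies: pd.DataFrame, ratings: pd.DataFrame, config: AnalysisConfig
) -> dict:
    """Equal-weight re-analysis: reclassification cross-tab + re-run tables.

    Cross-tabulates the weighted-rule overall level against the equal-sum
    level per study, then repeats every outcome table under the equal-sum
    scheme.
    """
    profiles = consensus_profiles(ratings)
    order = [lvl.label for lvl in reversed(Level)]
    crosstab = pd.DataFrame(0, index=order, columns=order)
    crosstab.index.name = "tree"
    crosstab.columns.name = "equal_sum"
    for p in profiles.values():
        crosstab.loc[
            combine_tree(p, config.rule_table).level.label,
            combine_equal_sum(p).level.label,
        ] += 1
    from dataclasses import replace
    eq_config = replace(config, scheme="equal_sum")
    return {"crosstab": crosstab, "tables": analyze(studies, ratings, eq_config)}


def _rater_grid(ratings: pd.DataFrame, dimension: str, scheme: str, rule_table=None) -> pd.DataFrame:
    """Wide subjects x raters grid of 1-3 scores for one rated dimension."""
    raters = ratings[ratings["rater_id"] != "consensus"]
    if dimension == "overall":
        def score(row):
            profile = IndicatorProfile.from_labels(
                row["expectation"], row["effort"], row["bond"]
            )
            return int(_combine(profile, scheme, rule_table))
        values = raters.apply(score, axis=1)
    else:
        values = raters[dimension].map(lambda v: int(Level.from_label(v)))
    wide = raters.assign(score=values).pivot(
        index="study_id", columns="rater_id", values="score"
    )
    return wide.sort_index()


def run_reliability_report(
    ratings: pd.DataFrame,
    scheme: str = "tree",
    rule_table=None,
    form: str = "twoway_random_single",
) -> pd.DataFrame:
    """ICC per rated dimension, with and without the consensus as extra rater.

    Rows: overall + the three indicators, each in a "raters" variant (the
    independent raters only) and, when a consensus row exists, a
    "with_consensus" variant treating the consensus as one more rater.
    """
    if ratings[ratings["rater_id"] != "consensus"]["rater_id"].nunique() < 2:
        raise ValueError("reliability report needs at least 2 independent raters")
    has_consensus = (ratings["rater_id"] == "consensus").any()
    cons = ratings[ratings["rater_id"] == "consensus"].set_index("study_id")
    rows = []
    for dimension in ("overall",) + INDICATORS:
        wide = _rater_grid(ratings, dimension, scheme, rule_table)
        matrix = RaterMatrix.from_frame(wide)
        results: list[tuple[str, ICCResult]] = [("raters", icc(matrix, form=form))]
        if has_consensus:
            if dimension == "overall":
                cons_scores = [
                    int(_combine(IndicatorProfile.from_labels(
                        cons.loc[sid, "expectation"],
                        cons.loc[sid, "effort"],
                        cons.loc[sid, "bond"],
                    ), scheme, rule_table))
                    for sid in matrix.subject_ids
                ]
            else:
                cons_scores = [
                    int(Level.from_label(cons.loc[sid, dimension]))
                    for sid in matrix.subject_ids
                ]
            results.append(
                ("with_consensus", icc_with_consensus(matrix, cons_scores, form=form))
            )
        for variant, res in results:
            rows.append(
                {
                    "dimension": dimension,
                    "variant": variant,
                    "icc": res.value,
                    "band": res.band,
                    "form": res.form,
                    "n_subjects": res.n_subjects,
                    "n_raters": res.n_raters,
                }
            )
    return pd.DataFrame(rows)


def render_table(table: OutcomeTable, decimals: int = 2) -> pd.DataFrame:
    """Rendered (rounded) view of an outcome table; JSON export keeps full precision."""
    out = table.data.copy()
    for col in ("estimate", "ci_low", "ci_high", "metareg_p", "het_p"):
        out[col] = out[col].round(decimals + 1 if col.endswith("_p") else decimals)
    out["i2"] = (100 * out["i2"]).round(0)
    return out


def tables_to_json(tables: Mapping[str, OutcomeTable]) -> str:
    payload = {
        name: {
            "measure": t.measure,
            "n_inestimable": t.n_inestimable,
            "rows": json.loads(t.data.to_json(orient="records")),
        }
        for name, t in tables.items()
    }
    return json.dumps(payload, indent=2, sort_keys=True)


def run_manifest(config: AnalysisConfig, extra: Mapping | None = None) -> dict:
    manifest = {"config": {k: v for k, v in asdict(config).items() if k != "rule_table"}}
    if extra:
        manifest.update(extra)
    return manifest
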