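"""Synthetic trial corpora with the structure the moderator meta-analysis assumes.

The generator emulates a corpus of two-arm randomized trials of digital
health interventions whose true effects differ by a latent study-level
motivation category:

* each study gets a latent overall motivation level (high/moderate/low) and
  an indicator triple drawn uniformly from the triples that map to that
  level under the weighted decision rule;
* the true standardized effect of each continuous outcome is
  ``theta = mu_by_level[level] + N(0, tau2)`` (a normal random effect);
  individual participant outcomes are then drawn and *summarized* to
  per-arm n/mean/SD, so means and SDs carry realistic finite-sample error;
* attrition events are binomial with control risk ``p0 ~ U(p0_range)`` and
  intervention risk ``p0 * exp(log_rr_by_level[level] + N(0, tau2))``;
* a configurable fraction of studies has the post SD blanked and replaced
  by a standard error, a 95% CI, or nothing but a baseline SD — exercising
  every SD-recovery path of the extraction rules;
* raters reproduce each latent indicator level independently with
  probability ``rater_agreement``; errors go to an adjacent level (boundary
  levels flip inward), and a consensus row records the latent truth.

Everything is deterministic given ``seed``; the returned manifest records
every latent draw so engine output can be compared to generator truth.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .effects import EffectEstimate
from .rating import Level, IndicatorProfile, all_profiles, combine_tree

__all__ = [
    "SimConfig",
    "simulate_studies",
    "simulate_rater_matrix",
    "simulate_corpus",
    "simulate_meta_effects",
]

CONTINUOUS_OUTCOMES = ("qol", "anxiety", "depression")


def _default_k_per_level() -> dict[str, int]:
    # mirrors the observed overall-motivation distribution of the rated corpus
    return {"high": 19, "moderate": 5, "low": 3}


def _default_mu_by_level() -> dict[str, float]:
    return {"high": 0.4, "moderate": 0.2, "low": 0.0}


def _default_log_rr_by_level() -> dict[str, float]:
    return {"high": math.log(1.6), "moderate": math.log(1.5), "low": math.log(1.2)}


@dataclass
class SimConfig:
    """Generative parameters of the synthetic corpus."""

    k_per_level: dict[str, int] = field(default_factory=_default_k_per_level)
    mu_by_level: dict[str, float] = field(default_factory=_default_mu_by_level)
    tau2: float = 0.04
    arm_n_range: tuple[int, int] = (30, 150)
    ctrl_sd: float = 1.0
    p0_range: tuple[float, float] = (0.10, 0.30)
    log_rr_by_level: dict[str, float] = field(default_factory=_default_log_rr_by_level)
    rater_agreement: float = 0.8
    n_raters: int = 4
    missing_sd_fraction: float = 0.15
    outcomes: tuple[str, ...] = ("qol", "anxiety", "depression", "attrition")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")
        if self.arm_n_range[0] < 10:
            raise ValueError("minimum arm size must be >= 10")
        if self.arm_n_range[0] > self.arm_n_range[1]:
            raise ValueError("arm_n_range must be (min, max) with min <= max")
        for prob in (self.rater_agreement, self.missing_sd_fraction, *self.p0_range):
            if not 0 <= prob <= 1:
                raise ValueError(f"probability {prob} outside [0, 1]")
        for level in ("high", "moderate", "low"):
            if level not in self.k_per_level:
                raise ValueError(f"k_per_level missing level {level!r}")


def _profiles_by_level() -> dict[str, list[IndicatorProfile]]:
    groups: dict[str, list[IndicatorProfile]] = {"high": [], "moderate": [], "low": []}
    for profile in all_profiles():
        groups[combine_tree(profile).level.label].append(profile)
    return groups


def _summarize_arm(draws: np.ndarray) -> tuple[float, float]:
    return float(draws.mean()), float(draws.std(ddof=1))


def simulate_studies(config: SimConfig) -> tuple[pd.DataFrame, dict]:
    """Generate the long-format studies table and the latent-truth manifest."""
    rng = np.random.default_rng(config.seed)
    groups = _profiles_by_level()
    studies: list[dict] = []
    manifest_studies: list[dict] = []
    sd_modes = ("se", "ci", "baseline_only")
    idx = 0
    for level in ("high", "moderate", "low"):
        for _ in range(config.k_per_level[level]):
            idx += 1
            study_id = f"S{idx:03d}"
            profile = groups[level][rng.integers(len(groups[level]))]
            n_t = int(rng.integers(config.arm_n_range[0], config.arm_n_range[1] + 1))
            n_c = int(rng.integers(config.arm_n_range[0], config.arm_n_range[1] + 1))
            blank_sd = rng.random() < config.missing_sd_fraction
            sd_mode = sd_modes[idx % 3] if blank_sd else "reported"
            record: dict = {
                "study_id": study_id,
                "level": level,
                "profile": [l.label for l in (profile.expectation, profile.effort, profile.bond)],
                "n_t": n_t,
                "n_c": n_c,
                "sd_mode": sd_mode,
                "theta": {},
            }
            for outcome in config.outcomes:
                if outcome == "attrition":
                    continue
                theta = config.mu_by_level[level] + rng.normal(0.0, math.sqrt(config.tau2))
                record["theta"][outcome] = theta
                draws_t = rng.normal(theta * config.ctrl_sd, config.ctrl_sd, size=n_t)
                draws_c = rng.normal(0.0, config.ctrl_sd, size=n_c)
                base_t = rng.normal(0.0, config.ctrl_sd, size=n_t)
                base_c = rng.normal(0.0, config.ctrl_sd, size=n_c)
                for arm, draws, base, n in (
                    ("intervention", draws_t, base_t, n_t),
                    ("control", draws_c, base_c, n_c),
                ):
                    mean, sd = _summarize_arm(draws)
                    _, baseline_sd = _summarize_arm(base)
                    row = {
                        "study_id": study_id,
                        "outcome": outcome,
                        "arm": arm,
                        "n": n,
                        "mean": mean,
                        "sd": sd,
                        "se": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "baseline_sd": baseline_sd,
                        "events": np.nan,
                        "timepoint_label": "post",
                        "post_intervention_order": 1,
                        "followup_weeks": 12.0,
                        "attrition_fraction": np.nan,
                        "measure_name": f"{outcome}_scale",
                    }
                    if sd_mode == "se":
                        row["sd"] = np.nan
                        row["se"] = sd / math.sqrt(n)
                    elif sd_mode == "ci":
                        row["sd"] = np.nan
                        half = 1.959963984540054 * sd / math.sqrt(n)
                        row["ci_low"] = mean - half
                        row["ci_high"] = mean + half
                    elif sd_mode == "baseline_only":
                        row["sd"] = np.nan
                    studies.append(row)
            if "attrition" in config.outcomes:
                p0 = float(rng.uniform(*config.p0_range))
                log_theta = config.log_rr_by_level[level] + rng.normal(
                    0.0, math.sqrt(config.tau2)
                )
                p1 = p0 * math.exp(log_theta)
                if p1 >= 1.0:
                    raise ValueError(
                        f"infeasible attrition risk {p1:.3f} >= 1 in study {study_id}"
                    )
                e_t = int(rng.binomial(n_t, p1))
                e_c = int(rng.binomial(n_c, p0))
                record["p0"] = p0
                record["log_rr"] = log_theta
                record["events"] = {"intervention": e_t, "control": e_c}
                frac = (e_t + e_c) / (n_t + n_c)
                for arm, ev, n in (("intervention", e_t, n_t), ("control", e_c, n_c)):
                    studies.append(
                        {
                            "study_id": study_id,
                            "outcome": "attrition",
                            "arm": arm,
                            "n": n,
                            "mean": np.nan,
                            "sd": np.nan,
                            "se": np.nan,
                            "ci_low": np.nan,
                            "ci_high": np.nan,
                            "baseline_sd": np.nan,
                            "events": ev,
                            "timepoint_label": "post",
                            "post_intervention_order": 1,
                            "followup_weeks": 12.0,
                            "attrition_fraction": frac,
                            "measure_name": "dropout",
                        }
                    )
                # measurement-tool selection keys off attrition, carried on all rows
                for row in studies:
                    if row["study_id"] == study_id:
                        row["attrition_fraction"] = frac
            manifest_studies.append(record)
    frame = pd.DataFrame(studies)
    manifest = {"config": asdict(config), "studies": manifest_studies}
    return frame, manifest


def simulate_rater_matrix(
    config: SimConfig, latent_profiles: Sequence[tuple[str, IndicatorProfile]]
) -> pd.DataFrame:
    """Per-rater indicator ratings for each study, plus the consensus row.

    Each rater reports the latent level with probability ``rater_agreement``,
    otherwise an adjacent level (moderate errors split evenly up/down;
    low/high errors flip inward to moderate).
    """
    rng = np.random.default_rng(config.seed + 1)

    def report(latent: Level) -> Level:
        if rng.random() < config.rater_agreement:
            return latent
        if latent == Level.MODERATE:
            return Level.LOW if rng.random() < 0.5 else Level.HIGH
        return Level.MODERATE

    rows = []
    for study_id, profile in latent_profiles:
        for r in range(1, config.n_raters + 1):
            rows.append(
                {
                    "study_id": study_id,
                    "rater_id": f"rater{r}",
                    "expectation": report(profile.expectation).label,
                    "effort": report(profile.effort).label,
                    "bond": report(profile.bond).label,
                }
            )
        rows.append(
            {
                "study_id": study_id,
                "rater_id": "consensus",
                "expectation": profile.expectation.label,
                "effort": profile.effort.label,
                "bond": profile.bond.label,
            }
        )
    return pd.DataFrame(rows)


def simulate_corpus(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Studies table, ratings table and manifest in one call."""
    studies, manifest = simulate_studies(config)
    latent = [
        (rec["study_id"], IndicatorProfile.from_labels(*rec["profile"]))
        for rec in manifest["studies"]
    ]
    ratings = simulate_rater_matrix(config, latent)
    return studies, ratings, manifest


def simulate_meta_effects(
    k: int,
    mu: float,
    tau2: float,
    vi_range: tuple[float, float] = (0.01, 0.1),
    seed: int | np.random.Generator = 0,
) -> list[EffectEstimate]:
    """Direct normal-normal draws (yi, vi) for engine unit tests.

    yi ~ N(mu + N(0, tau2), vi) with vi ~ U(vi_range).
    """
    if k < 2:
        raise ValueError("need k >= 2 effects")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vi = rng.uniform(*vi_range, size=k)
    theta = mu + rng.normal(0.0, math.sqrt(tau2), size=k)
    yi = rng.normal(theta, np.sqrt(vi))
    return [
        EffectEstimate(study_id=f"E{i+1:03d}", yi=float(y), vi=float(v), measure="smd")
        for i, (y, v) in enumerate(zip(yi, vi))
    ]
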