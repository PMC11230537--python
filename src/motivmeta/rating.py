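"""Study-level motivation rating engine.

Combines three ordinal indicators of baseline participant motivation in a
randomized trial of a self-care digital health intervention —

* **expectation**: does the study team actively select or enhance the
  motivation of potential participants?
* **effort**: how much active engagement is demanded of participants before
  treatment allocation?
* **bond**: how strong is the bond/trust between participants and the
  person or institution referring them to the study?

— into a single study-level motivation category (low / moderate / high)
under two schemes:

``tree``
    A weighted decision rule in which expectation and effort carry equal
    weight and bond carries lower weight (bond relies on more indirect
    study-level information).  The default rule scores the triple as
    ``W = 2*s1 + 2*s2 + s3`` on the 1–3 indicator scores (range 5–15) and
    cuts at W <= 7 (low), 8–12 (moderate), W >= 13 (high).  A user-supplied
    27-row rule table overrides the default verbatim, so any explicit
    decision tree honouring the same interface can be plugged in.

``equal_sum``
    The equal-weight sensitivity scheme: sum the three 1–3 scores
    (range 3–9) and cut at 3–5 (low), 6–7 (moderate), 8–9 (high).
"""
from __future__ import annotations

import enum
import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Level",
    "IndicatorProfile",
    "OverallRating",
    "level_to_score",
    "score_to_level",
    "combine_equal_sum",
    "combine_tree",
    "classify_sample",
    "all_profiles",
    "read_rule_table",
]

INDICATORS = ("expectation", "effort", "bond")


class Level(enum.IntEnum):
    """Ordinal motivation category; the integer value is the 1–3 score."""

    LOW = 1
    MODERATE = 2
    HIGH = 3

    @classmethod
    def from_label(cls, label: "Level | str") -> "Level":
        """Parse a category label (case-insensitive) into a Level."""
        if isinstance(label, Level):
            return label
        token = str(label).strip().lower()
        try:
            return cls[token.upper()]
        except KeyError:
            raise ValueError(
                f"unrecognized motivation level {label!r}; "
                f"expected one of 'low', 'moderate', 'high'"
            ) from None

    @property
    def label(self) -> str:
        return self.name.lower()


def level_to_score(level: Level | str) -> int:
    """Map low→1, moderate→2, high→3."""
    return int(Level.from_label(level))


def score_to_level(score: int) -> Level:
    """Inverse of :func:`level_to_score`."""
    try:
        return Level(int(score))
    except ValueError:
        raise ValueError(f"score {score!r} is not in {{1, 2, 3}}") from None


@dataclass(frozen=True)
class IndicatorProfile:
    """One study's ordinal ratings on the three motivation indicators."""

    expectation: Level
    effort: Level
    bond: Level

    def __post_init__(self) -> None:
        for name in INDICATORS:
            value = getattr(self, name)
            if value is None:
                raise ValueError(f"indicator {name!r} is missing")
            object.__setattr__(self, name, Level.from_label(value))

    @property
    def scores(self) -> tuple[int, int, int]:
        return (int(self.expectation), int(self.effort), int(self.bond))

    @classmethod
    def from_labels(
        cls, expectation: str, effort: str, bond: str
    ) -> "IndicatorProfile":
        return cls(
            Level.from_label(expectation),
            Level.from_label(effort),
            Level.from_label(bond),
        )


@dataclass(frozen=True)
class OverallRating:
    """Study-level motivation category produced by a combination scheme."""

    level: Level
    scheme: str  # "tree" or "equal_sum"
    raw_score: int

    def __post_init__(self) -> None:
        lo, hi = {"tree": (5, 15), "equal_sum": (3, 9)}[self.scheme]
        if not lo <= self.raw_score <= hi:
            raise ValueError(
                f"raw_score {self.raw_score} outside [{lo}, {hi}] "
                f"for scheme {self.scheme!r}"
            )


def combine_equal_sum(profile: IndicatorProfile) -> OverallRating:
    """Equal-weight scheme: sum of the three 1–3 scores, cut at 5/7.

    Score 3–5 → low, 6–7 → moderate, 8–9 → high.
    """
    total = sum(profile.scores)
    if total <= 5:
        level = Level.LOW
    elif total <= 7:
        level = Level.MODERATE
    else:
        level = Level.HIGH
    return OverallRating(level=level, scheme="equal_sum", raw_score=total)


#: Default weighted-score cut-offs for the tree scheme.
_TREE_LOW_MAX = 7
_TREE_HIGH_MIN = 13

RuleTable = Mapping[tuple[Level, Level, Level], Level]


def combine_tree(
    profile: IndicatorProfile, rule_table: RuleTable | None = None
) -> OverallRating:
    """Weighted decision rule: expectation and effort count double, bond single.

    Default rule: ``W = 2*s1 + 2*s2 + s3`` with W <= 7 low, 8–12 moderate,
    W >= 13 high.  When ``rule_table`` is given it must map all 27 level
    triples and is used verbatim for the level (the weighted score is still
    reported as ``raw_score``).
    """
    s1, s2, s3 = profile.scores
    weighted = 2 * s1 + 2 * s2 + s3
    if rule_table is not None:
        _validate_rule_table(rule_table)
        level = Level.from_label(
            rule_table[(profile.expectation, profile.effort, profile.bond)]
        )
    elif weighted <= _TREE_LOW_MAX:
        level = Level.LOW
    elif weighted >= _TREE_HIGH_MIN:
        level = Level.HIGH
    else:
        level = Level.MODERATE
    return OverallRating(level=level, scheme="tree", raw_score=weighted)


def _validate_rule_table(rule_table: RuleTable) -> None:
    missing = [
        triple
        for triple in itertools.product(Level, repeat=3)
        if triple not in rule_table
    ]
    if missing:
        raise ValueError(
            f"rule table is incomplete: {len(missing)} of 27 triples unmapped "
            f"(first missing: {tuple(l.label for l in missing[0])})"
        )


def read_rule_table(source) -> dict[tuple[Level, Level, Level], Level]:
    """Load a 27-row rule table from a CSV path or DataFrame.

    Expected columns: expectation, effort, bond, overall.
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    table = {
        (
            Level.from_label(row["expectation"]),
            Level.from_label(row["effort"]),
            Level.from_label(row["bond"]),
        ): Level.from_label(row["overall"])
        for _, row in df.iterrows()
    }
    _validate_rule_table(table)
    return table


def all_profiles() -> list[IndicatorProfile]:
    """All 27 indicator triples, in (expectation, effort, bond) lexical order."""
    return [
        IndicatorProfile(e, f, b) for e, f, b in itertools.product(Level, repeat=3)
    ]


def classify_sample(
    profiles: Sequence[IndicatorProfile],
    scheme: str = "tree",
    rule_table: RuleTable | None = None,
) -> dict[str, dict[str, int]]:
    """Tally the high/moderate/low distribution per indicator and overall.

    Returns a mapping with keys ``overall``, ``expectation``, ``effort`` and
    ``bond``, each a ``{"high": n, "moderate": n, "low": n}`` count dict whose
    values sum to ``len(profiles)``.
    """
    if not profiles:
        raise ValueError("classify_sample requires a non-empty list of profiles")
    combine = {
        "tree": lambda p: combine_tree(p, rule_table).level,
        "equal_sum": lambda p: combine_equal_sum(p).level,
    }[scheme]

    def tally(levels: Iterable[Level]) -> dict[str, int]:
        counts = Counter(level.label for level in levels)
        return {lvl.label: counts.get(lvl.label, 0) for lvl in reversed(Level)}

    return {
        "overall": tally(combine(p) for p in profiles),
        "expectation": tally(p.expectation for p in profiles),
        "effort": tally(p.effort for p in profiles),
        "bond": tally(p.bond for p in profiles),
    }
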