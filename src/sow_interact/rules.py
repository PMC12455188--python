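"""The published decision rules for the three classification steps.

The detection method has three steps — presence of an interaction
(before/after periods), valence (positive vs. negative; before, during,
after) and orientation (nose-nose, nose-neck, nose-tail; before,
during, after).  Each (step, period) combination has one published
depth-limited decision tree.  The trees are shipped as a
machine-readable decision-list table (``data/published_rules.yaml``);
this module evaluates them.

Thresholds are treated as data, not code: every branch is a
conjunction of ``feature <op> threshold`` conditions, branches are
tried in order, and a vector matching no branch receives the rule
set's default label.  Comparators are strict where the published text
is strict; a value exactly equal to a threshold fails the strict
comparison and falls through to the next branch or the default.
"""

from __future__ import annotations

import operator
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import yaml

from .features import PairFeatureVector

__all__ = [
    "STEPS",
    "STEP_PERIODS",
    "Condition",
    "Branch",
    "RuleSet",
    "load_published_rules",
    "published_rule_set",
    "classify",
    "classify_presence_before",
    "classify_presence_after",
    "classify_valence_before",
    "classify_valence_during",
    "classify_valence_after",
    "classify_orientation_before",
    "classify_orientation_during",
    "classify_orientation_after",
]

STEPS: tuple[str, ...] = ("presence", "valence", "orientation")

#: Periods each step supports.  Presence is defined only for the
#: before (start detection) and after (end detection) periods.
STEP_PERIODS: dict[str, tuple[str, ...]] = {
    "presence": ("before", "after"),
    "valence": ("before", "during", "after"),
    "orientation": ("before", "during", "after"),
}

_OPS = {
    "<": operator.lt,
    "<=": operator.le,
    ">": operator.gt,
    ">=": operator.ge,
}


@dataclass(frozen=True)
class Condition:
    feature: str
    op: str
    value: float

    def holds(self, fv: Mapping[str, float]) -> bool:
        if self.feature not in fv:
            raise KeyError(f"feature vector lacks {self.feature!r}")
        return _OPS[self.op](fv[self.feature], self.value)


@dataclass(frozen=True)
class Branch:
    label: str
    conditions: tuple[Condition, ...]


@dataclass(frozen=True)
class RuleSet:
    """One published tree as an ordered, total decision list."""

    step: str
    period: str
    branches: tuple[Branch, ...]
    default: str

    def apply(self, fv: Mapping[str, float]) -> str:
        for branch in self.branches:
            if all(c.holds(fv) for c in branch.conditions):
                return branch.label
        return self.default

    @property
    def labels(self) -> tuple[str, ...]:
        seen: list[str] = []
        for b in (*self.branches,):
            if b.label not in seen:
                seen.append(b.label)
        if self.default not in seen:
            seen.append(self.default)
        return tuple(seen)


def _parse_rule_sets(doc: dict) -> dict[tuple[str, str], RuleSet]:
    out: dict[tuple[str, str], RuleSet] = {}
    for rs in doc["rule_sets"]:
        branches = tuple(
            Branch(
                label=str(b["label"]),
                conditions=tuple(
                    Condition(str(c["feature"]), str(c["op"]), float(c["value"]))
                    for c in b["when"]
                ),
            )
            for b in rs["branches"]
        )
        key = (str(rs["step"]), str(rs["period"]))
        out[key] = RuleSet(step=key[0], period=key[1],
                           branches=branches, default=str(rs["default"]))
    return out


_PUBLISHED: dict[tuple[str, str], RuleSet] | None = None


def load_published_rules() -> dict[tuple[str, str], RuleSet]:
    """Load (and cache) the shipped published-rules table."""
    global _PUBLISHED
    if _PUBLISHED is None:
        text = (resources.files("sow_interact") / "data" / "published_rules.yaml") \
            .read_text(encoding="utf-8")
        _PUBLISHED = _parse_rule_sets(yaml.safe_load(text))
    return _PUBLISHED


def published_rule_set(step: str, period: str) -> RuleSet:
    if step not in STEPS:
        raise ValueError(f"unknown step {step!r}; expected one of {STEPS}")
    if period not in STEP_PERIODS[step]:
        raise ValueError(
            f"step {step!r} is defined for periods {STEP_PERIODS[step]}, "
            f"not {period!r}"
        )
    return load_published_rules()[(step, period)]


def _as_mapping(fv, step: str, period: str) -> Mapping[str, float]:
    if isinstance(fv, PairFeatureVector):
        if fv.period != period:
            raise ValueError(
                f"feature vector is for period {fv.period!r}, classifier "
                f"expects {period!r}"
            )
        return fv.to_flat_dict()
    return fv


def classify(fv, step: str, period: str, rule_set: RuleSet | None = None) -> str:
    """Classify a feature vector with a published (or supplied) rule set.

    ``fv`` may be a :class:`PairFeatureVector` (its period must match)
    or a flat feature mapping.
    """
    rs = rule_set if rule_set is not None else published_rule_set(step, period)
    return rs.apply(_as_mapping(fv, step, period))


#: Explanatory variable families per step.  Ordered as a screening
#: priority: the variables the published trees actually split on come
#: first, the collinear neck-pair variants last.
_STEP_FEATURES: dict[str, tuple[str, ...]] = {
    "presence": (
        "d_evolution_nose1_nose2", "avg_d_nose1_nose2",
        "d_evolution_nose2_tail1", "d_evolution_nose1_tail2",
        "avg_d_nose2_tail1", "avg_d_nose1_tail2",
        "prop_any_standing", "prop_both_lying",
        "prop_pooled_standing", "prop_pooled_sitting", "prop_pooled_lying",
        "d_travelled_sow1", "d_travelled_sow2",
        "d_evolution_nose1_neck2", "d_evolution_nose2_neck1",
        "avg_d_nose1_neck2", "avg_d_nose2_neck1",
    ),
    "valence": (
        "speed_nose1_nose2", "speed_nose1_tail2", "speed_nose2_tail1",
        "d_travelled_sow1", "d_travelled_sow2",
        "prop_any_standing", "prop_both_lying",
        "prop_pooled_standing", "prop_pooled_sitting", "prop_pooled_lying",
        "speed_nose1_neck2", "speed_nose2_neck1",
    ),
    "orientation": (
        "avg_d_nose1_nose2", "avg_d_nose2_tail1", "avg_d_nose1_tail2",
        "d_evolution_nose1_nose2", "d_evolution_nose2_tail1",
        "d_evolution_nose1_tail2",
        "avg_d_nose1_neck2", "avg_d_nose2_neck1",
        "d_evolution_nose1_neck2", "d_evolution_nose2_neck1",
    ),
}


def step_feature_set(step: str) -> list[str]:
    """Candidate explanatory variables for one step, in screening priority."""
    if step not in STEPS:
        raise ValueError(f"unknown step {step!r}; expected one of {STEPS}")
    return list(_STEP_FEATURES[step])


def classify_presence_before(fv) -> str:
    """Interaction start: nose convergence, or proximity plus standing."""
    return classify(fv, "presence", "before")


def classify_presence_after(fv) -> str:
    """Interaction end: nose-nose divergence at close-to-moderate range."""
    return classify(fv, "presence", "after")


def classify_valence_before(fv) -> str:
    return classify(fv, "valence", "before")


def classify_valence_during(fv) -> str:
    """Negative when one sow travels far or inter-sow speeds are high."""
    return classify(fv, "valence", "during")


def classify_valence_after(fv) -> str:
    """Negative when separation is fast or the recipient flees far."""
    return classify(fv, "valence", "after")


def classify_orientation_before(fv) -> str:
    return classify(fv, "orientation", "before")


def classify_orientation_during(fv) -> str:
    return classify(fv, "orientation", "during")


def classify_orientation_after(fv) -> str:
    return classify(fv, "orientation", "after")
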