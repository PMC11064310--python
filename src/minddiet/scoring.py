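"""Banded dietary-index scoring.

A :class:`ScoringRuleSet` holds one rule table (e.g. the 11-component
MY-MINDD index or the 15-component original MIND index).  Each frequency
component carries an ordered list of half-open bands that partition
``[0, inf)`` servings/week and award 0, 0.5 or 1 point; categorical
components map categories straight to points.  Intakes arrive in mixed
units (per day / week / month) and are normalised to servings/week before
band lookup.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "WEEKS_PER_MONTH",
    "MISSING",
    "UNITS",
    "ValidationError",
    "FrequencyValue",
    "ScoreBand",
    "ComponentRule",
    "ScoringRuleSet",
    "IntakeProfile",
    "DietScoreResult",
    "normalize_frequency",
    "score_component",
    "score_profile",
    "load_scoring_table",
    "builtin_table_names",
]

#: Month-to-week conversion uses the 30.44-day-month convention.
WEEKS_PER_MONTH = 4.348

UNITS = ("per_day", "per_week", "per_month")

_UNIT_TO_WEEKLY = {"per_day": 7.0, "per_week": 1.0, "per_month": 1.0 / WEEKS_PER_MONTH}

_BUILTIN_FILES = {"MY-MINDD": "mymindd.yaml", "MIND-original": "mind_original.yaml"}
_BUILTIN_SHAPE = {"MY-MINDD": (11, 7, 4), "MIND-original": (15, 10, 5)}

VALID_POINTS = (0.0, 0.5, 1.0)


class ValidationError(ValueError):
    """Raised for malformed rule tables, units, or intake values."""


class _Missing:
    """Sentinel for an absent intake; distinct from zero intake."""

    def __repr__(self) -> str:  # pragma: no cover
        return "MISSING"


MISSING = _Missing()


@dataclass(frozen=True)
class FrequencyValue:
    """A consumption frequency: ``amount`` events per ``unit``."""

    amount: float
    unit: str = "per_week"

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValidationError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if not math.isfinite(self.amount) or self.amount < 0:
            raise ValidationError(f"amount must be a finite non-negative number, got {self.amount!r}")


def normalize_frequency(value: FrequencyValue) -> float:
    """Convert a frequency to servings/week (day x7, month /4.348)."""
    return value.amount * _UNIT_TO_WEEKLY[value.unit]


@dataclass(frozen=True)
class ScoreBand:
    """One scoring band over weekly intake, with explicit bound closures."""

    lower: float
    upper: float
    points: float
    lower_closed: bool = True
    upper_closed: bool = False

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValidationError(f"band lower {self.lower} exceeds upper {self.upper}")
        if self.points not in VALID_POINTS:
            raise ValidationError(f"band points must be one of {VALID_POINTS}, got {self.points}")

    def contains(self, weekly: float) -> bool:
        above = weekly >= self.lower if self.lower_closed else weekly > self.lower
        below = weekly <= self.upper if self.upper_closed else weekly < self.upper
        return above and below


@dataclass(frozen=True)
class ComponentRule:
    """Scoring rule for one food-group component."""

    component_id: str
    display_name: str
    polarity: str  # "healthy" | "unhealthy"
    input_kind: str  # "frequency" | "categorical"
    bands: tuple[ScoreBand, ...] = ()
    categories: Mapping[str, float] = field(default_factory=dict)
    canonical_unit: str = "per_week"
    monotone: bool = True

    def __post_init__(self) -> None:
        if self.polarity not in ("healthy", "unhealthy"):
            raise ValidationError(f"{self.component_id}: bad polarity {self.polarity!r}")
        if self.input_kind == "frequency":
            self._validate_partition()
            if self.monotone:
                self._validate_monotone()
        elif self.input_kind == "categorical":
            if not self.categories:
                raise ValidationError(f"{self.component_id}: categorical rule with no categories")
            for cat, pts in self.categories.items():
                if pts not in VALID_POINTS:
                    raise ValidationError(f"{self.component_id}: bad points {pts} for category {cat!r}")
        else:
            raise ValidationError(f"{self.component_id}: bad input_kind {self.input_kind!r}")

    def _validate_partition(self) -> None:
        """Bands must partition [0, inf) exactly: no gaps, no overlaps."""
        if not self.bands:
            raise ValidationError(f"{self.component_id}: frequency rule with no bands")
        bands = sorted(self.bands, key=lambda b: (b.lower, not b.lower_closed))
        first = bands[0]
        if first.lower != 0 or not first.lower_closed:
            raise ValidationError(f"{self.component_id}: bands do not start at a closed 0 bound")
        for prev, nxt in zip(bands, bands[1:]):
            if prev.upper != nxt.lower or prev.upper_closed == nxt.lower_closed:
                raise ValidationError(
                    f"{self.component_id}: bands [{prev.lower}, {prev.upper}] and "
                    f"[{nxt.lower}, {nxt.upper}] gap or overlap"
                )
        last = bands[-1]
        if not (math.isinf(last.upper) and not last.upper_closed):
            raise ValidationError(f"{self.component_id}: bands do not extend to +inf")

    def _validate_monotone(self) -> None:
        bands = sorted(self.bands, key=lambda b: b.lower)
        pts = [b.points for b in bands]
        steps = [b - a for a, b in zip(pts, pts[1:])]
        ok = all(s >= 0 for s in steps) if self.polarity == "healthy" else all(s <= 0 for s in steps)
        if not ok:
            raise ValidationError(f"{self.component_id}: band points not monotone for {self.polarity} component")

    def score(self, intake) -> float | _Missing:
        """Points for one intake; ``MISSING`` propagates, never silently 0."""
        if intake is None or isinstance(intake, _Missing):
            return MISSING
        if self.input_kind == "categorical":
            if not isinstance(intake, str):
                raise ValidationError(f"{self.component_id}: expected a category, got {intake!r}")
            try:
                return self.categories[intake]
            except KeyError:
                raise ValidationError(
                    f"{self.component_id}: unknown category {intake!r}; "
                    f"expected one of {sorted(self.categories)}"
                ) from None
        if isinstance(intake, (int, float)):
            intake = FrequencyValue(float(intake), "per_week")
        if not isinstance(intake, FrequencyValue):
            raise ValidationError(f"{self.component_id}: expected a FrequencyValue, got {intake!r}")
        weekly = normalize_frequency(intake)
        for band in self.bands:
            if band.contains(weekly):
                return band.points
        raise ValidationError(f"{self.component_id}: no band contains {weekly}")  # pragma: no cover

    def score_array(self, weekly: np.ndarray) -> np.ndarray:
        """Vectorised band lookup over weekly intakes (frequency kind only)."""
        if self.input_kind != "frequency":
            raise ValidationError(f"{self.component_id}: score_array needs a frequency rule")
        weekly = np.asarray(weekly, dtype=float)
        out = np.full(weekly.shape, np.nan)
        for band in self.bands:
            above = weekly >= band.lower if band.lower_closed else weekly > band.lower
            below = weekly <= band.upper if band.upper_closed else weekly < band.upper
            out[above & below] = band.points
        return out

    @property
    def max_points(self) -> float:
        if self.input_kind == "categorical":
            return max(self.categories.values())
        return max(b.points for b in self.bands)


@dataclass(frozen=True)
class ScoringRuleSet:
    """A complete, validated diet-index rule table."""

    name: str
    components: tuple[ComponentRule, ...]

    def __post_init__(self) -> None:
        ids = [c.component_id for c in self.components]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"{self.name}: duplicate component ids")
        shape = _BUILTIN_SHAPE.get(self.name)
        if shape is not None:
            n, healthy, unhealthy = shape
            got_h = sum(c.polarity == "healthy" for c in self.components)
            got_u = len(self.components) - got_h
            if (len(self.components), got_h, got_u) != (n, healthy, unhealthy):
                raise ValidationError(
                    f"{self.name}: expected {n} components ({healthy} healthy / {unhealthy} "
                    f"unhealthy), got {len(self.components)} ({got_h}/{got_u})"
                )

    @property
    def max_total(self) -> float:
        return sum(c.max_points for c in self.components)

    def component(self, component_id: str) -> ComponentRule:
        for c in self.components:
            if c.component_id == component_id:
                return c
        raise KeyError(component_id)

    @property
    def component_ids(self) -> tuple[str, ...]:
        return tuple(c.component_id for c in self.components)


@dataclass
class IntakeProfile:
    """One participant's intakes keyed by component id.

    ``frequencies`` maps component id -> FrequencyValue (or MISSING);
    ``categories`` maps component id -> category string (or MISSING).
    """

    participant_id: str
    frequencies: dict = field(default_factory=dict)
    categories: dict = field(default_factory=dict)

    def intake_for(self, rule: ComponentRule):
        table = self.categories if rule.input_kind == "categorical" else self.frequencies
        return table.get(rule.component_id, MISSING)


@dataclass(frozen=True)
class DietScoreResult:
    participant_id: str
    component_scores: Mapping[str, float]
    total: float
    missing_components: tuple[str, ...]
    complete: bool


def score_component(rule: ComponentRule, intake) -> float | _Missing:
    """Score a single component; thin functional wrapper over the rule."""
    return rule.score(intake)


def score_profile(
    rules: ScoringRuleSet,
    profile: IntakeProfile,
    missing_policy: str = "refuse",
) -> DietScoreResult:
    """Score every component of ``rules`` for one profile and sum.

    missing_policy: "refuse" flags the total incomplete when any component
    is missing; "zero" counts missing components as 0 points.
    """
    if missing_policy not in ("refuse", "zero"):
        raise ValidationError(f"unknown missing_policy {missing_policy!r}")
    if not profile.frequencies and not profile.categories:
        raise ValidationError(f"profile {profile.participant_id!r} is empty")
    scores: dict[str, float] = {}
    missing: list[str] = []
    for rule in rules.components:
        pts = rule.score(profile.intake_for(rule))
        if isinstance(pts, _Missing):
            missing.append(rule.component_id)
            if missing_policy == "zero":
                scores[rule.component_id] = 0.0
        else:
            scores[rule.component_id] = pts
    total = float(sum(scores.values()))
    complete = not missing or missing_policy == "zero"
    return DietScoreResult(
        participant_id=profile.participant_id,
        component_scores=scores,
        total=total,
        missing_components=tuple(missing),
        complete=complete,
    )


def _parse_bound(raw, default: float) -> float:
    if raw is None:
        return default
    if isinstance(raw, (list, tuple)):
        amount, unit = raw
        return normalize_frequency(FrequencyValue(float(amount), unit))
    return float(raw)


def _parse_component(doc: Mapping) -> ComponentRule:
    kind = doc.get("kind", "frequency")
    common = dict(
        component_id=doc["id"],
        display_name=doc.get("display_name", doc["id"]),
        polarity=doc["polarity"],
        input_kind=kind,
        canonical_unit=doc.get("canonical_unit", "per_week"),
        monotone=doc.get("monotone", True),
    )
    if kind == "categorical":
        cats = {str(k): float(v) for k, v in doc["categories"].items()}
        return ComponentRule(categories=cats, **common)
    bands = []
    for b in doc["bands"]:
        bands.append(
            ScoreBand(
                lower=_parse_bound(b.get("lower"), 0.0),
                upper=_parse_bound(b.get("upper"), math.inf),
                points=float(b["points"]),
                lower_closed=bool(b.get("lower_closed", True)),
                upper_closed=bool(b.get("upper_closed", False)),
            )
        )
    return ComponentRule(bands=tuple(bands), **common)


def load_scoring_table(source) -> ScoringRuleSet:
    """Load and validate a rule table.

    ``source`` may be a builtin name ("MY-MINDD", "MIND-original"), a path
    to a YAML document, or an already-parsed mapping.
    """
    if isinstance(source, str) and source in _BUILTIN_FILES:
        ref = resources.files("minddiet.data") / _BUILTIN_FILES[source]
        doc = yaml.safe_load(ref.read_text(encoding="utf-8"))
    elif isinstance(source, Mapping):
        doc = source
    else:
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or "name" not in doc or "components" not in doc:
        raise ValidationError("rule-table document must declare 'name' and 'components'")
    components = tuple(_parse_component(c) for c in doc["components"])
    return ScoringRuleSet(name=str(doc["name"]), components=components)


def builtin_table_names() -> Sequence[str]:
    return tuple(_BUILTIN_FILES)
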