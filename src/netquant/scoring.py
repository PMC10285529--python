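"""Fuzzy interval scoring and the unambiguous-assignment decision rule.

Each ROI class is characterised by acceptance intervals ``[l, u]`` on a
subset of the features.  Rather than a hard interval test, membership is
graded by a partial score ``S(x; l, u, s)`` that equals 1 inside
``[l, u]`` and descends smoothly (half-sine ramps) to 0 over error
margins whose widths adapt to the interval::

    dl = s * l * (u - l) / (u + l)        du = s * u * (u - l) / (u + l)

so a single dimensionless margin factor ``s`` works for every feature
regardless of its units.  A class score is the product of the partial
scores of its ranged features; an ROI is assigned to a class only when
that class scores high (>= 0.8 by default) and every competing class
scores low (<= 0.4 by default) — otherwise it is flagged unknown and
left for manual inspection.  This trades recall for precision: with
misspecified parameters it is safer not to classify than to classify
wrong.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

from .errors import ConfigError
from .features import FEATURE_NAMES, FeatureVector

#: The seven named ROI classes.  NET and EXTRA_ARTIFACT apply to
#: extracellular-channel ROIs; the rest to total-DNA-channel ROIs.
CLASS_NAMES = ("PMN", "RND", "RUP", "PER", "NET", "BACTERIA", "EXTRA_ARTIFACT")

#: Default candidate set for the second (intracellular) stage.
INTRACELLULAR_CLASSES = ("PMN", "RND", "RUP", "PER", "BACTERIA")

UNKNOWN_INTRACELLULAR = "UNKNOWN_INTRACELLULAR"
UNKNOWN_EXTRACELLULAR = "UNKNOWN_EXTRACELLULAR"


class AmbiguityReason(str, Enum):
    NONE = "none"
    NO_HIGH_SCORE = "no_high_score"
    MULTIPLE_HIGH_SCORES = "multiple_high_scores"


@dataclass(frozen=True)
class FeatureRange:
    """Acceptance interval ``[l, u]`` for one feature.

    Either bound may be infinite (``-inf`` / ``inf``) meaning the class
    imposes no limit on that side; at most one bound may be infinite.
    """

    feature_name: str
    l: float
    u: float

    def __post_init__(self) -> None:
        if self.feature_name not in FEATURE_NAMES:
            raise ConfigError(f"unknown feature {self.feature_name!r}")
        if math.isinf(self.l) and math.isinf(self.u):
            raise ConfigError(f"{self.feature_name}: both bounds infinite")
        if self.l > self.u:
            raise ConfigError(
                f"{self.feature_name}: lower bound {self.l} exceeds upper bound {self.u}"
            )


def margins(rng: FeatureRange, s: float) -> tuple[float, float]:
    """Margin widths ``(dl, du)`` for a range at margin factor ``s``.

    Degenerate cases: an infinite bound removes the dependence on the
    interval length, so the finite side uses ``s * |bound|``; a point
    interval (``l == u``) or a zero bound gives a hard edge (margin 0).
    Magnitudes are used throughout so margins stay non-negative for
    signed features such as the mean LoG response.
    """
    l, u = rng.l, rng.u
    if math.isinf(u):
        return s * abs(l), math.inf
    if math.isinf(l):
        return math.inf, s * abs(u)
    if l == u:
        return 0.0, 0.0
    al, au = abs(l), abs(u)
    if al + au == 0:
        return 0.0, 0.0
    width = (u - l) / (al + au)
    return s * al * width, s * au * width


def partial_score(x: float, rng: FeatureRange, s: float) -> float:
    """Graded membership of feature value ``x`` in ``rng`` at margin ``s``.

    Returns 1 on ``[l, u]``, half-sine ramps on ``[l - dl, l]`` and
    ``[u, u + du]``, 0 outside; continuous and monotone on each side.
    ``s = 0`` reduces to a hard interval test.
    """
    if s < 0:
        raise ConfigError(f"margin factor s must be >= 0, got {s}")
    l, u = rng.l, rng.u
    if l <= x <= u:
        return 1.0
    dl, du = margins(rng, s)
    if x < l:
        if math.isinf(dl):  # no lower limit
            return 1.0
        if dl == 0.0 or x <= l - dl:
            return 0.0
        return 0.5 + 0.5 * math.sin(math.pi * (x - l + dl) / dl - math.pi / 2)
    # x > u
    if math.isinf(du):  # no upper limit
        return 1.0
    if du == 0.0 or x >= u + du:
        return 0.0
    return 0.5 + 0.5 * math.sin(math.pi * (x - u + du) / du - math.pi / 2)


@dataclass(frozen=True)
class ClassDefinition:
    """A named class with acceptance intervals on a subset of features."""

    class_name: str
    ranges: tuple[FeatureRange, ...]

    def __post_init__(self) -> None:
        if self.class_name not in CLASS_NAMES:
            raise ConfigError(f"unknown class {self.class_name!r}")
        names = [r.feature_name for r in self.ranges]
        if len(names) != len(set(names)):
            raise ConfigError(f"{self.class_name}: duplicate feature ranges")

    def score(self, fv: FeatureVector, s: float) -> float:
        """Product of partial scores; features without a range contribute 1."""
        out = 1.0
        for rng in self.ranges:
            out *= partial_score(fv[rng.feature_name], rng, s)
            if out == 0.0:
                break
        return out


@dataclass(frozen=True)
class ClassifierConfig:
    """Class definitions plus the shared margin factor and thresholds."""

    classes: Mapping[str, ClassDefinition]
    s: float = 0.2
    assign_threshold: float = 0.8
    reject_threshold: float = 0.4

    def __post_init__(self) -> None:
        if not 0 <= self.reject_threshold <= self.assign_threshold <= 1:
            raise ConfigError(
                "thresholds must satisfy 0 <= reject <= assign <= 1, got "
                f"reject={self.reject_threshold}, assign={self.assign_threshold}"
            )
        if self.s < 0:
            raise ConfigError(f"margin factor s must be >= 0, got {self.s}")
        for name, cd in self.classes.items():
            if name != cd.class_name:
                raise ConfigError(f"class key {name!r} != definition name {cd.class_name!r}")


@dataclass(frozen=True)
class ClassificationOutcome:
    roi_id: int
    scores: Mapping[str, float]
    label: str
    ambiguity_reason: AmbiguityReason = AmbiguityReason.NONE


def class_score(fv: FeatureVector, cd: ClassDefinition, s: float) -> float:
    return cd.score(fv, s)


def classify(
    fv: FeatureVector,
    config: ClassifierConfig,
    candidate_classes: Sequence[str] = INTRACELLULAR_CLASSES,
    roi_id: int = 0,
    unknown_label: str = UNKNOWN_INTRACELLULAR,
) -> ClassificationOutcome:
    """Assign an ROI to the unique unambiguously matching class.

    The label is the single candidate scoring >= ``assign_threshold``
    while all other candidates score <= ``reject_threshold``; both
    comparisons are closed, so a competitor sitting exactly at the
    rejection threshold does not block assignment.  Every other
    configuration yields the unknown label with a reason.
    """
    if not candidate_classes:
        raise ConfigError("candidate_classes must be non-empty")
    missing = [c for c in candidate_classes if c not in config.classes]
    if missing:
        raise ConfigError(f"candidate classes not defined in config: {missing}")
    scores = {c: config.classes[c].score(fv, config.s) for c in candidate_classes}
    high = [c for c, v in scores.items() if v >= config.assign_threshold]
    if not high:
        return ClassificationOutcome(roi_id, scores, unknown_label, AmbiguityReason.NO_HIGH_SCORE)
    if len(high) > 1:
        return ClassificationOutcome(
            roi_id, scores, unknown_label, AmbiguityReason.MULTIPLE_HIGH_SCORES
        )
    winner = high[0]
    if any(v > config.reject_threshold for c, v in scores.items() if c != winner):
        return ClassificationOutcome(
            roi_id, scores, unknown_label, AmbiguityReason.MULTIPLE_HIGH_SCORES
        )
    return ClassificationOutcome(roi_id, scores, winner, AmbiguityReason.NONE)
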