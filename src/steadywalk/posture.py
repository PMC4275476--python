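"""Pairwise joint-alignment posture checks, thresholds and lean estimation.

The posture model is deliberately simple and height-independent: a posture
is a set of *alignment rules*, each asserting that two named joints share
(within an error range ε, in meters) the same coordinate on one axis. Only
coordinate *differences* are compared, so the checks are invariant to where
the subject stands and need no per-subject calibration.

Therapists tune the engine through a :class:`ThresholdConfig`: a global
strictness multiplier on all error ranges, absolute per-rule overrides, and
a body-part inclusion mask so that, e.g., a patient who cannot move one arm
is not failed on arm rules.

Lateral lean is estimated from shoulder asymmetry: the shoulder-height
difference normalized by the lateral shoulder distance, a dimensionless
signed value whose sign names the lower shoulder's side.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .skeleton import JointName, SkeletonFrame


class Axis(str, Enum):
    x = "x"
    y = "y"


#: Body-part labels used by the default template and the inclusion mask.
ALL_PARTS = frozenset({"shoulders", "trunk", "arms", "legs"})


@dataclass(frozen=True)
class AlignmentRule:
    """Assert |coord(joint_a) - coord(joint_b)| <= ε on one axis."""

    id: str
    joint_a: JointName
    joint_b: JointName
    axis: Axis
    base_epsilon: float
    body_part: str

    def __post_init__(self) -> None:
        if self.joint_a == self.joint_b:
            raise ValueError(f"rule {self.id}: joints must differ")
        if not self.base_epsilon > 0:
            raise ValueError(f"rule {self.id}: base_epsilon must be > 0")


@dataclass
class PostureTemplate:
    """A named set of alignment rules encoding one posture."""

    name: str
    rules: list[AlignmentRule]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.rules]
        if len(ids) != len(set(ids)):
            raise ValueError(f"template {self.name}: rule ids must be unique")

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "rules": [
                    {
                        "id": r.id,
                        "joint_a": r.joint_a.value,
                        "joint_b": r.joint_b.value,
                        "axis": r.axis.value,
                        "base_epsilon": r.base_epsilon,
                        "body_part": r.body_part,
                    }
                    for r in self.rules
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PostureTemplate":
        doc = json.loads(text)
        return cls(
            name=doc["name"],
            rules=[
                AlignmentRule(
                    id=r["id"],
                    joint_a=JointName(r["joint_a"]),
                    joint_b=JointName(r["joint_b"]),
                    axis=Axis(r["axis"]),
                    base_epsilon=float(r["base_epsilon"]),
                    body_part=r["body_part"],
                )
                for r in doc["rules"]
            ],
        )


@dataclass
class ThresholdConfig:
    """The therapist-tunable surface of the engine.

    strictness
        Positive multiplier on every base ε; smaller means stricter.
    overrides
        Absolute per-rule ε values (meters). An override wins over
        strictness scaling: therapist-specific settings are absolute.
    included_parts
        Body-part labels actually checked; must be non-empty.
    balance_epsilon
        Dimensionless lean threshold beyond which the lean alert fires.
    debounce_frames
        Consecutive violating frames required before a fault counts.
    """

    strictness: float = 1.0
    overrides: dict[str, float] = field(default_factory=dict)
    included_parts: frozenset[str] = ALL_PARTS
    balance_epsilon: float = 0.1
    debounce_frames: int = 5

    def __post_init__(self) -> None:
        if not self.strictness > 0:
            raise ValueError(f"strictness must be > 0, got {self.strictness}")
        for rule_id, eps in self.overrides.items():
            if not eps > 0:
                raise ValueError(f"override for {rule_id} must be > 0")
        self.included_parts = frozenset(self.included_parts)
        if not self.included_parts:
            raise ValueError("included_parts must be non-empty")
        if not self.balance_epsilon > 0:
            raise ValueError("balance_epsilon must be > 0")
        if not (isinstance(self.debounce_frames, int) and self.debounce_frames >= 1):
            raise ValueError("debounce_frames must be an integer >= 1")

    def to_json(self) -> str:
        return json.dumps(
            {
                "strictness": self.strictness,
                "overrides": dict(self.overrides),
                "included_parts": sorted(self.included_parts),
                "balance_epsilon": self.balance_epsilon,
                "debounce_frames": self.debounce_frames,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ThresholdConfig":
        doc = json.loads(text)
        return cls(
            strictness=float(doc.get("strictness", 1.0)),
            overrides={k: float(v) for k, v in doc.get("overrides", {}).items()},
            included_parts=frozenset(doc.get("included_parts", ALL_PARTS)),
            balance_epsilon=float(doc.get("balance_epsilon", 0.1)),
            debounce_frames=int(doc.get("debounce_frames", 5)),
        )


@dataclass(frozen=True)
class RuleVerdict:
    rule_id: str
    difference: float  # signed, coord(joint_a) - coord(joint_b)
    effective_epsilon: float
    passed: bool


@dataclass(frozen=True)
class PostureVerdict:
    template_name: str
    verdicts: tuple[RuleVerdict, ...]
    correct: bool
    misaligned_joints: frozenset[JointName]


@dataclass(frozen=True)
class BalanceLevel:
    """Signed, shoulder-width-normalized lean in [-1, 1].

    Negative values mean the left shoulder is lower (patient leaning left).
    ``side`` names the lower shoulder when |value| exceeds the configured
    balance threshold, else ``"none"``; ``alert`` mirrors the red-scale
    condition shown to the patient.
    """

    value: float
    side: str  # "left" | "right" | "none"
    alert: bool


def effective_epsilon(rule: AlignmentRule, config: ThresholdConfig) -> float:
    """Error range actually applied to a rule: override, else base × strictness."""
    if rule.id in config.overrides:
        return config.overrides[rule.id]
    return rule.base_epsilon * config.strictness


def check_alignment(
    frame: SkeletonFrame, rule: AlignmentRule, config: ThresholdConfig
) -> RuleVerdict:
    """Evaluate one alignment rule on one frame.

    The boundary is inclusive: a difference exactly equal to ε passes
    ("zero or inside the error range").
    """
    diff = frame.coord(rule.joint_a, rule.axis.value) - frame.coord(
        rule.joint_b, rule.axis.value
    )
    eps = effective_epsilon(rule, config)
    return RuleVerdict(
        rule_id=rule.id,
        difference=diff,
        effective_epsilon=eps,
        passed=abs(diff) <= eps,
    )


def evaluate_posture(
    frame: SkeletonFrame, template: PostureTemplate, config: ThresholdConfig
) -> PostureVerdict:
    """Evaluate every included rule of a template; aggregate into a verdict.

    Only rules whose ``body_part`` is in ``config.included_parts`` are
    checked. Raises ``ValueError`` if the mask leaves nothing to check.
    """
    rules = [r for r in template.rules if r.body_part in config.included_parts]
    if not rules:
        raise ValueError(
            f"template {template.name}: no rules left after body-part masking"
        )
    verdicts = tuple(check_alignment(frame, r, config) for r in rules)
    misaligned: set[JointName] = set()
    for rule, verdict in zip(rules, verdicts):
        if not verdict.passed:
            misaligned.add(rule.joint_a)
            misaligned.add(rule.joint_b)
    correct = all(v.passed for v in verdicts)
    return PostureVerdict(
        template_name=template.name,
        verdicts=verdicts,
        correct=correct,
        misaligned_joints=frozenset(misaligned),
    )


def upright_template() -> PostureTemplate:
    """Default template for the upright stance held at the start and finish.

    One rule per clause of the stance description — standing up, arms close
    to the body without lifting, back straight, feet aligned with the
    shoulders — with ε defaults sized to typical adult anthropometry; every
    value can be overridden per rule via :class:`ThresholdConfig`.
    """
    J, A = JointName, Axis
    return PostureTemplate(
        name="upright",
        rules=[
            AlignmentRule("shoulders_level", J.ShoulderLeft, J.ShoulderRight, A.y, 0.04, "shoulders"),
            AlignmentRule("back_straight", J.ShoulderCenter, J.HipCenter, A.x, 0.04, "trunk"),
            AlignmentRule("hips_level", J.HipLeft, J.HipRight, A.y, 0.04, "trunk"),
            AlignmentRule("hand_left_at_side", J.HandLeft, J.HipLeft, A.x, 0.12, "arms"),
            AlignmentRule("hand_right_at_side", J.HandRight, J.HipRight, A.x, 0.12, "arms"),
            AlignmentRule("hand_left_not_lifted", J.HandLeft, J.HipLeft, A.y, 0.15, "arms"),
            AlignmentRule("hand_right_not_lifted", J.HandRight, J.HipRight, A.y, 0.15, "arms"),
            AlignmentRule("foot_left_under_shoulder", J.AnkleLeft, J.ShoulderLeft, A.x, 0.10, "legs"),
            AlignmentRule("foot_right_under_shoulder", J.AnkleRight, J.ShoulderRight, A.x, 0.10, "legs"),
        ],
    )


#: Rules checked while walking (step 2): lateral balance and trunk posture.
#: Arm and foot rules are incompatible with gait and apply only to the holds.
WALKING_PARTS = frozenset({"shoulders", "trunk"})


def walking_template(template: PostureTemplate) -> PostureTemplate:
    """Subset of a template appropriate while the subject is in motion."""
    return PostureTemplate(
        name=f"{template.name}:walking",
        rules=[r for r in template.rules if r.body_part in WALKING_PARTS],
    )


def mask_rules(
    template: PostureTemplate, excluded_parts: Iterable[str]
) -> PostureTemplate:
    """Template minus the rules whose body part is excluded.

    Excluding everything is allowed here; :func:`evaluate_posture` raises
    later if there is nothing left to check.
    """
    excluded = set(excluded_parts)
    return PostureTemplate(
        name=template.name,
        rules=[r for r in template.rules if r.body_part not in excluded],
    )


def balance_level(frame: SkeletonFrame, config: ThresholdConfig) -> BalanceLevel:
    """Estimate lateral lean from shoulder asymmetry.

    value = (ShoulderLeft.y − ShoulderRight.y) / |ShoulderLeft.x −
    ShoulderRight.x|, clamped to [−1, 1]. A negative value means the left
    shoulder is lower. The alert fires when |value| strictly exceeds
    ``config.balance_epsilon``.
    """
    left = frame.joints[JointName.ShoulderLeft]
    right = frame.joints[JointName.ShoulderRight]
    width = abs(left.x - right.x)
    if width < 1e-3:
        raise ValueError(
            f"degenerate shoulder width {width:.4f} m at t={frame.t}"
        )
    value = (left.y - right.y) / width
    value = max(-1.0, min(1.0, value))
    if abs(value) <= config.balance_epsilon:
        side = "none"
    elif value < 0:
        side = "left"
    else:
        side = "right"
    return BalanceLevel(value=value, side=side, alert=side != "none")
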