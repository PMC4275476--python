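"""Three-step exercise state machine, fault debouncing and feedback events.

The monitored exercise has three phases, tracked by a ``step`` variable
that only ever increases within an attempt:

1. hold an upright posture at the start line,
2. walk a straight course (default 5 m) without leaning or leaving the
   corridor,
3. stop at the finish line and hold the upright posture again.

During the walk the monitor runs three detectors per frame — lateral lean
(balance), posture on the walking rule subset, and the corridor bounds —
and debounces them: a fault must persist for ``debounce_frames``
consecutive frames before it fires, and one maximal consecutive run counts
as a single error, whatever its length. Feedback events mirror what a
patient-facing UI would render (instructions, alerts, corrective arrows,
conclusions); attempt duration is recorded for the therapist but is never
placed in any event payload shown to the patient.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable

from .skeleton import JointName, SkeletonFrame, SkeletonStream, validate_frame
from .posture import (
    PostureTemplate,
    ThresholdConfig,
    balance_level,
    evaluate_posture,
    walking_template,
)

# Event kinds
TASK_INSTRUCTION = "task_instruction"
BALANCE_ALERT = "balance_alert"
MARGIN_TOUCH = "margin_touch"
MISALIGNED_BONES = "misaligned_bones"
CORRECTIVE_ARROW = "corrective_arrow"
CONGRATULATION = "congratulation"
CONCLUSION = "conclusion"

# Severities: intrusive alerts are reserved for faults that carry fall risk.
INFORMATIONAL = "informational"
INTRUSIVE = "intrusive"

_SEVERITY = {
    TASK_INSTRUCTION: INFORMATIONAL,
    BALANCE_ALERT: INTRUSIVE,
    MARGIN_TOUCH: INTRUSIVE,
    MISALIGNED_BONES: INFORMATIONAL,
    CORRECTIVE_ARROW: INFORMATIONAL,
    CONGRATULATION: INFORMATIONAL,
    CONCLUSION: INFORMATIONAL,
}

FAULT_BALANCE = "balance"
FAULT_MARGIN = "margin"
FAULT_POSTURE = "posture"

_CONCLUSION_MESSAGES = {
    FAULT_BALANCE: "Keep your shoulders level; avoid leaning to either side.",
    FAULT_MARGIN: "Stay between the walking lines.",
    FAULT_POSTURE: "Keep the upright posture while walking.",
}


class MonitorError(ValueError):
    pass


@dataclass
class ExerciseSpec:
    """Geometry and timing of the straight-line walking exercise."""

    course_length: float = 5.0
    start_z: float = 1.0
    finish_z: float | None = None  # defaults to start_z + course_length
    corridor_center_x: float = 0.0
    corridor_half_width: float = 0.25
    hold_seconds: float = 3.0
    start_zone_tolerance: float = 0.15
    direction: str = "forward"  # "backward" negates the z mapping

    def __post_init__(self) -> None:
        if not self.course_length > 0:
            raise ValueError("course_length must be > 0")
        if self.finish_z is None:
            self.finish_z = self.start_z + self.course_length
        if abs((self.finish_z - self.start_z) - self.course_length) > 1e-9:
            raise ValueError("finish_z - start_z must equal course_length")
        if not self.corridor_half_width > 0:
            raise ValueError("corridor_half_width must be > 0")
        if not self.hold_seconds > 0:
            raise ValueError("hold_seconds must be > 0")
        if not self.start_zone_tolerance > 0:
            raise ValueError("start_zone_tolerance must be > 0")
        if self.direction not in ("forward", "backward"):
            raise ValueError("direction must be 'forward' or 'backward'")

    # The walk is parameterized by signed advance so the backward variant is
    # a pure sign flip of the z mapping.
    @property
    def entry_z(self) -> float:
        return self.start_z if self.direction == "forward" else self.finish_z

    @property
    def exit_z(self) -> float:
        return self.finish_z if self.direction == "forward" else self.start_z

    def advance(self, z: float) -> float:
        if self.direction == "forward":
            return z - self.start_z
        return self.finish_z - z

    def to_json(self) -> str:
        return json.dumps(
            {
                "course_length": self.course_length,
                "start_z": self.start_z,
                "finish_z": self.finish_z,
                "corridor_center_x": self.corridor_center_x,
                "corridor_half_width": self.corridor_half_width,
                "hold_seconds": self.hold_seconds,
                "start_zone_tolerance": self.start_zone_tolerance,
                "direction": self.direction,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ExerciseSpec":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class FeedbackEvent:
    t: float
    kind: str
    severity: str
    payload: dict

    def to_dict(self) -> dict:
        return {
            "t": self.t,
            "kind": self.kind,
            "severity": self.severity,
            "payload": self.payload,
        }


@dataclass(frozen=True)
class ErrorEvent:
    fault_id: str
    start_t: float
    end_t: float

    def to_dict(self) -> dict:
        return {
            "fault_id": self.fault_id,
            "start_t": self.start_t,
            "end_t": self.end_t,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ErrorEvent":
        return cls(d["fault_id"], d["start_t"], d["end_t"])


class RunDebouncer:
    """Run-length fault detector.

    Feed one boolean per frame; a run is *confirmed* (and reported exactly
    once) after ``min_frames`` consecutive violating frames, and the whole
    maximal run is recorded as a single ``(start_t, end_t)`` interval.
    Runs shorter than ``min_frames`` are discarded as sensor flicker.
    """

    def __init__(self, min_frames: int):
        if min_frames < 1:
            raise ValueError("min_frames must be >= 1")
        self.min_frames = min_frames
        self.count = 0
        self._run_start: float | None = None
        self._last_violating_t: float | None = None
        self.runs: list[tuple[float, float]] = []

    def feed(self, t: float, violating: bool) -> bool:
        """Returns True exactly on the frame where a run is confirmed."""
        if violating:
            if self.count == 0:
                self._run_start = t
            self.count += 1
            self._last_violating_t = t
            return self.count == self.min_frames
        if self.count >= self.min_frames:
            self.runs.append((self._run_start, self._last_violating_t))
        self.count = 0
        self._run_start = None
        return False

    def finish(self) -> None:
        """Close a still-open confirmed run (stream or phase ended)."""
        if self.count >= self.min_frames:
            self.runs.append((self._run_start, self._last_violating_t))
        self.count = 0
        self._run_start = None


@dataclass
class ExerciseState:
    """Mutable state of one exercise attempt."""

    spec: ExerciseSpec
    template: PostureTemplate
    config: ThresholdConfig
    step: int = 1
    terminal: bool = False
    hold_elapsed: float = 0.0
    progress_frac: float = 0.0
    events_log: list[FeedbackEvent] = field(default_factory=list)
    error_events: list[ErrorEvent] = field(default_factory=list)
    attempt_start_t: float | None = None
    attempt_end_t: float | None = None
    step2_entry_z: float | None = None
    # internals
    _started: bool = False
    _last_t: float | None = None
    _hold_anchor_t: float | None = None
    _walk_template: PostureTemplate | None = None
    _debouncers: dict[str, RunDebouncer] = field(default_factory=dict)
    _fault_first_seen: dict[str, float] = field(default_factory=dict)

    @property
    def active_violations(self) -> dict[str, int]:
        """Consecutive violating-frame count per fault id (pre-debounce)."""
        return {k: d.count for k, d in self._debouncers.items() if d.count > 0}


def new_session(
    spec: ExerciseSpec, template: PostureTemplate, config: ThresholdConfig
) -> ExerciseState:
    """Fresh attempt state at step 1 with empty logs."""
    state = ExerciseState(spec=spec, template=template, config=config)
    state._walk_template = walking_template(template)
    for fault in (FAULT_BALANCE, FAULT_MARGIN, FAULT_POSTURE):
        state._debouncers[fault] = RunDebouncer(config.debounce_frames)
    return state


def corridor_check(frame: SkeletonFrame, spec: ExerciseSpec) -> str:
    """Which corridor boundary, if any, the subject is crossing.

    Checked on both ankles and the pelvis; the corridor is inclusive, so a
    point exactly on a line is not a touch. Returns "left", "right" or
    "none" (the side naming the crossed boundary; x grows to the right).
    """
    xs = [
        frame.coord(JointName.AnkleLeft, "x"),
        frame.coord(JointName.AnkleRight, "x"),
        frame.coord(JointName.HipCenter, "x"),
    ]
    left_bound = spec.corridor_center_x - spec.corridor_half_width
    right_bound = spec.corridor_center_x + spec.corridor_half_width
    left_excess = left_bound - min(xs)
    right_excess = max(xs) - right_bound
    if left_excess <= 0 and right_excess <= 0:
        return "none"
    return "left" if left_excess >= right_excess else "right"


def progress(state: ExerciseState) -> float:
    """Fraction of the course covered: 0 before the walk, 1 at/after finish."""
    return state.progress_frac


def _emit(state: ExerciseState, t: float, kind: str, payload: dict) -> FeedbackEvent:
    event = FeedbackEvent(t=t, kind=kind, severity=_SEVERITY[kind], payload=payload)
    state.events_log.append(event)
    return event


def _hold_update(state: ExerciseState, t: float, compliant: bool) -> bool:
    """Accumulate hold time over consecutive compliant frames.

    Any non-compliant frame resets the hold (the posture must be held
    without swinging movements). Returns True when the required hold is
    reached.
    """
    if not compliant:
        state._hold_anchor_t = None
        state.hold_elapsed = 0.0
        return False
    if state._hold_anchor_t is None:
        state._hold_anchor_t = t
    state.hold_elapsed = t - state._hold_anchor_t
    return state.hold_elapsed >= state.spec.hold_seconds


def _feed_fault(
    state: ExerciseState, t: float, fault_id: str, violating: bool
) -> bool:
    deb = state._debouncers[fault_id]
    confirmed = deb.feed(t, violating)
    if confirmed and fault_id not in state._fault_first_seen:
        state._fault_first_seen[fault_id] = t
    return confirmed


def _close_faults(state: ExerciseState) -> None:
    for fault_id, deb in state._debouncers.items():
        deb.finish()
        for start_t, end_t in deb.runs:
            state.error_events.append(ErrorEvent(fault_id, start_t, end_t))
        deb.runs.clear()
    state.error_events.sort(key=lambda e: (e.start_t, e.fault_id))


def _conclusions(state: ExerciseState) -> list[str]:
    seen: list[str] = []
    for event in sorted(state.error_events, key=lambda e: e.start_t):
        if event.fault_id not in seen:
            seen.append(event.fault_id)
    return [_CONCLUSION_MESSAGES.get(f, f"Correct fault: {f}") for f in seen]


def update(
    state: ExerciseState, frame: SkeletonFrame
) -> tuple[ExerciseState, list[FeedbackEvent]]:
    """Advance the state machine by one frame; returns new events.

    The spec, template and threshold configuration travel with the state.
    Raises :class:`MonitorError` on an invalid frame or a timestamp that
    runs backward.
    """
    events_before = len(state.events_log)
    problems = validate_frame(frame)
    if problems:
        raise MonitorError(f"invalid frame at t={frame.t}: {problems[0]}")
    if state._last_t is not None and frame.t < state._last_t:
        raise MonitorError(
            f"frame at t={frame.t} precedes previous t={state._last_t}"
        )
    if state.terminal:
        return state, []

    spec, config = state.spec, state.config
    if not state._started:
        state._started = True
        _emit(state, frame.t, TASK_INSTRUCTION, {
            "step": 1,
            "message": "Stand at the start line in an upright posture.",
        })

    hip_z = frame.coord(JointName.HipCenter, "z")

    if state.step == 1:
        in_zone = abs(hip_z - spec.entry_z) <= spec.start_zone_tolerance
        upright = in_zone and evaluate_posture(frame, state.template, config).correct
        compliant = in_zone and upright
        if compliant and state.attempt_start_t is None:
            state.attempt_start_t = frame.t
        if _hold_update(state, frame.t, compliant):
            state.step = 2
            state.step2_entry_z = hip_z
            state._hold_anchor_t = None
            state.hold_elapsed = 0.0
            _emit(state, frame.t, TASK_INSTRUCTION, {
                "step": 2,
                "message": "Walk straight ahead to the finish line.",
            })

    elif state.step == 2:
        # balance / lean
        lean = balance_level(frame, config)
        if _feed_fault(state, frame.t, FAULT_BALANCE, lean.alert):
            _emit(state, frame.t, BALANCE_ALERT, {"side": lean.side})
            _emit(state, frame.t, CORRECTIVE_ARROW, {
                "side": "right" if lean.side == "left" else "left",
            })
        # posture on the walking rule subset (if the mask leaves any)
        walk_rules = [
            r for r in state._walk_template.rules
            if r.body_part in config.included_parts
        ]
        if walk_rules:
            verdict = evaluate_posture(frame, state._walk_template, config)
            if _feed_fault(state, frame.t, FAULT_POSTURE, not verdict.correct):
                _emit(state, frame.t, MISALIGNED_BONES, {
                    "joints": sorted(j.value for j in verdict.misaligned_joints),
                })
        # corridor
        side = corridor_check(frame, spec)
        if _feed_fault(state, frame.t, FAULT_MARGIN, side != "none"):
            _emit(state, frame.t, MARGIN_TOUCH, {"side": side})

        state.progress_frac = max(
            state.progress_frac,
            min(1.0, max(0.0, spec.advance(hip_z) / spec.course_length)),
        )
        if spec.advance(hip_z) >= spec.course_length:
            state.step = 3
            state.progress_frac = 1.0
            for deb in state._debouncers.values():
                deb.finish()
            _emit(state, frame.t, TASK_INSTRUCTION, {
                "step": 3,
                "message": "Stop at the finish line and hold the upright posture.",
            })

    elif state.step == 3:
        at_finish = abs(hip_z - spec.exit_z) <= spec.start_zone_tolerance
        compliant = at_finish and evaluate_posture(
            frame, state.template, config
        ).correct
        if _hold_update(state, frame.t, compliant):
            state.terminal = True
            state.attempt_end_t = frame.t
            _close_faults(state)
            if state.error_events:
                _emit(state, frame.t, CONCLUSION, {
                    "messages": _conclusions(state),
                })
            else:
                _emit(state, frame.t, CONGRATULATION, {
                    "message": "Well done — attempt completed without errors!",
                })

    state._last_t = frame.t
    return state, state.events_log[events_before:]


def _build_result(state: ExerciseState, index: int, complete: bool) -> "AttemptResult":
    if not complete:
        _close_faults(state)
    duration = 0.0
    if state.attempt_start_t is not None:
        end = state.attempt_end_t if state.attempt_end_t is not None else state._last_t
        if end is not None:
            duration = end - state.attempt_start_t
    return AttemptResult(
        index=index,
        success=complete and not state.error_events,
        error_events=list(state.error_events),
        duration=duration,
        conclusions=_conclusions(state),
        complete=complete,
    )


@dataclass
class AttemptResult:
    """Outcome of one attempt, as reported to the therapist.

    ``duration`` is therapist-only data: it appears here and in session
    reports but never in patient-facing feedback events.
    """

    index: int
    success: bool
    error_events: list[ErrorEvent]
    duration: float
    conclusions: list[str]
    complete: bool = True

    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "success": self.success,
            "error_events": [e.to_dict() for e in self.error_events],
            "duration": self.duration,
            "conclusions": list(self.conclusions),
            "complete": self.complete,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AttemptResult":
        return cls(
            index=d["index"],
            success=d["success"],
            error_events=[ErrorEvent.from_dict(e) for e in d["error_events"]],
            duration=d["duration"],
            conclusions=list(d["conclusions"]),
            complete=d.get("complete", True),
        )


def finalize_attempt(state: ExerciseState, index: int = 1) -> AttemptResult:
    """Summarize a terminal attempt. Raises if the attempt is still running."""
    if not state.terminal:
        raise MonitorError("attempt has not completed; cannot finalize")
    return _build_result(state, index, complete=True)


def run_attempt(
    stream: SkeletonStream,
    spec: ExerciseSpec,
    template: PostureTemplate,
    config: ThresholdConfig,
    index: int = 1,
) -> tuple[AttemptResult, list[FeedbackEvent]]:
    """Batch driver: fold :func:`update` over a stream, then finalize.

    If the stream ends before the attempt completes the result is flagged
    ``complete=False`` (and cannot be a success).
    """
    state = new_session(spec, template, config)
    for frame in stream:
        state, _ = update(state, frame)
        if state.terminal:
            break
    if state.terminal:
        return finalize_attempt(state, index), state.events_log
    return _build_result(state, index, complete=False), state.events_log
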