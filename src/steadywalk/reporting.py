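"""Therapist-facing session reports and parameter updates.

A session report aggregates the attempts of one session — successes, error
counts per fault, per-attempt and mean durations — together with a snapshot
of the threshold configuration in force. Reports serialize to JSON; parsing
recomputes the totals from the attempt list and rejects files whose stored
totals disagree (a tamper/corruption guard, since reports travel between
the patient's machine and the therapist).

Therapist updates are the remote half of the adaptation loop: a small JSON
document changing strictness, per-rule overrides, the body-part mask or
exercise-spec fields, applied atomically and logged with a timestamp.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone

from .monitor import AttemptResult, ExerciseSpec
from .posture import ThresholdConfig


class ReportIntegrityError(ValueError):
    pass


class UpdateRejectedError(ValueError):
    pass


def _totals(attempts: list[AttemptResult]) -> dict:
    errors_by_fault: dict[str, int] = {}
    for a in attempts:
        for e in a.error_events:
            errors_by_fault[e.fault_id] = errors_by_fault.get(e.fault_id, 0) + 1
    return {
        "attempts": len(attempts),
        "successes": sum(1 for a in attempts if a.success),
        "total_errors": sum(len(a.error_events) for a in attempts),
        "errors_by_fault": dict(sorted(errors_by_fault.items())),
    }


@dataclass
class SessionReport:
    session_id: str
    patient_id: str  # opaque identifier; no personal data is modeled
    attempts: list[AttemptResult]
    totals: dict
    durations: list[float]
    mean_duration: float
    config_snapshot: ThresholdConfig


def summarize(
    attempts: list[AttemptResult],
    config: ThresholdConfig,
    session_id: str = "session-1",
    patient_id: str = "anonymous",
) -> SessionReport:
    """Deterministic aggregation of a session's attempts."""
    durations = [a.duration for a in attempts]
    mean = sum(durations) / len(durations) if durations else 0.0
    return SessionReport(
        session_id=session_id,
        patient_id=patient_id,
        attempts=list(attempts),
        totals=_totals(attempts),
        durations=durations,
        mean_duration=mean,
        config_snapshot=config,
    )


def serialize_report(report: SessionReport) -> str:
    return json.dumps(
        {
            "session_id": report.session_id,
            "patient_id": report.patient_id,
            "attempts": [a.to_dict() for a in report.attempts],
            "totals": report.totals,
            "durations": report.durations,
            "mean_duration": report.mean_duration,
            "config_snapshot": json.loads(report.config_snapshot.to_json()),
        },
        indent=2,
        ensure_ascii=False,
    )


def parse_report(text: str) -> SessionReport:
    """Parse a report and verify its totals against the attempt list."""
    doc = json.loads(text)
    attempts = [AttemptResult.from_dict(a) for a in doc["attempts"]]
    recomputed = _totals(attempts)
    if doc.get("totals") != recomputed:
        raise ReportIntegrityError(
            f"stored totals {doc.get('totals')} disagree with "
            f"recomputed {recomputed}"
        )
    config = ThresholdConfig.from_json(json.dumps(doc["config_snapshot"]))
    return SessionReport(
        session_id=doc["session_id"],
        patient_id=doc["patient_id"],
        attempts=attempts,
        totals=recomputed,
        durations=list(doc["durations"]),
        mean_duration=doc["mean_duration"],
        config_snapshot=config,
    )


@dataclass
class TherapistUpdate:
    """A partial change to the monitoring parameters; None means keep."""

    strictness: float | None = None
    overrides: dict[str, float] | None = None
    included_parts: set[str] | None = None
    balance_epsilon: float | None = None
    debounce_frames: int | None = None
    spec_changes: dict | None = None
    note: str = ""

    @classmethod
    def from_json(cls, text: str) -> "TherapistUpdate":
        doc = json.loads(text)
        return cls(
            strictness=doc.get("strictness"),
            overrides=doc.get("overrides"),
            included_parts=(
                set(doc["included_parts"]) if "included_parts" in doc else None
            ),
            balance_epsilon=doc.get("balance_epsilon"),
            debounce_frames=doc.get("debounce_frames"),
            spec_changes=doc.get("spec_changes"),
            note=doc.get("note", ""),
        )

    def to_json(self) -> str:
        doc: dict = {}
        if self.strictness is not None:
            doc["strictness"] = self.strictness
        if self.overrides is not None:
            doc["overrides"] = self.overrides
        if self.included_parts is not None:
            doc["included_parts"] = sorted(self.included_parts)
        if self.balance_epsilon is not None:
            doc["balance_epsilon"] = self.balance_epsilon
        if self.debounce_frames is not None:
            doc["debounce_frames"] = self.debounce_frames
        if self.spec_changes is not None:
            doc["spec_changes"] = self.spec_changes
        doc["note"] = self.note
        return json.dumps(doc, indent=2, ensure_ascii=False)


def apply_update(
    config: ThresholdConfig,
    spec: ExerciseSpec,
    update: TherapistUpdate,
    now: datetime | None = None,
) -> tuple[ThresholdConfig, ExerciseSpec, dict]:
    """Apply a therapist update; only named fields change.

    Returns the new (config, spec) plus a timestamped change-log entry.
    Raises :class:`UpdateRejectedError` if the result would violate the
    configuration invariants (e.g. non-positive strictness or an empty
    body-part mask).
    """
    changes: dict = {}
    cfg_kwargs = dict(
        strictness=config.strictness,
        overrides=dict(config.overrides),
        included_parts=set(config.included_parts),
        balance_epsilon=config.balance_epsilon,
        debounce_frames=config.debounce_frames,
    )
    for name in (
        "strictness", "overrides", "included_parts",
        "balance_epsilon", "debounce_frames",
    ):
        value = getattr(update, name)
        if value is not None:
            changes[name] = value if not isinstance(value, set) else sorted(value)
            cfg_kwargs[name] = value
    try:
        new_config = ThresholdConfig(**cfg_kwargs)
    except ValueError as exc:
        raise UpdateRejectedError(f"invalid configuration update: {exc}")

    spec_kwargs = {
        f.name: getattr(spec, f.name) for f in dataclasses.fields(ExerciseSpec)
    }
    if update.spec_changes:
        unknown = set(update.spec_changes) - set(spec_kwargs)
        if unknown:
            raise UpdateRejectedError(f"unknown exercise fields: {sorted(unknown)}")
        # changing the course geometry must keep start/length/finish coherent
        if (
            "course_length" in update.spec_changes
            or "start_z" in update.spec_changes
        ) and "finish_z" not in update.spec_changes:
            spec_kwargs["finish_z"] = None
        spec_kwargs.update(update.spec_changes)
        changes["spec"] = dict(update.spec_changes)
    try:
        new_spec = ExerciseSpec(**spec_kwargs)
    except ValueError as exc:
        raise UpdateRejectedError(f"invalid exercise update: {exc}")

    stamp = (now or datetime.now(timezone.utc)).isoformat()
    log_entry = {"timestamp": stamp, "changes": changes, "note": update.note}
    return new_config, new_spec, log_entry
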