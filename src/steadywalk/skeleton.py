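"""Skeleton data model and the line-delimited JSON stream dialect.

One skeleton frame is a timestamped snapshot of 20 named body joints, each
with an (x, y, z) position in meters:

* x — lateral, positive toward the patient's right as seen by the sensor,
* y — vertical, up positive,
* z — longitudinal, increasing along the walking direction away from the
  sensor.

A stream file is JSONL: one header object with metadata followed by one
object per frame, ``{"t": <seconds>, "joints": {<name>: [x, y, z], ...}}``.
Timestamps are seconds since stream start and must be strictly increasing.
Frames with missing, duplicated or non-finite joints are rejected at parse
time with the offending line number; occluded joints are never imputed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator


class JointName(str, Enum):
    """The 20 tracked joints of a Kinect-v1-style skeleton."""

    HipCenter = "HipCenter"
    Spine = "Spine"
    ShoulderCenter = "ShoulderCenter"
    Head = "Head"
    ShoulderLeft = "ShoulderLeft"
    ElbowLeft = "ElbowLeft"
    WristLeft = "WristLeft"
    HandLeft = "HandLeft"
    ShoulderRight = "ShoulderRight"
    ElbowRight = "ElbowRight"
    WristRight = "WristRight"
    HandRight = "HandRight"
    HipLeft = "HipLeft"
    KneeLeft = "KneeLeft"
    AnkleLeft = "AnkleLeft"
    FootLeft = "FootLeft"
    HipRight = "HipRight"
    KneeRight = "KneeRight"
    AnkleRight = "AnkleRight"
    FootRight = "FootRight"

    def __str__(self) -> str:  # "HipCenter", not "JointName.HipCenter"
        return self.value


#: Canonical serialization order for joints within a frame record.
JOINT_ORDER: tuple[JointName, ...] = tuple(JointName)

N_JOINTS = 20


class StreamFormatError(ValueError):
    """Raised when a skeleton stream violates the dialect; carries the line."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class Joint:
    """One named joint position, in meters."""

    name: JointName
    x: float
    y: float
    z: float

    def coord(self, axis: str) -> float:
        return getattr(self, axis)


@dataclass
class SkeletonFrame:
    """Timestamp plus the full 20-joint map; the unit of all monitoring."""

    t: float
    joints: dict[JointName, Joint]

    def pos(self, name: JointName) -> tuple[float, float, float]:
        j = self.joints[name]
        return (j.x, j.y, j.z)

    def coord(self, name: JointName, axis: str) -> float:
        return self.joints[name].coord(axis)

    def translated(self, dx: float, dy: float, dz: float) -> "SkeletonFrame":
        """A copy with every joint shifted by a constant vector."""
        return SkeletonFrame(
            t=self.t,
            joints={
                n: Joint(n, j.x + dx, j.y + dy, j.z + dz)
                for n, j in self.joints.items()
            },
        )


@dataclass
class StreamMetadata:
    """Nominal capture metadata. ``subject_height`` is informational only:
    all posture logic compares coordinates relative to the subject, so the
    engine never reads it."""

    fps: float | None = None
    subject_height: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.fps is not None and not self.fps > 0:
            raise ValueError(f"fps must be positive, got {self.fps}")


@dataclass
class SkeletonStream:
    meta: StreamMetadata
    frames: list[SkeletonFrame] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[SkeletonFrame]:
        return iter(self.frames)

    @property
    def duration(self) -> float:
        if not self.frames:
            return 0.0
        return self.frames[-1].t - self.frames[0].t


def validate_frame(frame: SkeletonFrame) -> list[str]:
    """Report invariant violations of a frame; empty list means valid.

    Never raises: callers decide whether a violation is fatal. Each
    descriptor names the offending joint (and axis for non-finite values).
    """
    problems: list[str] = []
    if frame.t < 0 or not math.isfinite(frame.t):
        problems.append(f"timestamp must be finite and >= 0, got {frame.t}")
    for name in JOINT_ORDER:
        if name not in frame.joints:
            problems.append(f"missing joint {name.value}")
    for name, joint in frame.joints.items():
        if name not in JointName.__members__.values():
            problems.append(f"unknown joint {name}")
            continue
        for axis in ("x", "y", "z"):
            v = joint.coord(axis)
            if not math.isfinite(v):
                problems.append(f"non-finite coordinate {name.value}.{axis}")
    return problems


def _frame_from_record(record: dict, line: int) -> SkeletonFrame:
    try:
        t = float(record["t"])
    except (KeyError, TypeError, ValueError):
        raise StreamFormatError("frame record lacks a numeric 't'", line)
    raw = record.get("joints")
    if not isinstance(raw, dict):
        raise StreamFormatError("frame record lacks a 'joints' object", line)
    joints: dict[JointName, Joint] = {}
    for key, xyz in raw.items():
        try:
            name = JointName(key)
        except ValueError:
            raise StreamFormatError(f"unknown joint name {key!r}", line)
        if name in joints:
            raise StreamFormatError(f"duplicate joint {name.value}", line)
        if not (isinstance(xyz, (list, tuple)) and len(xyz) == 3):
            raise StreamFormatError(
                f"joint {name.value} must be a 3-element [x, y, z] array", line
            )
        joints[name] = Joint(name, float(xyz[0]), float(xyz[1]), float(xyz[2]))
    frame = SkeletonFrame(t=t, joints=joints)
    problems = validate_frame(frame)
    if problems:
        raise StreamFormatError("; ".join(problems), line)
    return frame


def parse_stream(lines: str | Iterable[str]) -> SkeletonStream:
    """Parse the JSONL skeleton dialect into a validated stream.

    The first non-blank line is the metadata header; every later non-blank
    line is one frame record. Raises :class:`StreamFormatError` (with the
    line number) on any malformed record, incomplete frame, non-finite
    coordinate, or non-monotone timestamp. An accepted stream is non-empty.
    """
    if isinstance(lines, str):
        lines = lines.splitlines()
    meta: StreamMetadata | None = None
    frames: list[SkeletonFrame] = []
    last_t: float | None = None
    for lineno, raw in enumerate(lines, start=1):
        text = raw.strip()
        if not text:
            continue
        try:
            record = json.loads(text)
        except json.JSONDecodeError as exc:
            raise StreamFormatError(f"invalid JSON: {exc.msg}", lineno)
        if not isinstance(record, dict):
            raise StreamFormatError("each line must be a JSON object", lineno)
        if meta is None:
            if "t" in record or "joints" in record:
                raise StreamFormatError(
                    "first line must be the metadata header", lineno
                )
            fps = record.get("fps")
            try:
                meta = StreamMetadata(
                    fps=None if fps is None else float(fps),
                    subject_height=record.get("subject_height"),
                    source=str(record.get("source", "")),
                )
            except ValueError as exc:
                raise StreamFormatError(str(exc), lineno)
            continue
        frame = _frame_from_record(record, lineno)
        if last_t is not None and frame.t <= last_t:
            raise StreamFormatError(
                f"timestamps must be strictly increasing "
                f"({frame.t} after {last_t})",
                lineno,
            )
        last_t = frame.t
        frames.append(frame)
    if meta is None:
        raise StreamFormatError("stream has no metadata header")
    if not frames:
        raise StreamFormatError("stream contains no frames")
    return SkeletonStream(meta=meta, frames=frames)


def write_stream(stream: SkeletonStream) -> str:
    """Serialize a stream canonically; exact inverse of :func:`parse_stream`.

    Joints are written in the fixed enum order and floats use Python's
    shortest round-trip representation, so writing is deterministic and the
    parse/write round trip is bit-exact.
    """
    if not stream.frames:
        raise ValueError("cannot serialize an empty stream")
    header: dict = {"source": stream.meta.source}
    if stream.meta.fps is not None:
        header["fps"] = stream.meta.fps
    if stream.meta.subject_height is not None:
        header["subject_height"] = stream.meta.subject_height
    out = [json.dumps(header, sort_keys=True)]
    for frame in stream.frames:
        problems = validate_frame(frame)
        if problems:
            raise ValueError(f"invalid frame at t={frame.t}: {problems[0]}")
        record = {
            "t": frame.t,
            "joints": {
                name.value: [
                    frame.joints[name].x,
                    frame.joints[name].y,
                    frame.joints[name].z,
                ]
                for name in JOINT_ORDER
            },
        }
        out.append(json.dumps(record))
    return "\n".join(out) + "\n"
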