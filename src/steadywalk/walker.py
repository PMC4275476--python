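"""Seeded synthetic walker: parametric skeleton streams with ground truth.

Generates Kinect-v1-style 20-joint streams of a person standing upright and
walking a straight course, with controllable impairments — constant lateral
lean, lateral drift, body sway, arm swing and Gaussian joint noise — so the
posture engine and exercise monitor are testable end-to-end without any
sensor hardware. Every stream is driven by a single seeded generator with
noise drawn in a fixed joint order, so identical parameters and seed yield
bitwise-identical streams after canonical serialization.

Lean is modeled as a vertical shear of the upper body about the hip center:
each upper joint drops by ``(x - x_hip) * sin(lean)``. This keeps the
lateral shoulder distance constant, so the shoulder-asymmetry balance
measure recovers exactly ``sin(lean)`` from noiseless frames — the
generator and the detector agree analytically, which is what makes the
sharp-threshold tests meaningful.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable

import numpy as np

from .skeleton import (
    JOINT_ORDER,
    Joint,
    JointName,
    SkeletonFrame,
    SkeletonStream,
    StreamMetadata,
)
from .monitor import ExerciseSpec

#: Joints displaced by the lean shear (everything above the pelvis).
UPPER_BODY: frozenset[JointName] = frozenset(
    {
        JointName.Spine,
        JointName.ShoulderCenter,
        JointName.Head,
        JointName.ShoulderLeft,
        JointName.ElbowLeft,
        JointName.WristLeft,
        JointName.HandLeft,
        JointName.ShoulderRight,
        JointName.ElbowRight,
        JointName.WristRight,
        JointName.HandRight,
    }
)

_ARM_JOINTS_LEFT = (JointName.ElbowLeft, JointName.WristLeft, JointName.HandLeft)
_ARM_JOINTS_RIGHT = (JointName.ElbowRight, JointName.WristRight, JointName.HandRight)

#: Extra standing time beyond the required hold, so the monitor has margin
#: to confirm the hold before the walk phase begins (seconds).
HOLD_MARGIN = 1.0

_ARM_SWING_FREQ = 1.0  # Hz, typical slow-gait arm cadence


class AnthropometricModel:
    """Fixed per-joint offsets as fractions of standing height.

    Shipped as a data table (``data/anthropometry.json``); left/right
    symmetric in the lateral axis by construction.
    """

    def __init__(self, offsets: dict[JointName, tuple[float, float, float]]):
        if set(offsets) != set(JOINT_ORDER):
            raise ValueError("anthropometric table must cover all 20 joints")
        for name, (x, y, z) in offsets.items():
            mirror = _mirror_name(name)
            mx, my, mz = offsets[mirror]
            if not (math.isclose(x, -mx) and my == y and mz == z):
                raise ValueError(f"offsets not left/right symmetric at {name}")
        self.offsets = offsets

    @classmethod
    def default(cls) -> "AnthropometricModel":
        text = (
            resources.files("steadywalk") / "data" / "anthropometry.json"
        ).read_text()
        doc = json.loads(text)
        return cls(
            {JointName(k): tuple(v) for k, v in doc["offsets"].items()}
        )

    def shoulder_width(self, height: float) -> float:
        left = self.offsets[JointName.ShoulderLeft][0]
        right = self.offsets[JointName.ShoulderRight][0]
        return abs(right - left) * height


def _mirror_name(name: JointName) -> JointName:
    if name.value.endswith("Left"):
        return JointName(name.value[:-4] + "Right")
    if name.value.endswith("Right"):
        return JointName(name.value[:-5] + "Left")
    return name


@dataclass
class WalkerParams:
    """Parameters of the simulated subject and their impairments.

    lean_deg
        Constant lateral lean in degrees; positive lowers the *right*
        shoulder. ``lean_profile`` (deg as a function of t) overrides it.
    drift_rate
        Lateral drift in meters per meter of forward advance.
    sway_amp / sway_freq
        Sinusoidal whole-body lateral sway (rigid translation).
    arm_swing_amp
        Longitudinal arm-swing amplitude during the walk phase.
    noise_sd
        Std. dev. of iid Gaussian noise added to every coordinate, meters.
    """

    height: float = 1.7
    speed: float = 0.5
    fps: float = 30.0
    lean_deg: float = 0.0
    lean_profile: Callable[[float], float] | None = None
    drift_rate: float = 0.0
    sway_amp: float = 0.01
    sway_freq: float = 0.3
    arm_swing_amp: float = 0.03
    noise_sd: float = 0.003
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.height > 0:
            raise ValueError("height must be > 0")
        if not self.speed > 0:
            raise ValueError("speed must be > 0")
        if not self.fps > 0:
            raise ValueError("fps must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _lean_at(params: WalkerParams, t: float) -> float:
    if params.lean_profile is not None:
        return params.lean_profile(t)
    return params.lean_deg


def _apply_lean(
    joints: dict[JointName, Joint], lean_deg: float, pivot_x: float
) -> None:
    if lean_deg == 0.0:
        return
    s = math.sin(math.radians(lean_deg))
    for name in UPPER_BODY:
        j = joints[name]
        joints[name] = Joint(name, j.x, j.y - (j.x - pivot_x) * s, j.z)


def _make_frame(
    model: AnthropometricModel,
    params: WalkerParams,
    t: float,
    center_x: float,
    z: float,
    lean_deg: float,
    arm_phase: float | None,
    rng: np.random.Generator,
) -> SkeletonFrame:
    h = params.height
    joints: dict[JointName, Joint] = {}
    for name in JOINT_ORDER:
        ox, oy, oz = model.offsets[name]
        joints[name] = Joint(name, center_x + ox * h, oy * h, z + oz * h)
    _apply_lean(joints, lean_deg, pivot_x=center_x)
    if arm_phase is not None and params.arm_swing_amp > 0:
        swing = params.arm_swing_amp * math.sin(arm_phase)
        for name in _ARM_JOINTS_LEFT:
            j = joints[name]
            joints[name] = Joint(name, j.x, j.y, j.z + swing)
        for name in _ARM_JOINTS_RIGHT:
            j = joints[name]
            joints[name] = Joint(name, j.x, j.y, j.z - swing)
    if params.noise_sd > 0:
        noise = rng.normal(0.0, params.noise_sd, size=(len(JOINT_ORDER), 3))
        for i, name in enumerate(JOINT_ORDER):
            j = joints[name]
            joints[name] = Joint(
                name, j.x + noise[i, 0], j.y + noise[i, 1], j.z + noise[i, 2]
            )
    return SkeletonFrame(t=t, joints=joints)


def _metadata(params: WalkerParams) -> StreamMetadata:
    return StreamMetadata(
        fps=params.fps,
        subject_height=params.height,
        source="steadywalk.walker",
    )


def standing_frames(
    params: WalkerParams,
    duration: float,
    z: float = 1.0,
    center_x: float = 0.0,
) -> SkeletonStream:
    """Stationary upright subject at longitudinal position ``z``.

    Only lean and noise apply; there is no sway, drift or arm swing, so
    noiseless shoulder asymmetry follows the closed form
    ``shoulder_width * sin(lean)`` at every frame.
    """
    if not duration > 0:
        raise ValueError("duration must be > 0")
    model = AnthropometricModel.default()
    rng = np.random.default_rng(params.seed)
    frames = []
    n = int(round(duration * params.fps))
    for i in range(n):
        t = i / params.fps
        frames.append(
            _make_frame(
                model, params, t, center_x, z,
                _lean_at(params, t), arm_phase=None, rng=rng,
            )
        )
    return SkeletonStream(meta=_metadata(params), frames=frames)


def walking_stream(params: WalkerParams, spec: ExerciseSpec) -> SkeletonStream:
    """Full exercise recording: hold at the start, walk the course, hold at
    the finish.

    The standing holds last ``spec.hold_seconds + 1`` s so the monitor can
    confirm them. During the walk the pelvis advances at constant speed;
    drift and sway displace the whole skeleton laterally (rigid
    translations), arm swing displaces arm joints longitudinally.
    """
    t_hold = spec.hold_seconds + HOLD_MARGIN
    t_walk = spec.course_length / params.speed
    if t_walk * params.fps < 2:
        raise ValueError(
            f"speed {params.speed} m/s spans the course in fewer than 2 frames"
        )
    total = t_hold + t_walk + t_hold
    model = AnthropometricModel.default()
    rng = np.random.default_rng(params.seed)
    sign = 1.0 if spec.direction == "forward" else -1.0
    frames = []
    n = int(round(total * params.fps))
    for i in range(n):
        t = i / params.fps
        if t < t_hold:
            advance = 0.0
            arm_phase = None
        elif t < t_hold + t_walk:
            advance = params.speed * (t - t_hold)
            arm_phase = 2 * math.pi * _ARM_SWING_FREQ * (t - t_hold)
        else:
            advance = spec.course_length
            arm_phase = None
        z = spec.entry_z + sign * advance
        center_x = (
            spec.corridor_center_x
            + params.drift_rate * advance
            + params.sway_amp * math.sin(2 * math.pi * params.sway_freq * t)
        )
        frames.append(
            _make_frame(
                model, params, t, center_x, z,
                _lean_at(params, t), arm_phase, rng,
            )
        )
    return SkeletonStream(meta=_metadata(params), frames=frames)


def inject_fault(
    stream: SkeletonStream,
    fault: str,
    window: tuple[float, float],
    magnitude: float,
) -> tuple[SkeletonStream, dict]:
    """Overlay a labeled impairment on an existing stream.

    fault
        ``"lean"`` — step change of lateral lean (magnitude in degrees,
        positive lowers the right shoulder), applied as the same upper-body
        shear the generator uses, pivoted at each frame's own hip center;
        ``"drift"`` — constant lateral offset of the whole skeleton
        (magnitude in meters);
        ``"freeze"`` — joints pinned to their positions at the window start
        (magnitude ignored).

    Returns the modified stream and a ground-truth descriptor
    ``{"kind", "t0", "t1", "magnitude"}`` for assertions.
    """
    t0, t1 = window
    if not (t1 > t0):
        raise ValueError("fault window must have t1 > t0")
    if t0 < stream.frames[0].t or t1 > stream.frames[-1].t:
        raise ValueError("fault window must lie within the stream span")
    if fault not in ("lean", "drift", "freeze"):
        raise ValueError(f"unknown fault kind {fault!r}")

    out_frames: list[SkeletonFrame] = []
    frozen: dict[JointName, Joint] | None = None
    for frame in stream.frames:
        if not (t0 <= frame.t <= t1) or (fault != "freeze" and magnitude == 0.0):
            out_frames.append(frame)
            continue
        joints = dict(frame.joints)
        if fault == "lean":
            _apply_lean(
                joints, magnitude, pivot_x=joints[JointName.HipCenter].x
            )
        elif fault == "drift":
            joints = {
                n: Joint(n, j.x + magnitude, j.y, j.z) for n, j in joints.items()
            }
        elif fault == "freeze":
            if frozen is None:
                frozen = dict(frame.joints)
            joints = {
                n: Joint(n, j.x, j.y, j.z) for n, j in frozen.items()
            }
        out_frames.append(SkeletonFrame(t=frame.t, joints=joints))
    truth = {"kind": fault, "t0": t0, "t1": t1, "magnitude": magnitude}
    return SkeletonStream(meta=copy.copy(stream.meta), frames=out_frames), truth
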