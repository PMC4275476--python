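"""Exercise state machine, debouncing, feedback events, attempt results."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import steadywalk as sw
from steadywalk import JointName as J
from steadywalk.monitor import (
    BALANCE_ALERT,
    CONGRATULATION,
    CORRECTIVE_ARROW,
    FAULT_BALANCE,
    TASK_INSTRUCTION,
)


def _fold(stream, spec, template, config):
    """Incremental drive of the monitor, recording (t, step, progress)."""
    state = sw.new_session(spec, template, config)
    trace = []
    for frame in stream:
        state, _ = sw.update(state, frame)
        trace.append((frame.t, state.step, sw.progress(state)))
        if state.terminal:
            break
    return state, trace


class TestNewSession:
    def test_fresh_state(self, spec, template, config):
        state = sw.new_session(spec, template, config)
        assert state.step == 1
        assert sw.progress(state) == 0.0
        assert state.events_log == []
        assert state.active_violations == {}

    def test_inconsistent_spec_rejected(self):
        with pytest.raises(ValueError):
            sw.ExerciseSpec(course_length=-1.0)
        with pytest.raises(ValueError):
            sw.ExerciseSpec(start_z=1.0, finish_z=3.0, course_length=5.0)

    def test_first_update_emits_task_instruction(self, spec, template, config,
                                                 upright_frame):
        state = sw.new_session(spec, template, config)
        _, events = sw.update(state, upright_frame)
        assert events and events[0].kind == TASK_INSTRUCTION


class TestCorridorCheck:
    def test_centered_walker_inside(self, upright_frame, spec):
        assert sw.corridor_check(upright_frame, spec) == "none"

    def test_offset_pelvis_crosses_right(self, spec):
        joints = {n: sw.Joint(n, 0.0, 1.0, 2.0) for n in sw.JOINT_ORDER}
        joints[J.HipCenter] = sw.Joint(J.HipCenter, 0.30, 1.0, 2.0)
        frame = sw.SkeletonFrame(t=0.0, joints=joints)
        assert sw.corridor_check(frame, spec) == "right"

    def test_exactly_on_the_boundary_is_inside(self, spec):
        joints = {n: sw.Joint(n, 0.0, 1.0, 2.0) for n in sw.JOINT_ORDER}
        joints[J.HipCenter] = sw.Joint(J.HipCenter, spec.corridor_half_width, 1.0, 2.0)
        frame = sw.SkeletonFrame(t=0.0, joints=joints)
        assert sw.corridor_check(frame, spec) == "none"


class TestCleanAttempt:
    def test_step_sequence_success_and_congratulation(
        self, clean_stream, spec, template, config
    ):
        result, events = sw.run_attempt(clean_stream, spec, template, config)
        assert result.success and result.complete
        assert result.error_events == []
        assert result.conclusions == []
        assert any(e.kind == CONGRATULATION for e in events)

    def test_step_only_increases_through_1_2_3(
        self, clean_stream, spec, template, config
    ):
        _, trace = _fold(clean_stream, spec, template, config)
        steps = [s for _, s, _ in trace]
        assert all(b >= a for a, b in zip(steps, steps[1:]))
        assert sorted(set(steps)) == [1, 2, 3]

    def test_progress_zero_then_half_then_one(
        self, clean_stream, spec, template, config
    ):
        _, trace = _fold(clean_stream, spec, template, config)
        by_t = {t: (s, p) for t, s, p in trace}
        for t, (step, prog) in by_t.items():
            if step == 1:
                assert prog == 0.0
        # pelvis at mid-course: hold(4 s) + 2.5 m / 0.5 m/s = 9 s
        step, prog = by_t[9.0]
        assert step == 2 and prog == pytest.approx(0.5, abs=0.02)
        assert trace[-1][2] == 1.0

    def test_progress_non_decreasing(self, clean_stream, spec, template, config):
        _, trace = _fold(clean_stream, spec, template, config)
        progs = [p for _, _, p in trace]
        assert all(b >= a for a, b in zip(progs, progs[1:]))

    def test_duration_matches_attempt_window(
        self, clean_stream, spec, template, config
    ):
        result, _ = sw.run_attempt(clean_stream, spec, template, config)
        # compliant from t=0; hold(3) + margin(1) + walk(10) + hold(3)
        assert result.duration == pytest.approx(17.0, abs=1 / 30 + 1e-9)

    def test_batch_equals_incremental_fold(self, clean_stream, spec, template, config):
        batch_result, batch_events = sw.run_attempt(
            clean_stream, spec, template, config
        )
        state, _ = _fold(clean_stream, spec, template, config)
        folded_result = sw.finalize_attempt(state)
        assert folded_result.to_dict() == batch_result.to_dict()
        assert [e.to_dict() for e in state.events_log] == [
            e.to_dict() for e in batch_events
        ]

    def test_deterministic_event_logs(self, clean_stream, spec, template, config):
        _, events_a = sw.run_attempt(clean_stream, spec, template, config)
        _, events_b = sw.run_attempt(clean_stream, spec, template, config)
        assert [e.to_dict() for e in events_a] == [e.to_dict() for e in events_b]


class TestIncompleteAttempts:
    def test_never_reaching_the_start_zone_stays_at_step_1(
        self, spec, template, config
    ):
        stream = sw.standing_frames(
            sw.WalkerParams(noise_sd=0.0, seed=2), duration=6.0,
            z=spec.start_z + 2.0,
        )
        result, _ = sw.run_attempt(stream, spec, template, config)
        assert not result.complete and not result.success
        state, trace = _fold(stream, spec, template, config)
        assert all(s == 1 for _, s, _ in trace)

    def test_single_frame_stream_is_incomplete(self, upright_frame, spec,
                                               template, config):
        stream = sw.SkeletonStream(
            meta=sw.StreamMetadata(fps=30.0), frames=[upright_frame]
        )
        result, _ = sw.run_attempt(stream, spec, template, config)
        assert not result.complete

    def test_finalize_before_terminal_raises(self, spec, template, config,
                                             upright_frame):
        state = sw.new_session(spec, template, config)
        state, _ = sw.update(state, upright_frame)
        with pytest.raises(sw.MonitorError, match="not completed"):
            sw.finalize_attempt(state)


class TestInjectedLean:
    def test_single_balance_run_covering_the_fault_window(
        self, clean_stream, spec, template, config
    ):
        faulty, truth = sw.inject_fault(clean_stream, "lean", (6.0, 9.0), 10.0)
        result, events = sw.run_attempt(faulty, spec, template, config)
        assert not result.success
        balance_runs = [e for e in result.error_events if e.fault_id == FAULT_BALANCE]
        assert len(balance_runs) == 1
        debounce_span = config.debounce_frames / 30.0
        run = balance_runs[0]
        assert run.start_t == pytest.approx(truth["t0"], abs=debounce_span)
        assert run.end_t == pytest.approx(truth["t1"], abs=debounce_span)

    def test_corrective_arrow_points_away_from_the_lower_shoulder(
        self, clean_stream, spec, template, config
    ):
        # positive lean lowers the right shoulder -> correct toward the left
        faulty, _ = sw.inject_fault(clean_stream, "lean", (6.0, 9.0), 10.0)
        _, events = sw.run_attempt(faulty, spec, template, config)
        alerts = [e for e in events if e.kind == BALANCE_ALERT]
        arrows = [e for e in events if e.kind == CORRECTIVE_ARROW]
        assert alerts and alerts[0].payload["side"] == "right"
        assert arrows and arrows[0].payload["side"] == "left"

    def test_two_disjoint_fault_windows_give_two_error_runs(
        self, clean_stream, spec, template, config
    ):
        faulty, _ = sw.inject_fault(clean_stream, "lean", (5.0, 6.5), 10.0)
        faulty, _ = sw.inject_fault(faulty, "lean", (9.0, 10.5), 10.0)
        result, _ = sw.run_attempt(faulty, spec, template, config)
        balance_runs = [e for e in result.error_events if e.fault_id == FAULT_BALANCE]
        assert len(balance_runs) == 2

    def test_conclusions_one_message_per_fault_ordered(self, clean_stream, spec,
                                                       template, config):
        faulty, _ = sw.inject_fault(clean_stream, "lean", (6.0, 9.0), 10.0)
        result, _ = sw.run_attempt(faulty, spec, template, config)
        fault_ids = {e.fault_id for e in result.error_events}
        assert len(result.conclusions) == len(fault_ids)


class TestSharpThreshold:
    """The detector and generator agree analytically: the alert fires iff
    sin(lean) exceeds the balance threshold."""

    @pytest.mark.parametrize("lean_deg", [3.0, 4.0, 5.0, 5.5, 6.0, 7.0, 9.0])
    def test_alert_iff_sin_lean_exceeds_epsilon(self, lean_deg, config):
        frames = sw.standing_frames(
            sw.WalkerParams(noise_sd=0.0, lean_deg=lean_deg, seed=0), 0.5
        )
        expected = math.sin(math.radians(lean_deg)) > config.balance_epsilon
        for frame in frames:
            assert sw.balance_level(frame, config).alert == expected


class TestDebouncer:
    @staticmethod
    def _oracle(mask, ts, min_frames):
        """Independent run-length encoding of the violation mask."""
        runs, count, start, last = [], 0, None, None
        for t, v in zip(ts, mask):
            if v:
                if count == 0:
                    start = t
                count += 1
                last = t
            else:
                if count >= min_frames:
                    runs.append((start, last))
                count = 0
        if count >= min_frames:
            runs.append((start, last))
        return runs

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        mask=st.lists(st.booleans(), min_size=1, max_size=80),
        min_frames=st.integers(1, 6),
    )
    def test_runs_match_rle_oracle(self, mask, min_frames):
        ts = [i / 30.0 for i in range(len(mask))]
        deb = sw.RunDebouncer(min_frames)
        confirmations = [t for t, v in zip(ts, mask) if deb.feed(t, v)]
        deb.finish()
        assert deb.runs == self._oracle(mask, ts, min_frames)
        assert len(confirmations) == len(deb.runs)

    def test_short_flicker_never_fires(self):
        deb = sw.RunDebouncer(5)
        for i, v in enumerate([True] * 4 + [False] + [True] * 4 + [False]):
            assert not deb.feed(i / 30.0, v)
        deb.finish()
        assert deb.runs == []


class TestEventHygiene:
    def test_duration_never_appears_in_event_payloads(self, clean_stream, spec,
                                                      template, config):
        faulty, _ = sw.inject_fault(clean_stream, "lean", (6.0, 9.0), 10.0)
        for stream in (clean_stream, faulty):
            result, events = sw.run_attempt(stream, spec, template, config)
            for event in events:
                for key in event.payload:
                    assert key not in ("duration", "time", "elapsed")
            assert result.duration > 0  # but it is in the therapist-side result

    def test_success_iff_zero_error_events(self, clean_stream, spec, template,
                                           config):
        for fault_args in (None, ("lean", (6.0, 9.0), 10.0),
                           ("drift", (6.0, 9.0), 0.4)):
            stream = clean_stream
            if fault_args:
                stream, _ = sw.inject_fault(clean_stream, *fault_args)
            result, _ = sw.run_attempt(stream, spec, template, config)
            assert result.success == (result.complete and not result.error_events)

    def test_invalid_frame_is_a_monitor_error(self, spec, template, config,
                                              upright_frame):
        state = sw.new_session(spec, template, config)
        del upright_frame.joints[J.FootLeft]
        with pytest.raises(sw.MonitorError, match="FootLeft"):
            sw.update(state, upright_frame)
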