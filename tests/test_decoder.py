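"""Decoder: cursor mapping, angle classification, dwell selection, grasp gating."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abstractmyo import (
    AbstractDecoder,
    DecisionBoundaries,
    DwellSelector,
    GraspMap,
    GraspStateMachine,
    MAVSample,
    MAVStream,
    TaskSpaceConfig,
    classify_target,
    evaluate_familiarization_stage,
    mav_to_cursor,
    run_familiarization_trial,
)
from abstractmyo.errors import ConfigurationError, ProtocolError

T0 = np.datetime64("2022-01-01T09:00:00.000", "ms")


def _sample(offset_ms, x, y):
    return MAVSample(T0 + np.timedelta64(int(offset_ms), "ms"), x, y)


def _stream(points, step_ms=50):
    t = T0 + (step_ms * np.arange(len(points))).astype("timedelta64[ms]")
    return MAVStream(t, np.asarray(points, dtype=float))


class TestCursor:
    def test_on_axis(self):
        c = mav_to_cursor(_sample(0, 0.5, 0.0))
        assert c.v == 0.0 and c.r == 0.5

    def test_diagonal_symmetry(self):
        c = mav_to_cursor(_sample(0, 0.3, 0.3))
        assert c.v == pytest.approx(45.0)

    def test_origin_angle_undefined(self):
        c = mav_to_cursor(_sample(0, 0.0, 0.0))
        assert c.r == 0.0 and c.v is None


class TestClassifyTarget:
    def test_low_angle_is_target_one(self):
        assert classify_target(10.0) == 1

    def test_boundary_belongs_to_upper_region(self):
        assert classify_target(22.5) == 2
        assert classify_target(45.0) == 3
        assert classify_target(67.5) == 4

    def test_matches_exhaustive_interval_search_on_grid(self):
        b = DecisionBoundaries(19.1, 43.2, 64.9)  # a customized-style set
        grid = np.round(np.arange(0.0, 90.0 + 1e-9, 0.1), 10)

        def oracle(v):
            for target, (lo, hi) in enumerate(
                [(0.0, b.b12), (b.b12, b.b23), (b.b23, b.b34), (b.b34, 90.0 + 1e-12)],
                start=1,
            ):
                if lo <= v < hi or (target == 4 and v == 90.0):
                    return target
            raise AssertionError

        got = classify_target(grid, b)
        expected = np.array([oracle(v) for v in grid])
        np.testing.assert_array_equal(got, expected)

    def test_partition_covers_every_angle_once_and_is_monotone(self):
        grid = np.linspace(0.0, 90.0, 901)
        targets = classify_target(grid)
        assert set(np.unique(targets)) == {1, 2, 3, 4}
        assert np.all(np.diff(targets) >= 0)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            classify_target(-1.0)
        with pytest.raises(ValueError):
            classify_target(90.5)

    def test_unordered_boundaries_rejected(self):
        with pytest.raises(ConfigurationError):
            DecisionBoundaries(45.0, 22.5, 67.5)


def _disc_path(cfg, target, n_steps, step_ms=50):
    """Samples sitting at a target's disc center."""
    c = cfg.target_centers()[target - 1]
    return [(c[0], c[1])] * n_steps


class TestDwellSelector:
    def test_fires_once_after_dwell(self, cfg):
        sel = DwellSelector(cfg)
        fired = [sel.update(mav_to_cursor(s)) for s in _stream(_disc_path(cfg, 3, 14))]
        fired = [f for f in fired if f]
        assert fired == [3]  # 1.2x dwell, single fire

    def test_oscillation_below_dwell_never_fires(self, cfg):
        sel = DwellSelector(cfg)
        inside = _disc_path(cfg, 2, 8)  # 0.35 s < 0.5 s dwell
        out = [(0.01, 0.01)] * 2
        fired = [
            sel.update(mav_to_cursor(s))
            for s in _stream((inside + out) * 5)
        ]
        assert not any(fired)

    def test_grazing_two_targets_matches_sliding_window_oracle(self, cfg, rng):
        # random walk bouncing between discs 2 and 3 and the space between
        centers = cfg.target_centers()
        pts = []
        for _ in range(400):
            which = rng.choice([1, 2, None], p=[0.4, 0.4, 0.2])
            if which is None:
                pts.append((0.4, 0.4))
            else:
                jitter = rng.uniform(-cfg.target_radius, cfg.target_radius, 2) * 0.9
                pts.append(tuple(centers[which] + jitter * 0.7))
        stream = _stream(pts)
        sel = DwellSelector(cfg)
        fired = [(i, sel.update(mav_to_cursor(s))) for i, s in enumerate(stream)]
        fired = [(i, f) for i, f in fired if f]

        # oracle: replay sample-by-sample, tracking continuous in-disc runs
        def disc_of(p):
            d = np.hypot(centers[:, 0] - p[0], centers[:, 1] - p[1])
            k = int(np.argmin(d))
            return k + 1 if d[k] <= cfg.target_radius else None

        expected = []
        run_disc, run_start, run_fired = None, None, False
        for i, p in enumerate(pts):
            d = disc_of(p)
            if d != run_disc:
                run_disc, run_start, run_fired = d, i, False
            elif d is not None and not run_fired and (i - run_start) * 50 >= cfg.dwell_ms:
                run_fired = True
                expected.append((i, d))
        assert fired == expected


class TestGraspStateMachine:
    def _fire(self, machine, target, t_ms, cfg):
        """Put the cursor at the target's center and report a dwell fire."""
        center = cfg.target_centers()[target - 1]
        c = mav_to_cursor(_sample(t_ms, center[0], center[1]))
        return machine.step(c, target)

    def _rest(self, machine, t_ms):
        return machine.step(mav_to_cursor(_sample(t_ms, 0.01, 0.01)), None)

    def test_armed_close_then_gated_reclose(self, cfg):
        m = GraspStateMachine(cfg=cfg)
        self._rest(m, 0)
        cmd = self._fire(m, 1, 100, cfg)
        assert cmd is not None and cmd.grasp == "power" and m.hand.state == "power"
        # second closing fire without an intervening open: discarded
        assert self._fire(m, 2, 200, cfg) is None
        assert m.n_discarded == 1

    def test_open_requires_closed_hand(self, cfg):
        m = GraspStateMachine(cfg=cfg)
        self._rest(m, 0)
        assert self._fire(m, 4, 100, cfg) is None  # already open
        self._fire(m, 1, 200, cfg)
        cmd = self._fire(m, 4, 300, cfg)
        assert cmd is not None and cmd.grasp == "open" and m.hand.is_open

    def test_close_requires_basket_rearm(self, cfg):
        m = GraspStateMachine(cfg=cfg)
        self._rest(m, 0)
        self._fire(m, 1, 100, cfg)
        self._fire(m, 4, 200, cfg)  # open again, but no basket visit yet
        assert self._fire(m, 2, 300, cfg) is None
        self._rest(m, 400)
        assert self._fire(m, 2, 500, cfg) is not None

    def test_random_fire_sequences_match_oracle_automaton(self, cfg, rng):
        """50-step random fire/rest sequences against a brute-force
        simulation of the two-state automaton."""
        for trial in range(20):
            m = GraspStateMachine(cfg=cfg)
            state, armed = "OPEN", False
            expected, got = [], []
            for step in range(50):
                action = rng.choice(["rest", 1, 2, 3, 4])
                t_ms = step * 100
                if action == "rest":
                    self._rest(m, t_ms)
                    if state == "OPEN":
                        armed = True
                    continue
                cmd = self._fire(m, int(action), t_ms, cfg)
                got.append(cmd.target if cmd else None)
                # oracle
                tgt = int(action)
                if tgt in (1, 2, 3):
                    if state == "OPEN" and armed:
                        state, armed = "CLOSED", False
                        expected.append(tgt)
                    else:
                        expected.append(None)
                else:
                    if state == "CLOSED":
                        state = "OPEN"
                        expected.append(4)
                    else:
                        expected.append(None)
            assert got == expected

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.lists(st.sampled_from(["rest", 1, 2, 3, 4]), max_size=60))
    def test_never_two_closing_commands_without_open_between(self, actions):
        cfg = TaskSpaceConfig()
        m = GraspStateMachine(cfg=cfg)
        emitted = []
        for step, action in enumerate(actions):
            t_ms = step * 100
            if action == "rest":
                self._rest(m, t_ms)
            else:
                cmd = self._fire(m, action, t_ms, cfg)
                if cmd:
                    emitted.append(cmd.target)
        for a, b in zip(emitted, emitted[1:]):
            if a in (1, 2, 3):
                assert b == 4  # a closing command is always followed by open


class TestAbstractDecoder:
    def test_stream_never_leaving_basket_emits_nothing(self, cfg, rng):
        pts = rng.uniform(0.0, cfg.basket_radius * 0.6, size=(200, 2))
        decoder = AbstractDecoder(cfg)
        assert decoder.decode(_stream(pts)) == []

    def test_boundary_update_applies_only_after_timestamp(self, cfg):
        """Reconfiguring boundaries mid-session affects only later commands."""
        center = cfg.target_centers()[0]  # v = 11.25 deg
        pts = (
            [(0.01, 0.01)] * 3 + [tuple(center)] * 14
            + [(0.01, 0.01)] * 3
            + [tuple(cfg.target_centers()[3])] * 14  # open
            + [(0.01, 0.01)] * 3 + [tuple(center)] * 14
        )
        stream = _stream(pts)
        decoder = AbstractDecoder(cfg)
        # after the first close+open, route 11.25 deg into target 2
        t_update = stream.t[0] + np.timedelta64(40 * 50, "ms")
        decoder.schedule_update(t_update, boundaries=DecisionBoundaries(5.0, 45.0, 67.5))
        cmds = decoder.decode(stream)
        assert [c.target for c in cmds] == [1, 4, 2]
        assert all(
            c.target == 2 for c in cmds if np.datetime64(c.t, "ms") > t_update
        )


class TestFamiliarization:
    def _reach(self, cfg, target, n_pre=2, n_travel=10, step_ms=50):
        end = cfg.target_centers()[target - 1]
        pts = [(0.01, 0.01)] * n_pre
        pts += [tuple(end * k / n_travel) for k in range(1, n_travel + 1)]
        return _stream(pts, step_ms)

    def test_hit_within_timeout(self, cfg):
        res = run_familiarization_trial(self._reach(cfg, 2), 2, cfg)
        assert res.success and res.time_to_hit_s < 1.5

    def test_never_leaving_basket_fails_at_timeout(self, cfg):
        stream = _stream([(0.01, 0.02)] * 40)
        res = run_familiarization_trial(stream, 1, cfg)
        assert not res.success and res.time_to_hit_s is None

    def test_slow_reach_fails(self, cfg):
        res = run_familiarization_trial(self._reach(cfg, 2, n_travel=40), 2, cfg)
        assert not res.success

    def test_stream_not_starting_in_basket_rejected(self, cfg):
        stream = _stream([(0.5, 0.5)] * 5)
        with pytest.raises(ProtocolError):
            run_familiarization_trial(stream, 1, cfg)

    def test_stage_success_rates_match_per_trial_recount(self, cfg, rng):
        """40 noisy trials; stage cleared iff every target exceeds 70%."""
        results = []
        for trial in range(40):
            target = trial % 4 + 1
            # mis-aim some trials toward a wrong target
            aimed = target if rng.random() > 0.2 else (target % 4) + 1
            results.append((target, run_familiarization_trial(self._reach(cfg, aimed), target, cfg)))
        stage = evaluate_familiarization_stage(results)
        for target in (1, 2, 3, 4):
            hits = [r.success for tgt, r in results if tgt == target]
            assert stage["per_target_rate"][target] == pytest.approx(
                sum(hits) / len(hits)
            )
        assert stage["cleared"] == all(
            stage["per_target_rate"][t] > 0.7 for t in (1, 2, 3, 4)
        )
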