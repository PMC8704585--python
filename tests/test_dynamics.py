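"""Integrator dynamics: closed form vs numerical oracle, gating, smear."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import rk4_cascade, segments_from_train
from vismem import (
    DecayRate,
    FeatureEvent,
    FeaturePolarity,
    GatingSignal,
    ModelParams,
    PiecewiseDrive,
    drive_from_events,
    integrate_first_order,
    motion_smear_extent,
    pool,
    simulate_condition,
)
from vismem.dynamics import CompiledCondition

V, AV, S = FeaturePolarity.V, FeaturePolarity.AV, FeaturePolarity.S
TAU = 0.0291


def random_train(rng, n_events=4, t_max=120.0):
    """Contiguous random V/AV/S train inside [0, t_max] (single frame)."""
    events = []
    t = 0.0
    for i in range(n_events):
        dur = float(rng.uniform(5.0, (t_max / n_events) - 1.0))
        pol = [V, AV, S][int(rng.integers(3))]
        events.append(FeatureEvent(pol, t, dur, 0, 0))
        t += dur + float(rng.uniform(0.0, 1.0))
    return tuple(events)


def closed_form_y(events, gating, tau, eval_times):
    dV = drive_from_events(events, V)
    dAV = drive_from_events(events, AV)
    extra = tuple(gating.switch_times) + tuple(eval_times)
    xV = integrate_first_order(dV, tau, gating, extra_breakpoints=dAV.breakpoints + extra)
    xAV = integrate_first_order(dAV, tau, gating, extra_breakpoints=dV.breakpoints + extra)
    y = pool(xV, xAV, tau=tau, gating=gating)
    return xV, xAV, y


class TestDecayRate:
    def test_time_constant_is_reciprocal_rate(self):
        assert DecayRate(0.02).time_constant == pytest.approx(50.0)

    @pytest.mark.parametrize("bad", [0.0, -0.1])
    def test_rejects_non_positive_rate(self, bad):
        with pytest.raises(ValueError):
            DecayRate(bad)


class TestDriveFromEvents:
    def test_single_event_box(self):
        ev = (FeatureEvent(V, 0.0, 30.0, 0, 0),)
        d = drive_from_events(ev, V)
        assert d.level(10.0) == 1.0
        assert d.level(35.0) == 0.0

    def test_straight_events_drive_nothing(self):
        ev = (FeatureEvent(S, 0.0, 30.0, 0, 0), FeatureEvent(S, 30.0, 30.0, 0, 0))
        for pol in (V, AV, S):
            d = drive_from_events(ev, pol)
            assert all(d.level(t) == 0.0 for t in (0.0, 15.0, 45.0))

    def test_polarity_selects_matching_events(self):
        ev = (FeatureEvent(V, 0.0, 30.0, 0, 0), FeatureEvent(AV, 30.0, 30.0, 0, 0))
        d = drive_from_events(ev, AV)
        assert d.level(15.0) == 0.0
        assert d.level(45.0) == 1.0

    def test_overlapping_events_sum(self):
        ev = (FeatureEvent(V, 0.0, 30.0, 0, 0), FeatureEvent(V, 10.0, 30.0, 0, 0))
        d = drive_from_events(ev, V)
        assert d.level(20.0) == 2.0

    def test_excluded_and_occluded_are_silent(self):
        ev = (
            FeatureEvent(V, 0.0, 30.0, 0, 0, excluded=True),
            FeatureEvent(V, 30.0, 30.0, 0, 0, occluded=True),
        )
        d = drive_from_events(ev, V)
        assert d.level(10.0) == 0.0 and d.level(40.0) == 0.0


class TestFirstOrder:
    def test_zero_drive_stays_at_rest(self):
        sol = integrate_first_order(PiecewiseDrive.zero(), TAU)
        assert sol.at(0.0) == 0.0 and sol.at(500.0) == 0.0

    def test_step_response_matches_oracle(self):
        # unit drive for 30 ms, then free decay for 160 ms
        d = PiecewiseDrive((0.0, 30.0), (1.0,))
        sol = integrate_first_order(d, TAU)
        oracle = rk4_cascade([(0.0, 30.0, 1, 1.0, 0.0), (30.0, 190.0, 1, 0.0, 0.0)], TAU)
        x30, x190 = oracle[0][1], oracle[1][1]
        assert sol.at(30.0) == pytest.approx(x30, rel=1e-9)
        assert sol.at(190.0) == pytest.approx(x190, rel=1e-9)
        # charge reaches ~20 units; 160 ms of decay leaves under 1%
        assert x30 == pytest.approx(20.0, abs=0.05)
        assert x190 / x30 < 0.01

    def test_frozen_gate_holds_state(self):
        d = PiecewiseDrive((0.0, 30.0), (1.0,))
        gate = GatingSignal.from_off_intervals([(30.0, 190.0)])
        sol = integrate_first_order(d, TAU, gate)
        x30 = sol.at(30.0)
        assert sol.at(100.0) == x30
        assert sol.at(189.9) == x30

    def test_rejects_non_positive_tau(self):
        with pytest.raises(ValueError):
            integrate_first_order(PiecewiseDrive.zero(), -0.1)


class TestPool:
    def test_balanced_drives_give_pure_decay(self):
        ev = (FeatureEvent(V, 0.0, 30.0, 0, 0), FeatureEvent(AV, 0.0, 30.0, 0, 0))
        gating = GatingSignal.always_on()
        _, _, y = closed_form_y(ev, gating, TAU, (50.0,))
        assert y.at(25.0) == pytest.approx(0.0, abs=1e-12)
        assert y.at(50.0) == pytest.approx(0.0, abs=1e-12)

    def test_swapping_polarities_flips_sign(self):
        ev1 = (FeatureEvent(V, 0.0, 30.0, 0, 0), FeatureEvent(AV, 30.0, 30.0, 0, 0))
        ev2 = (FeatureEvent(AV, 0.0, 30.0, 0, 0), FeatureEvent(V, 30.0, 30.0, 0, 0))
        g = GatingSignal.always_on()
        ts = np.array([15.0, 45.0, 90.0])
        _, _, y1 = closed_form_y(ev1, g, TAU, ts)
        _, _, y2 = closed_form_y(ev2, g, TAU, ts)
        assert np.allclose(y1.at(ts), -np.asarray(y2.at(ts)), rtol=0, atol=1e-12)

    def test_two_frame_train_matches_oracle(self):
        # V 30 ms, AV 30 ms, gated 160 ms blank, V 30 ms
        ev = (
            FeatureEvent(V, 0.0, 30.0, 0, 0),
            FeatureEvent(AV, 30.0, 30.0, 0, 0),
            FeatureEvent(V, 220.0, 30.0, 0, 1),
        )
        gating = GatingSignal.from_off_intervals([(60.0, 220.0)])
        _, _, y = closed_form_y(ev, gating, TAU, (250.0, 300.0))
        cuts = [0.0, 30.0, 60.0, 220.0, 250.0, 300.0]
        segs = segments_from_train(ev, gating.value, cuts)
        oracle = {t: yv for (t, _, _, yv) in rk4_cascade(segs, TAU)}
        for t in (250.0, 300.0):
            assert y.at(t) == pytest.approx(oracle[t], rel=1e-6)

    def test_distinct_pool_rate_matches_oracle(self):
        ev = (FeatureEvent(V, 0.0, 40.0, 0, 0), FeatureEvent(AV, 40.0, 20.0, 0, 0))
        g = GatingSignal.always_on()
        dV, dAV = drive_from_events(ev, V), drive_from_events(ev, AV)
        xV = integrate_first_order(dV, TAU, g, extra_breakpoints=dAV.breakpoints)
        xAV = integrate_first_order(dAV, TAU, g, extra_breakpoints=dV.breakpoints)
        y = pool(xV, xAV, tau=0.01, gating=g)
        segs = segments_from_train(ev, g.value, [0.0, 40.0, 60.0, 120.0])
        oracle = rk4_cascade(segs, TAU, tau_y=0.01)
        assert y.at(120.0) == pytest.approx(oracle[-1][3], rel=1e-6)

    def test_mismatched_feature_rates_rejected(self):
        d = PiecewiseDrive((0.0, 30.0), (1.0,))
        a = integrate_first_order(d, 0.02)
        b = integrate_first_order(d, 0.03)
        with pytest.raises(ValueError):
            pool(a, b)


class TestSimulateCondition:
    def test_empty_train_reads_zero(self):
        p = ModelParams(tau=TAU, sigma=1.0, readout=100.0)
        y_r, trace = simulate_condition((), p)
        assert y_r == 0.0
        assert np.all(trace.y == 0.0)

    def test_gated_memory_is_constant_through_the_blank(self, make_train):
        train = make_train("V-AV-V")
        ys = []
        for r in (80.0, 130.0, 219.0):  # all inside the 60-220 ms blank
            p = ModelParams(tau=TAU, sigma=1.0, readout=r, variant="gated")
            ys.append(simulate_condition(train, p, with_trace=False)[0])
        assert ys[0] == ys[1] == ys[2]

    def test_leaky_later_av_dominates_after_offset(self):
        # V 30 ms then AV 30 ms: at stimulus offset the slow pooled stage
        # still reflects the earlier V, but as it keeps integrating the
        # negative xV - xAV tail the later AV takes over
        ev = (FeatureEvent(V, 0.0, 30.0, 0, 0), FeatureEvent(AV, 30.0, 30.0, 0, 0))
        p = ModelParams(tau=TAU, sigma=1.0, readout=150.0, variant="leaky")
        y_r, _ = simulate_condition(ev, p)
        segs = segments_from_train(ev, lambda t: 1, [0.0, 30.0, 60.0, 150.0])
        assert y_r == pytest.approx(rk4_cascade(segs, TAU)[-1][3], rel=1e-6)
        assert y_r < 0

    def test_readout_may_precede_late_events(self, make_train):
        train = make_train("V-AV-V")
        p_early = ModelParams(tau=TAU, sigma=1.0, readout=50.0, variant="leaky")
        ev_frame1 = tuple(e for e in train if e.frame_index == 0)
        y_full, _ = simulate_condition(train, p_early)
        y_f1, _ = simulate_condition(ev_frame1, p_early)
        assert y_full == pytest.approx(y_f1, rel=1e-12)

    def test_readout_origin_last_offset(self):
        ev = (FeatureEvent(V, 0.0, 30.0, 0, 0),)
        p_abs = ModelParams(tau=TAU, sigma=1.0, readout=80.0, variant="leaky")
        p_rel = ModelParams(tau=TAU, sigma=1.0, readout=50.0, variant="leaky",
                            readout_origin="last_offset")
        assert simulate_condition(ev, p_abs, with_trace=False)[0] == pytest.approx(
            simulate_condition(ev, p_rel, with_trace=False)[0], rel=1e-12)

    def test_predictions_blind_to_position_and_labels(self, make_train):
        """Only polarity and timing matter: retinotopic position, stream
        labels and eccentricity metadata (e.g. a cue) never reach the
        integrators — integration is mandatory."""
        from dataclasses import replace
        train = make_train("V-AV-S")
        relabeled = tuple(
            replace(e, position=e.position + 9, stream_id="other", eccentricity=16.5)
            for e in train
        )
        p = ModelParams(tau=TAU, sigma=1.0, readout=300.0)
        assert (simulate_condition(train, p, with_trace=False)[0]
                == simulate_condition(relabeled, p, with_trace=False)[0])

    def test_trace_csv_schema(self, make_train, tmp_path):
        p = ModelParams(tau=TAU, sigma=1.0, readout=300.0)
        _, trace = simulate_condition(make_train("V-AV-S"), p)
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        header = path.read_text().splitlines()[0]
        assert header == "t_ms,xV,xAV,y,m"

    def test_every_offset_policy_freezes_after_last_element(self):
        ev = (FeatureEvent(V, 0.0, 30.0, 0, 0),)
        p = ModelParams(tau=TAU, sigma=1.0, readout=500.0, variant="gated",
                        gating_policy="every_offset")
        y_r, _ = simulate_condition(ev, p)
        y30, _ = simulate_condition(ev, ModelParams(tau=TAU, sigma=1.0, readout=30.0,
                                                    variant="gated",
                                                    gating_policy="every_offset"))
        assert y_r == y30  # frozen at the offset transient


class TestCompiledCondition:
    def test_matches_reference_path_on_random_trains(self, make_train):
        rng = np.random.default_rng(42)
        trains = [random_train(rng) for _ in range(10)]
        trains += [make_train(s) for s in ("V-AV-S", "S-S-V", "V-AV-V-AV")]
        for variant in ("leaky", "gated"):
            comps = [CompiledCondition(t, variant=variant) for t in trains]
            for _ in range(5):
                p = ModelParams(
                    tau=float(10 ** rng.uniform(-3, -0.5)),
                    sigma=1.0,
                    readout=float(rng.uniform(0.0, 600.0)),
                    variant=variant,
                )
                for t, c in zip(trains, comps):
                    ref = simulate_condition(t, p, with_trace=False)[0]
                    assert c.y_at(p) == pytest.approx(ref, rel=1e-12, abs=1e-12)


class TestSuperposition:
    """The cascade is linear: responses to drive sets add exactly."""

    def test_superposition_on_random_fixtures(self):
        rng = np.random.default_rng(7)
        p = ModelParams(tau=TAU, sigma=1.0, readout=150.0, variant="leaky")
        for _ in range(20):
            a = random_train(rng, n_events=3)
            b = tuple(
                FeatureEvent(e.polarity, e.onset, e.duration, 1, e.frame_index)
                for e in random_train(rng, n_events=3)
            )
            y_a = simulate_condition(a, p, with_trace=False)[0]
            y_b = simulate_condition(b, p, with_trace=False)[0]
            y_ab = simulate_condition(tuple(sorted(a + b, key=lambda e: e.onset)),
                                      p, with_trace=False)[0]
            scale = max(1.0, abs(y_ab))
            assert abs(y_ab - (y_a + y_b)) / scale < 1e-9


@settings(max_examples=25, derandomize=True, deadline=None)
@given(
    dur1=st.floats(5.0, 40.0),
    dur2=st.floats(5.0, 40.0),
    gap=st.floats(0.0, 100.0),
    tau=st.floats(0.005, 0.1),
)
def test_closed_form_matches_oracle_property(dur1, dur2, gap, tau):
    """Closed-form cascade equals RK4 on a V..AV train with a gated gap."""
    ev = (
        FeatureEvent(V, 0.0, dur1, 0, 0),
        FeatureEvent(AV, dur1 + gap, dur2, 0, 1 if gap > 0 else 0),
    )
    end = dur1 + gap + dur2
    gating = (GatingSignal.from_off_intervals([(dur1, dur1 + gap)])
              if gap > 0 else GatingSignal.always_on())
    _, _, y = closed_form_y(ev, gating, tau, (end,))
    cuts = sorted({0.0, dur1, dur1 + gap, end})
    segs = segments_from_train(ev, gating.value, cuts)
    oracle = rk4_cascade(segs, tau)
    scale = max(1.0, abs(oracle[-1][3]))
    assert abs(y.at(end) - oracle[-1][3]) / scale < 1e-6


class TestMotionSmear:
    def test_extent_vanishes_as_threshold_approaches_one(self):
        assert motion_smear_extent(0.01, 0.01, 0.999999) == pytest.approx(0.0, abs=1e-4)

    def test_extent_matches_brute_force_thresholding(self):
        # comet-tail profile: activity a distance d behind the dot was
        # deposited d/speed ms ago and has decayed by exp(-tau d/speed)
        speed, tau, thr = 0.01, 0.01, 0.05
        d_grid = np.linspace(0.0, 10.0, 2_000_001)
        residual = np.exp(-tau * d_grid / speed)
        brute = d_grid[residual >= thr].max()
        assert motion_smear_extent(speed, tau, thr) == pytest.approx(brute, abs=1e-4)
        assert motion_smear_extent(speed, tau, thr) == pytest.approx(3.0, abs=0.005)

    def test_extent_scales_linearly_with_speed(self):
        e1 = motion_smear_extent(0.01, 0.02, 0.1)
        e2 = motion_smear_extent(0.02, 0.02, 0.1)
        assert e2 == pytest.approx(2 * e1, rel=1e-12)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.5, 1.5])
    def test_threshold_domain(self, bad):
        with pytest.raises(ValueError):
            motion_smear_extent(0.01, 0.01, bad)
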