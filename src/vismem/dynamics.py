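"""Leaky-integrator dynamics of visual sensory memory.

Feature detectors tuned to opposite vernier polarities act as leaky
integrators of their stimulus drive,

    dxV/dt  = -tau * xV  + IV(t)
    dxAV/dt = -tau * xAV + IAV(t),

and their outputs are pooled by a second leaky stage,

    dy/dt = -tau * y + xV(t) - xAV(t),

whose value at the readout time is converted to a percept by the sigmoid
in :mod:`vismem.readout`.  The *gated* variant multiplies every
right-hand side by a transient-driven signal m(t) in {0, 1}: when m = 0
(during inter-frame intervals) both integration and decay stop, so the
memory contents are frozen rather than leaking away.  This is the
mechanism distinguishing non-retinotopic sensory memory (contents survive
a 100-220 ms blank) from the classic retinotopic store (contents decay
with time constant 1/tau, fitted at ~34 ms).

Because stimulus drives are piecewise constant, both stages admit exact
closed-form solutions segment by segment; that closed form is the primary
solver throughout the package.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .stimuli import FeatureEvent, FeaturePolarity, StimulusSequence

__all__ = [
    "DecayRate",
    "GatingSignal",
    "PiecewiseDrive",
    "ActivityTrace",
    "ModelParams",
    "drive_from_events",
    "integrate_first_order",
    "pool",
    "simulate_condition",
    "CompiledCondition",
    "motion_smear_extent",
    "FirstOrderSolution",
    "CascadeSolution",
]

# Two first-order stages sharing a rate give a repeated eigenvalue; below
# this relative rate difference the (t * exp) branch is used.
_REPEATED_EIG_RTOL = 1e-10


@dataclass(frozen=True)
class DecayRate:
    """Passive decay rate of a leaky integrator, in ms^-1.

    ``time_constant`` (1/tau, ms) is the time for activity to fall to
    1/e of its value once the drive is switched off.
    """

    tau: float

    def __post_init__(self) -> None:
        if not (self.tau > 0):
            raise ValueError(f"decay rate tau must be positive, got {self.tau}")

    @property
    def time_constant(self) -> float:
        return 1.0 / self.tau


def _as_rate(tau: "DecayRate | float") -> DecayRate:
    return tau if isinstance(tau, DecayRate) else DecayRate(float(tau))


@dataclass(frozen=True)
class GatingSignal:
    """Binary modulatory signal m(t), right-continuous, finitely switching.

    The signal starts at ``start_value`` and flips at each time in
    ``switch_times``.  m = 1 lets the integrators evolve; m = 0 freezes
    them (both leak and input are gated off).
    """

    switch_times: tuple[float, ...] = ()
    start_value: int = 1

    def __post_init__(self) -> None:
        if list(self.switch_times) != sorted(self.switch_times):
            raise ValueError("switch_times must be sorted")
        if self.start_value not in (0, 1):
            raise ValueError("start_value must be 0 or 1")

    def value(self, t: float) -> int:
        flips = bisect.bisect_right(self.switch_times, t)
        return self.start_value ^ (flips % 2)

    @classmethod
    def always_on(cls) -> "GatingSignal":
        return cls()

    @classmethod
    def from_off_intervals(cls, intervals: Iterable[tuple[float, float]]) -> "GatingSignal":
        """Gating that is 0 exactly on the given disjoint intervals [a, b)."""
        times: list[float] = []
        for a, b in sorted(intervals):
            if b <= a:
                continue
            if times and a < times[-1]:
                raise ValueError("off intervals must be disjoint")
            if math.isinf(b):
                times.append(a)
                break
            times.extend((a, b))
        return cls(switch_times=tuple(times), start_value=1)


@dataclass(frozen=True)
class PiecewiseDrive:
    """Piecewise-constant stimulus drive.

    ``levels[i]`` holds on ``[breakpoints[i], breakpoints[i+1])``; the
    drive is zero outside the breakpoint span.
    """

    breakpoints: tuple[float, ...]
    levels: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.breakpoints) != len(self.levels) + 1:
            raise ValueError("need exactly one more breakpoint than levels")
        if any(b >= a for a, b in zip(self.breakpoints[1:], self.breakpoints)):
            raise ValueError("breakpoints must be strictly increasing")
        if not all(math.isfinite(v) for v in self.levels):
            raise ValueError("drive levels must be finite")

    def level(self, t: float) -> float:
        i = bisect.bisect_right(self.breakpoints, t) - 1
        if i < 0 or i >= len(self.levels):
            return 0.0
        return self.levels[i]

    @classmethod
    def zero(cls) -> "PiecewiseDrive":
        return cls(breakpoints=(0.0, 1.0), levels=(0.0,))


def drive_from_events(
    events: Sequence[FeatureEvent],
    polarity: FeaturePolarity,
    amplitude: float = 1.0,
) -> PiecewiseDrive:
    """Stimulus drive for one polarity channel from an event train.

    The drive equals ``amplitude`` while a matching event is on screen
    (overlapping events sum) and zero elsewhere.  Straight (S) elements
    and events flagged excluded or occluded contribute nothing.
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    polarity = FeaturePolarity.parse(polarity)
    deltas: dict[float, float] = {}
    if polarity is not FeaturePolarity.S:
        for e in events:
            if e.polarity is polarity and e.drives:
                deltas[e.onset] = deltas.get(e.onset, 0.0) + amplitude
                deltas[e.offset] = deltas.get(e.offset, 0.0) - amplitude
    if not deltas:
        return PiecewiseDrive.zero()
    times = sorted(deltas)
    levels: list[float] = []
    acc = 0.0
    for t in times[:-1]:
        acc += deltas[t]
        levels.append(acc)
    return PiecewiseDrive(breakpoints=tuple(times), levels=tuple(levels))


# ---------------------------------------------------------------------------
# Closed-form solutions
# ---------------------------------------------------------------------------


def _merged_segment_starts(
    drives: Sequence[PiecewiseDrive],
    gating: GatingSignal,
    extra: Iterable[float] = (),
) -> list[float]:
    pts = {0.0}
    for d in drives:
        pts.update(d.breakpoints)
    pts.update(gating.switch_times)
    pts.update(extra)
    return sorted(p for p in pts if p >= 0.0)


@dataclass(frozen=True)
class FirstOrderSolution:
    """Exact segment-wise solution of one gated leaky integrator.

    On a segment starting at ``a`` with gate open and constant drive c:
    ``x(t) = c/tau + (x(a) - c/tau) * exp(-tau (t - a))``; with the gate
    closed the state is frozen at x(a).  The state is continuous across
    segment boundaries; the last segment extends to +infinity with zero
    drive.
    """

    tau: float
    starts: np.ndarray        # segment start times
    gates: np.ndarray         # m in {0, 1} per segment
    drives: np.ndarray        # constant drive per segment
    x_starts: np.ndarray      # state at each segment start

    def _segment_index(self, t: np.ndarray) -> np.ndarray:
        return np.clip(np.searchsorted(self.starts, t, side="right") - 1, 0, None)

    def at(self, t) -> np.ndarray | float:
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        i = self._segment_index(t_arr)
        dt = np.maximum(t_arr - self.starts[i], 0.0)
        eq = self.drives[i] / self.tau
        moving = self.gates[i] == 1
        out = np.where(
            moving,
            eq + (self.x_starts[i] - eq) * np.exp(-self.tau * dt),
            self.x_starts[i],
        )
        return out if np.ndim(t) else float(out[0])

    def segment_params(self, i: int) -> tuple[float, float, float, float]:
        """(start, gate, drive, x_start) of segment i."""
        return (
            float(self.starts[i]),
            float(self.gates[i]),
            float(self.drives[i]),
            float(self.x_starts[i]),
        )


def integrate_first_order(
    drive: PiecewiseDrive,
    tau: DecayRate | float,
    gating: GatingSignal | None = None,
    x0: float = 0.0,
    extra_breakpoints: Iterable[float] = (),
) -> FirstOrderSolution:
    """Solve dx/dt = m(t) [-tau x + I(t)] exactly for a piecewise drive."""
    rate = _as_rate(tau).tau
    gating = gating or GatingSignal.always_on()
    starts = _merged_segment_starts([drive], gating, extra_breakpoints)
    gates = np.array([gating.value(s) for s in starts], dtype=int)
    drives = np.array([drive.level(s) for s in starts], dtype=float)
    x_starts = np.empty(len(starts))
    x = float(x0)
    for i, s in enumerate(starts):
        x_starts[i] = x
        if i + 1 < len(starts):
            dt = starts[i + 1] - s
            if gates[i] == 1:
                eq = drives[i] / rate
                x = eq + (x - eq) * math.exp(-rate * dt)
    return FirstOrderSolution(
        tau=rate,
        starts=np.asarray(starts, dtype=float),
        gates=gates,
        drives=drives,
        x_starts=x_starts,
    )


@dataclass(frozen=True)
class CascadeSolution:
    """Exact solution of the pooled stage driven by two first-order stages.

    Within an open-gate segment the forcing xV - xAV has the form
    ``F0 + F1 * exp(-tau_x (t - a))``.  When the pooled rate equals the
    feature rate the eigenvalue is repeated and the particular solution
    carries a ``(t - a) * exp(-tau (t - a))`` term; otherwise the
    standard two-exponential form applies.  A closed gate freezes y.
    """

    tau_y: float
    tau_x: float
    starts: np.ndarray
    gates: np.ndarray
    f0: np.ndarray            # constant part of forcing per segment
    f1: np.ndarray            # coefficient of exp(-tau_x dt) per segment
    y_starts: np.ndarray

    @property
    def repeated(self) -> bool:
        return abs(self.tau_y - self.tau_x) <= _REPEATED_EIG_RTOL * self.tau_y

    def _eval_segment(self, dt, f0, f1, y0):
        ty, tx = self.tau_y, self.tau_x
        if self.repeated:
            part = f0 / ty
            return part + (f1 * dt) * np.exp(-ty * dt) + (y0 - part) * np.exp(-ty * dt)
        a = f0 / ty
        b = f1 / (ty - tx)
        c = y0 - a - b
        return a + b * np.exp(-tx * dt) + c * np.exp(-ty * dt)

    def at(self, t) -> np.ndarray | float:
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        i = np.clip(np.searchsorted(self.starts, t_arr, side="right") - 1, 0, None)
        dt = np.maximum(t_arr - self.starts[i], 0.0)
        moving = self.gates[i] == 1
        out = np.where(
            moving,
            self._eval_segment(dt, self.f0[i], self.f1[i], self.y_starts[i]),
            self.y_starts[i],
        )
        return out if np.ndim(t) else float(out[0])


def _forcing_coefficients(
    sol: FirstOrderSolution, start: float
) -> tuple[float, float]:
    """(F0, F1) with x(start + dt) = F0 + F1 exp(-tau_x dt) on the segment."""
    i = int(sol._segment_index(np.array([start]))[0])
    s, gate, drive, _ = sol.segment_params(i)
    x_here = float(sol.at(start))
    if gate == 0:
        return x_here, 0.0
    eq = drive / sol.tau
    return eq, x_here - eq


def pool(
    xV: FirstOrderSolution,
    xAV: FirstOrderSolution,
    tau: DecayRate | float | None = None,
    gating: GatingSignal | None = None,
    y0: float = 0.0,
) -> CascadeSolution:
    """Solve dy/dt = m(t) [-tau y + xV(t) - xAV(t)] exactly.

    The two feature stages must share their decay rate (the exponent of
    the forcing); the pooled rate defaults to that same rate, the case
    with a repeated eigenvalue.
    """
    if abs(xV.tau - xAV.tau) > _REPEATED_EIG_RTOL * xV.tau:
        raise ValueError("xV and xAV must share their decay rate")
    tau_x = xV.tau
    tau_y = _as_rate(tau).tau if tau is not None else tau_x
    gating = gating or GatingSignal.always_on()
    starts = sorted(
        set(xV.starts.tolist())
        | set(xAV.starts.tolist())
        | set(gating.switch_times)
        | {0.0}
    )
    gates = np.array([gating.value(s) for s in starts], dtype=int)
    f0 = np.empty(len(starts))
    f1 = np.empty(len(starts))
    y_starts = np.empty(len(starts))
    y = float(y0)
    sol = None
    for i, s in enumerate(starts):
        fv0, fv1 = _forcing_coefficients(xV, s)
        fa0, fa1 = _forcing_coefficients(xAV, s)
        f0[i], f1[i] = fv0 - fa0, fv1 - fa1
        y_starts[i] = y
        if i + 1 < len(starts) and gates[i] == 1:
            dt = starts[i + 1] - s
            tmp = CascadeSolution(
                tau_y=tau_y,
                tau_x=tau_x,
                starts=np.array([s]),
                gates=np.array([1]),
                f0=np.array([f0[i]]),
                f1=np.array([f1[i]]),
                y_starts=np.array([y]),
            )
            y = float(tmp.at(s + dt))
    return CascadeSolution(
        tau_y=tau_y,
        tau_x=tau_x,
        starts=np.asarray(starts, dtype=float),
        gates=gates,
        f0=f0,
        f1=f1,
        y_starts=y_starts,
    )


# ---------------------------------------------------------------------------
# Condition-level simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelParams:
    """Free parameters and variant switches of the sensory-memory model.

    tau : decay rate in ms^-1 (fitted value in the source data: 0.0291,
        i.e. a ~34 ms time constant).
    sigma : slope constant of the sigmoid readout, in activity units.
    readout : readout time r in ms at which y is converted to a percept.
    variant : 'leaky' evolves throughout (retinotopic store); 'gated'
        freezes the state whenever m(t) = 0 (non-retinotopic store).
    gating_policy : 'isi_only' closes the gate exactly during the blank
        intervals between display frames; 'every_offset' closes it
        whenever no element is on screen, including after the last one.
    tau_y : optional distinct decay rate for the pooled stage; defaults
        to ``tau`` (single fitted rate).
    readout_origin : 'onset' measures r from first-frame onset,
        'last_offset' from the disappearance of the last element.
    amplitude : drive level per element; fixed at 1 by convention since
        a joint rescaling of amplitude and sigma leaves all predictions
        unchanged.
    """

    tau: float
    sigma: float
    readout: float
    variant: str = "gated"
    gating_policy: str = "isi_only"
    tau_y: float | None = None
    readout_origin: str = "onset"
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.readout < 0:
            raise ValueError("readout time must be >= 0")
        if self.variant not in ("leaky", "gated"):
            raise ValueError("variant must be 'leaky' or 'gated'")
        if self.gating_policy not in ("isi_only", "every_offset"):
            raise ValueError("gating_policy must be 'isi_only' or 'every_offset'")
        if self.readout_origin not in ("onset", "last_offset"):
            raise ValueError("readout_origin must be 'onset' or 'last_offset'")


@dataclass(frozen=True)
class ActivityTrace:
    """Time-sampled activities of one simulated condition."""

    times: np.ndarray
    xV: np.ndarray
    xAV: np.ndarray
    y: np.ndarray
    m: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_ms": self.times, "xV": self.xV, "xAV": self.xAV, "y": self.y, "m": self.m}
        )

    def to_csv(self, path, **kwargs) -> None:
        self.to_frame().to_csv(path, index=False, **kwargs)


def _events_of(train) -> tuple[FeatureEvent, ...]:
    if isinstance(train, StimulusSequence):
        return train.events
    return tuple(train)


def _frame_windows(events: Sequence[FeatureEvent]) -> list[tuple[float, float]]:
    windows: dict[int, list[float]] = {}
    for e in events:
        w = windows.setdefault(e.frame_index, [e.onset, e.offset])
        w[0] = min(w[0], e.onset)
        w[1] = max(w[1], e.offset)
    return [tuple(windows[k]) for k in sorted(windows)]


def _gating_for(events: Sequence[FeatureEvent], params: ModelParams) -> GatingSignal:
    if params.variant == "leaky" or not events:
        return GatingSignal.always_on()
    if params.gating_policy == "isi_only":
        wins = _frame_windows(events)
        off = [
            (a_end, b_start)
            for (_, a_end), (b_start, _) in zip(wins, wins[1:])
            if b_start > a_end
        ]
        return GatingSignal.from_off_intervals(off)
    # every_offset: gate closed whenever nothing is on screen, for good
    # (the last offset transient freezes the final contents).
    edges = sorted({e.onset for e in events} | {e.offset for e in events})
    def on(t):  # any event covering t
        return any(e.onset <= t < e.offset for e in events)
    off: list[tuple[float, float]] = []
    for a, b in zip(edges, edges[1:]):
        if not on(a):
            off.append((a, b))
    off.append((max(e.offset for e in events), math.inf))
    # merge adjacent
    merged: list[tuple[float, float]] = []
    for a, b in off:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return GatingSignal.from_off_intervals(merged)


def simulate_condition(
    train,
    params: ModelParams,
    trace_step: float = 1.0,
    with_trace: bool = True,
) -> tuple[float, ActivityTrace | None]:
    """Simulate one condition and read out the pooled activity.

    ``train`` is an ordered event train (or :class:`StimulusSequence`)
    restricted to one motion stream.  Returns ``y`` at the readout time
    together with the full activity trace sampled on the merged segment
    boundaries plus a uniform grid (``trace_step`` ms); pass
    ``with_trace=False`` to skip the trace (the fast path used inside
    fitting loops).
    """
    events = _events_of(train)
    r = params.readout
    if events and params.readout_origin == "last_offset":
        r = max(e.offset for e in events) + params.readout

    gating = _gating_for(events, params)
    dV = drive_from_events(events, FeaturePolarity.V, params.amplitude)
    dAV = drive_from_events(events, FeaturePolarity.AV, params.amplitude)
    tau = DecayRate(params.tau)
    extra = tuple(gating.switch_times) + (r,)
    xV = integrate_first_order(dV, tau, gating, 0.0, extra_breakpoints=dAV.breakpoints + extra)
    xAV = integrate_first_order(dAV, tau, gating, 0.0, extra_breakpoints=dV.breakpoints + extra)
    y = pool(xV, xAV, tau=params.tau_y or params.tau, gating=gating, y0=0.0)

    if not with_trace:
        return float(y.at(r)), None

    t_end = max([r] + [e.offset for e in events]) if events else r
    grid = np.arange(0.0, t_end + trace_step, trace_step)
    times = np.unique(np.concatenate([grid, y.starts, [r, t_end]]))
    times = times[(times >= 0) & (times <= t_end)]
    trace = ActivityTrace(
        times=times,
        xV=np.asarray(xV.at(times)),
        xAV=np.asarray(xAV.at(times)),
        y=np.asarray(y.at(times)),
        m=np.array([gating.value(t) for t in times], dtype=int),
    )
    return float(y.at(r)), trace


class CompiledCondition:
    """Precompiled segment program for one event train.

    The segment boundaries, gate values and drive levels of a condition
    do not depend on (tau, sigma, r), so they are computed once and the
    per-parameter-vector work reduces to a scalar recursion over
    segments — the hot path inside fitting loops.  ``y_at`` agrees with
    :func:`simulate_condition` to machine precision.
    """

    def __init__(self, train, variant: str = "gated",
                 gating_policy: str = "isi_only", amplitude: float = 1.0):
        events = _events_of(train)
        self.variant = variant
        self.gating_policy = gating_policy
        probe = ModelParams(tau=1.0, sigma=1.0, readout=0.0, variant=variant,
                            gating_policy=gating_policy, amplitude=amplitude)
        gating = _gating_for(events, probe)
        dV = drive_from_events(events, FeaturePolarity.V, amplitude)
        dAV = drive_from_events(events, FeaturePolarity.AV, amplitude)
        starts = _merged_segment_starts([dV, dAV], gating)
        self.starts = starts
        self.gates = [gating.value(s) for s in starts]
        self.cV = [dV.level(s) for s in starts]
        self.cAV = [dAV.level(s) for s in starts]
        self.last_offset = max((e.offset for e in events), default=0.0)
        self.empty = not any(e.drives for e in events)

    @staticmethod
    def _advance(xV, xAV, y, cV, cAV, dt, tau, tau_y):
        eV, eA = cV / tau, cAV / tau
        decx = math.exp(-tau * dt)
        f0 = eV - eA
        f1 = (xV - eV) - (xAV - eA)
        if abs(tau_y - tau) <= _REPEATED_EIG_RTOL * tau_y:
            dec = math.exp(-tau_y * dt)
            y_new = f0 / tau_y + f1 * dt * dec + (y - f0 / tau_y) * dec
        else:
            a = f0 / tau_y
            b = f1 / (tau_y - tau)
            y_new = a + b * decx + (y - a - b) * math.exp(-tau_y * dt)
        return eV + (xV - eV) * decx, eA + (xAV - eA) * decx, y_new

    def y_at(self, params: ModelParams) -> float:
        """Pooled activity at the readout time for the given parameters."""
        if self.empty:
            return 0.0
        r = params.readout
        if params.readout_origin == "last_offset":
            r += self.last_offset
        tau = params.tau
        tau_y = params.tau_y or params.tau
        xV = xAV = y = 0.0
        starts, gates = self.starts, self.gates
        n = len(starts)
        for i in range(n):
            s = starts[i]
            if r <= s:
                break
            seg_end = starts[i + 1] if i + 1 < n else math.inf
            dt = min(r, seg_end) - s
            if gates[i] == 1:
                xV, xAV, y = self._advance(
                    xV, xAV, y, self.cV[i], self.cAV[i], dt, tau, tau_y
                )
        return y


def motion_smear_extent(
    speed: float,
    tau: DecayRate | float,
    visibility_threshold: float,
) -> float:
    """Length of the motion smear trailing a moving stimulus.

    Persisting retinotopic activity behind a dot moving at ``speed``
    (deg/ms) decays as exp(-tau t); the visible trail ends where the
    residual falls to ``visibility_threshold`` of the activity under the
    dot, at distance ``(speed / tau) * ln(1 / threshold)`` degrees.
    """
    if not (0.0 < visibility_threshold < 1.0):
        raise ValueError("visibility_threshold must lie strictly in (0, 1)")
    if speed < 0:
        raise ValueError("speed must be >= 0")
    rate = _as_rate(tau).tau
    return (speed / rate) * math.log(1.0 / visibility_threshold)
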