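"""Independent numerical oracle for the integrator dynamics.

A fixed-step 4th-order Runge-Kutta integrator of the gated cascade

    dxV/dt  = m [-tau_x xV  + IV]
    dxAV/dt = m [-tau_x xAV + IAV]
    dy/dt   = m [-tau_y y + xV - xAV]

on piecewise-constant inputs.  Integration proceeds segment by segment
(each segment has constant m, IV, IAV) so discontinuities never fall
inside a step; within a segment the right-hand side is smooth and RK4 at
step 0.01 ms resolves it to well below 1e-6 relative error.  This module
deliberately shares no code with vismem's closed-form solver.
"""

from __future__ import annotations

import math


def rk4_cascade(
    segments: list[tuple[float, float, int, float, float]],
    tau_x: float,
    tau_y: float | None = None,
    h: float = 0.01,
    state0: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> list[tuple[float, float, float, float]]:
    """Integrate the cascade over ``segments`` = [(t0, t1, m, cV, cAV), ...].

    Returns the state (t, xV, xAV, y) at the end of every segment,
    starting from ``state0`` at the first segment's start.  Segments
    must be contiguous and ordered.
    """
    tau_y = tau_x if tau_y is None else tau_y
    xV, xAV, y = state0
    out = []
    for (t0, t1, m, cV, cAV) in segments:
        if t1 < t0:
            raise ValueError("segment end before start")
        if m == 0:
            # gate closed: d/dt = 0 exactly
            out.append((t1, xV, xAV, y))
            continue

        def f(state):
            sxV, sxAV, sy = state
            return (
                -tau_x * sxV + cV,
                -tau_x * sxAV + cAV,
                -tau_y * sy + sxV - sxAV,
            )

        span = t1 - t0
        n = max(1, math.ceil(span / h))
        dt = span / n
        for _ in range(n):
            s = (xV, xAV, y)
            k1 = f(s)
            k2 = f(tuple(si + 0.5 * dt * ki for si, ki in zip(s, k1)))
            k3 = f(tuple(si + 0.5 * dt * ki for si, ki in zip(s, k2)))
            k4 = f(tuple(si + dt * ki for si, ki in zip(s, k3)))
            xV, xAV, y = (
                si + dt / 6.0 * (a + 2 * b + 2 * c + d)
                for si, a, b, c, d in zip(s, k1, k2, k3, k4)
            )
        out.append((t1, xV, xAV, y))
    return out


def segments_from_train(events, gating_value, cuts, tau_ignored=None):
    """Build contiguous (t0, t1, m, cV, cAV) segments from an event train.

    ``cuts`` is a sorted list of boundary times covering the span of
    interest; ``gating_value(t)`` gives m on [t, next).  Drives are the
    sums of unit amplitudes of active V / AV events (excluded and
    occluded events contribute nothing).
    """
    def level(t, pol):
        tot = 0.0
        for e in events:
            if e.polarity.value == pol and e.drives and e.onset <= t < e.offset:
                tot += 1.0
        return tot

    segs = []
    for a, b in zip(cuts, cuts[1:]):
        segs.append((a, b, gating_value(a), level(a, "V"), level(a, "AV")))
    return segs
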