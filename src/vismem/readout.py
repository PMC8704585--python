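"""Sigmoid readout: pooled activity -> accordance and dominance.

Observers report the perceived vernier offset direction; *accordance* is
the percentage of reports agreeing with the reference (central) vernier,
50% being chance.  The internal stimulus strength is the pooled activity
y at the readout time, mapped through

    d(y) = 100 / (1 + exp(-2 y / sigma)),

a psychometric sigmoid with slope constant sigma.  Subtracting the 50%
chance level gives the *dominance level* in [-50, +50]: positive values
mean the reference vernier dominates the percept, negative values the
opposing (anti-vernier) offset.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = [
    "accordance_from_activity",
    "accordance_to_dominance",
    "dominance_from_activity",
    "additivity_prediction",
]


def accordance_from_activity(y_r, sigma: float):
    """Percent accordance for pooled activity ``y_r`` at readout.

    Strictly increasing in ``y_r`` with range (0, 100); zero activity
    maps to the 50% chance level.  Accepts scalars or arrays.
    """
    if not np.ndim(sigma) == 0 or not sigma > 0:
        raise ValueError(f"sigma must be a positive scalar, got {sigma!r}")
    y = np.asarray(y_r, dtype=float)
    out = 100.0 * expit(2.0 * y / float(sigma))  # = 100 / (1 + exp(-2 y / sigma))
    return out if y.ndim else float(out)


def accordance_to_dominance(accordance):
    """Dominance level (accordance minus the 50% chance level)."""
    a = np.asarray(accordance, dtype=float)
    if np.any(a < 0) or np.any(a > 100):
        raise ValueError("accordance must lie in [0, 100]")
    out = a - 50.0
    return out if a.ndim else float(out)


def dominance_from_activity(y_r, sigma: float):
    """Convenience composition: activity -> accordance -> dominance."""
    return accordance_to_dominance(accordance_from_activity(y_r, sigma))


def additivity_prediction(dom_C, dom_F, clip: bool = True):
    """Linear prediction for a combined condition: dom_C + dom_F.

    Feature integration is approximately linear, so the dominance of a
    combined condition (reference offset plus flank offset in the same
    stream) is predicted by the sum of the single-offset dominances.
    The raw sum is clipped to the reportable [-50, 50] range unless
    ``clip=False`` (useful for diagnostics).
    """
    s = np.asarray(dom_C, dtype=float) + np.asarray(dom_F, dtype=float)
    if clip:
        s = np.clip(s, -50.0, 50.0)
    return s if s.ndim else float(s)
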