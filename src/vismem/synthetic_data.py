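"""Synthetic observers and condition batteries.

No public dataset accompanies the dominance experiments, so every other
module is exercised against simulated data: binomial observer responses
whose success probability is the model-predicted accordance, and
reproducible condition batteries built around the three named anchor
conditions (V-AV-S, S-S-V, V-AV-V-AV) plus randomized fillers emulating
the "30 other combinations" used for the original three-parameter fit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stimuli import BATTERY_COLUMNS, FeaturePolarity

__all__ = ["simulate_responses", "battery_generator", "ANCHOR_CONDITIONS"]

# Named anchor conditions with the published two-frame timing
# (30 ms sub-frames, 160 ms inter-stimulus interval, group motion).
ANCHOR_CONDITIONS: list[tuple[str, float, float]] = [
    ("V-AV-S", 30.0, 160.0),
    ("S-S-V", 30.0, 160.0),
    ("V-AV-V-AV", 30.0, 160.0),
]

# Filler timing ranges bracket all published timings
# (30 ms frames; 100-220 ms inter-stimulus intervals).
_FRAME_RANGE = (10.0, 100.0)
_ISI_RANGE = (0.0, 300.0)
_DEFAULT_TRIALS = 100


def simulate_responses(
    predicted_accordance,
    n_trials: int = _DEFAULT_TRIALS,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate two-alternative observer reports for each condition.

    ``predicted_accordance`` maps condition_id -> accordance in percent
    (a mapping or a Series).  Each condition draws
    ``k ~ Binomial(n_trials, accordance / 100)`` accordant reports from
    a generator seeded with ``seed``; the table records the seed so runs
    are reproducible.
    """
    acc = pd.Series(predicted_accordance, dtype=float)
    if ((acc < 0) | (acc > 100)).any():
        raise ValueError("accordance values must lie in [0, 100]")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    k = rng.binomial(n_trials, acc.to_numpy() / 100.0)
    return pd.DataFrame(
        {
            "condition_id": acc.index.astype(str),
            "n_trials": n_trials,
            "k_accordant": k,
            "seed": seed,
        }
    )


def battery_generator(
    n_conditions: int = 33,
    seed: int = 0,
    n_trials: int = _DEFAULT_TRIALS,
) -> pd.DataFrame:
    """Reproducible condition battery with fixed anchors.

    The first three rows are always the anchors V-AV-S, S-S-V and
    V-AV-V-AV at the published timing; the remaining
    ``n_conditions - 3`` rows are randomized V/AV/S combinations (3 or
    4 tokens) with frame durations drawn from [10, 100] ms and
    inter-stimulus intervals from [0, 300] ms.  Identical across seeds
    for the anchors, seed-dependent for the fillers.
    """
    if n_conditions < 1:
        raise ValueError("n_conditions must be >= 1")
    rng = np.random.default_rng(seed)
    tokens = [p.value for p in FeaturePolarity]
    rows = []
    for spec, frame_ms, isi_ms in ANCHOR_CONDITIONS[:n_conditions]:
        rows.append((spec, spec, frame_ms, isi_ms))
    for i in range(max(0, n_conditions - len(ANCHOR_CONDITIONS))):
        n_tok = int(rng.integers(3, 5))
        spec = "-".join(rng.choice(tokens) for _ in range(n_tok))
        frame_ms = float(np.round(rng.uniform(*_FRAME_RANGE), 1))
        isi_ms = float(np.round(rng.uniform(*_ISI_RANGE), 1))
        rows.append((f"rand{i:02d}-{spec}", spec, frame_ms, isi_ms))
    df = pd.DataFrame(rows, columns=["condition_id", "spec", "frame_ms", "isi_ms"])
    df["percept"] = "group"
    df["n_trials"] = n_trials
    df["k_accordant"] = np.nan
    return df.loc[:, BATTERY_COLUMNS]
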