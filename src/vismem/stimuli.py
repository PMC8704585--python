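"""Stimulus paradigms for probing visual sensory memory.

Two classic paradigms are represented here:

* the **sequential metacontrast** (SQM) stream, in which a central vernier
  line is followed by pairs of flanking lines at increasing eccentricity,
  giving rise to two expanding apparent-motion streams; and
* the **Ternus-Pikler display** (TPD), a two-frame three-element
  apparent-motion display in which long inter-stimulus intervals yield
  "group motion" (every element appears to shift one position) and short
  ones yield "element motion" (only the outer element appears to jump).

Elements carry a vernier feature that is either offset in the reference
direction (``V``), offset oppositely (``AV``, the anti-vernier) or straight
(``S``, zero offset).  Feature integration in non-retinotopic sensory
memory is *stream specific*: only elements lying on the same motion stream
are pooled.  The functions in this module construct event trains and
resolve stream membership; the actual integration dynamics live in
:mod:`vismem.dynamics`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

__all__ = [
    "FeaturePolarity",
    "FeatureEvent",
    "StimulusSequence",
    "TernusDisplay",
    "MotionPercept",
    "CorrespondenceMap",
    "build_sqm_stream",
    "build_ternus",
    "ternus_events",
    "correspondence",
    "stream_events",
    "apply_saccade",
    "occlude_event",
    "remove_event",
    "read_battery",
    "write_battery",
    "BATTERY_COLUMNS",
]


class FeaturePolarity(enum.Enum):
    """Vernier feature polarity of a stimulus element.

    ``V`` is an offset in the reference direction (drive +1), ``AV`` the
    opposite offset (drive -1) and ``S`` a straight element with zero
    offset that contributes no feature drive.
    """

    V = "V"
    AV = "AV"
    S = "S"

    @property
    def drive_value(self) -> int:
        return {FeaturePolarity.V: 1, FeaturePolarity.AV: -1, FeaturePolarity.S: 0}[self]

    @classmethod
    def parse(cls, token: Union[str, "FeaturePolarity"]) -> "FeaturePolarity":
        if isinstance(token, cls):
            return token
        try:
            return cls(str(token).strip().upper())
        except ValueError:
            raise ValueError(
                f"unknown polarity token {token!r}; expected one of V, AV, S"
            ) from None


class MotionPercept(enum.Enum):
    """Perceived motion organisation of a Ternus-Pikler display."""

    element = "element"
    group = "group"


@dataclass(frozen=True)
class FeatureEvent:
    """One stimulus element: a vernier feature at a time and place.

    Parameters
    ----------
    polarity : FeaturePolarity
        Feature carried by the element.
    onset, duration : float
        Presentation time in ms; ``duration`` must be positive.
    position : int
        Retinotopic position index (0 = fovea/centre by convention).
    frame_index : int
        Display frame the element belongs to; frames are separated by
        inter-stimulus intervals.
    stream_id : str or None
        Motion-stream label; ``None`` if unresolved.
    eccentricity : float or None
        Optional physical eccentricity in arcmin.  Metadata only: the
        dynamics never read it.
    excluded : bool
        True when the element falls outside the integration window and
        must not drive the integrators.
    occluded : bool
        True when the element is occluded: it contributes no drive but
        preserves stream continuity (unlike removal, which splits the
        stream).
    """

    polarity: FeaturePolarity
    onset: float
    duration: float
    position: int
    frame_index: int = 0
    stream_id: str | None = None
    eccentricity: float | None = None
    excluded: bool = False
    occluded: bool = False

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"event duration must be positive, got {self.duration}")
        if self.onset < 0:
            raise ValueError(f"event onset must be >= 0, got {self.onset}")
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")

    @property
    def offset(self) -> float:
        """Time at which the element disappears (ms)."""
        return self.onset + self.duration

    @property
    def drives(self) -> bool:
        """Whether this event contributes input to the integrators."""
        return not (self.excluded or self.occluded) and self.polarity is not FeaturePolarity.S


@dataclass(frozen=True)
class StimulusSequence:
    """An ordered train of feature events with frame boundaries."""

    events: tuple[FeatureEvent, ...]
    frame_windows: tuple[tuple[float, float], ...]
    total_duration: float

    def __post_init__(self) -> None:
        onsets = [e.onset for e in self.events]
        if onsets != sorted(onsets):
            raise ValueError("events must be sorted by onset")
        for (a0, a1), (b0, b1) in zip(self.frame_windows, self.frame_windows[1:]):
            if not (a0 <= a1 <= b0 <= b1):
                raise ValueError("frame windows must be ordered and non-overlapping")
        for e in self.events:
            w = self.frame_windows[e.frame_index]
            if not (w[0] <= e.onset and e.offset <= w[1] + 1e-9):
                raise ValueError(
                    f"event at {e.onset} ms does not lie inside frame window {w}"
                )

    def __len__(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class TernusDisplay:
    """A (possibly modified) two-frame Ternus-Pikler display.

    Frame 1 shows elements at positions {0, 1, 2}, frame 2 at {1, 2, 3}.
    The centre of frame 1 (position 1) may be split into two successive
    sub-frames, each of ``frame_duration`` ms, to probe retinotopic
    integration; the frame-2 element that corresponds to it under group
    motion (position 2) may be split likewise.
    """

    frame1_polarities: Mapping[int, FeaturePolarity]
    frame2_polarities: Mapping[int, FeaturePolarity]
    frame_duration: float
    isi: float
    sub_frame_split: tuple[FeaturePolarity, FeaturePolarity] | None = None
    frame2_sub_frame_split: tuple[FeaturePolarity, FeaturePolarity] | None = None

    def __post_init__(self) -> None:
        if self.frame_duration <= 0:
            raise ValueError("frame_duration must be positive")
        if self.isi < 0:
            raise ValueError("isi must be >= 0")
        if set(self.frame1_polarities) != {0, 1, 2}:
            raise ValueError("frame 1 must have elements exactly at positions {0, 1, 2}")
        if set(self.frame2_polarities) != {1, 2, 3}:
            raise ValueError("frame 2 must have elements exactly at positions {1, 2, 3}")

    @property
    def frame1_duration(self) -> float:
        return self.frame_duration * (2 if self.sub_frame_split else 1)

    @property
    def frame2_duration(self) -> float:
        return self.frame_duration * (2 if self.frame2_sub_frame_split else 1)

    @property
    def frame2_onset(self) -> float:
        return self.frame1_duration + self.isi


@dataclass(frozen=True)
class CorrespondenceMap:
    """Element correspondences between the two Ternus frames.

    Under group motion every element shifts one position (0→1, 1→2, 2→3);
    under element motion the outer element jumps (0→3) while the shared
    positions 1 and 2 appear stationary.
    """

    moving_pairs: frozenset[tuple[int, int]]
    stationary_positions: frozenset[int]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for p1, _ in self.moving_pairs:
            if p1 in seen:
                raise ValueError("a frame-1 position appears in more than one pair")
            seen.add(p1)
        if seen | set(self.stationary_positions) != {0, 1, 2}:
            raise ValueError("mapped frame-1 positions must cover exactly {0, 1, 2}")

    def source_of(self, frame2_position: int) -> int | None:
        """Frame-1 position bound to ``frame2_position``; None if unbound."""
        if frame2_position in self.stationary_positions:
            return frame2_position
        for p1, p2 in self.moving_pairs:
            if p2 == frame2_position:
                return p1
        return None


_GROUP_MAP = CorrespondenceMap(frozenset({(0, 1), (1, 2), (2, 3)}), frozenset())
_ELEMENT_MAP = CorrespondenceMap(frozenset({(0, 3)}), frozenset({1, 2}))


def correspondence(display: TernusDisplay, percept: MotionPercept | str) -> CorrespondenceMap:
    """Motion correspondences for a Ternus display under a given percept.

    The percept is supplied by the caller (it depends on the ISI in ways
    not modelled here): ``group`` binds 0→1, 1→2, 2→3, ``element`` binds
    0→3 with positions 1 and 2 stationary.
    """
    percept = MotionPercept(percept) if not isinstance(percept, MotionPercept) else percept
    return _GROUP_MAP if percept is MotionPercept.group else _ELEMENT_MAP


# ---------------------------------------------------------------------------
# Sequential metacontrast
# ---------------------------------------------------------------------------

_SIDES = ("attended", "unattended")

OffsetSpec = Union[
    FeaturePolarity,
    str,
    "tuple[FeaturePolarity | str, str]",
]


def _normalise_offsets(
    offsets: Mapping[int, OffsetSpec] | None,
) -> dict[int, tuple[FeaturePolarity, str]]:
    out: dict[int, tuple[FeaturePolarity, str]] = {}
    for pos, spec in (offsets or {}).items():
        if isinstance(spec, tuple):
            pol, side = spec
            side = str(side).lower()
            if side not in _SIDES:
                raise ValueError(f"offset side must be one of {_SIDES}, got {side!r}")
        else:
            pol, side = spec, "attended"
        out[int(pos)] = (FeaturePolarity.parse(pol), side)
    return out


def build_sqm_stream(
    n_pairs: int,
    element_duration: float = 30.0,
    soa: float = 30.0,
    attended_side: str = "left",
    offsets: Mapping[int, OffsetSpec] | None = None,
    integration_window: float = 400.0,
) -> StimulusSequence:
    """Build a sequential-metacontrast stream.

    A central line at position 0 is followed by ``n_pairs`` pairs of
    flanking lines at retinotopic positions ±k, one pair every ``soa``
    ms, producing two expanding motion streams.  Flanks on
    ``attended_side`` carry ``stream_id='attended'`` (stream position k
    for the k-th flank), the mirror flanks ``'unattended'``; the central
    line opens the attended stream.

    ``offsets`` maps stream position → polarity, optionally as
    ``(polarity, side)`` with side in {'attended', 'unattended'}
    (default attended); unlisted elements are straight.  Events whose
    onset falls at or beyond ``integration_window`` ms (measured from
    stimulus onset; sensory-memory integration is mandatory only within
    roughly the first 400-450 ms) are flagged ``excluded`` and do not
    drive the integrators.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if element_duration <= 0 or soa <= 0:
        raise ValueError("element_duration and soa must be positive")
    if attended_side not in ("left", "right"):
        raise ValueError("attended_side must be 'left' or 'right'")
    norm = _normalise_offsets(offsets)
    for pos in norm:
        if not (0 <= pos <= n_pairs):
            raise ValueError(
                f"offset position {pos} out of range for a stream with {n_pairs} flank pairs"
            )

    att_sign = -1 if attended_side == "left" else 1

    def _pol(stream_pos: int, side: str) -> FeaturePolarity:
        pol_side = norm.get(stream_pos)
        if pol_side is not None and pol_side[1] == side:
            return pol_side[0]
        return FeaturePolarity.S

    events: list[FeatureEvent] = []
    central_pol = norm.get(0, (FeaturePolarity.S, "attended"))[0]
    events.append(
        FeatureEvent(
            polarity=central_pol,
            onset=0.0,
            duration=element_duration,
            position=0,
            frame_index=0,
            stream_id="attended",
            excluded=False,
        )
    )
    for k in range(1, n_pairs + 1):
        onset = k * soa
        excl = onset >= integration_window
        events.append(
            FeatureEvent(
                polarity=_pol(k, "attended"),
                onset=onset,
                duration=element_duration,
                position=att_sign * k,
                frame_index=k,
                stream_id="attended",
                excluded=excl,
            )
        )
        events.append(
            FeatureEvent(
                polarity=_pol(k, "unattended"),
                onset=onset,
                duration=element_duration,
                position=-att_sign * k,
                frame_index=k,
                stream_id="unattended",
                excluded=excl,
            )
        )
    windows = tuple(
        (k * soa, k * soa + element_duration) for k in range(n_pairs + 1)
    )
    return StimulusSequence(
        events=tuple(events),
        frame_windows=windows,
        total_duration=n_pairs * soa + element_duration,
    )


# ---------------------------------------------------------------------------
# Ternus-Pikler displays
# ---------------------------------------------------------------------------


def build_ternus(
    spec: str,
    frame_duration: float = 30.0,
    isi: float = 160.0,
) -> TernusDisplay:
    """Build a modified Ternus display from a condition string.

    The string lists polarities hyphen-separated: the first two tokens
    are the successive sub-frames at the centre of frame 1, the third
    the frame-2 element corresponding to that centre under group motion,
    and an optional fourth token splits the frame-2 element likewise.
    ``'V-AV-S'`` thus shows V then AV at the frame-1 centre and a
    straight element in frame 2; ``'S-S-V'`` shows only the frame-2 V.
    Each sub-frame lasts ``frame_duration`` ms.
    """
    tokens = [t for t in str(spec).split("-") if t != ""]
    if len(tokens) not in (3, 4):
        raise ValueError(
            f"condition spec must have 3 or 4 tokens, got {len(tokens)} in {spec!r}"
        )
    pols = [FeaturePolarity.parse(t) for t in tokens]
    S = FeaturePolarity.S
    return TernusDisplay(
        frame1_polarities={0: S, 1: pols[0], 2: S},
        frame2_polarities={1: S, 2: pols[2], 3: S},
        frame_duration=float(frame_duration),
        isi=float(isi),
        sub_frame_split=(pols[0], pols[1]),
        frame2_sub_frame_split=(pols[2], pols[3]) if len(pols) == 4 else None,
    )


def ternus_events(display: TernusDisplay) -> tuple[FeatureEvent, ...]:
    """All elements of the display as feature events (frame indices 0, 1)."""
    d = display.frame_duration
    events: list[FeatureEvent] = []
    for pos, pol in sorted(display.frame1_polarities.items()):
        if pos == 1 and display.sub_frame_split:
            a, b = display.sub_frame_split
            events.append(FeatureEvent(a, 0.0, d, pos, 0))
            events.append(FeatureEvent(b, d, d, pos, 0))
        else:
            events.append(FeatureEvent(pol, 0.0, display.frame1_duration, pos, 0))
    t2 = display.frame2_onset
    for pos, pol in sorted(display.frame2_polarities.items()):
        if pos == 2 and display.frame2_sub_frame_split:
            a, b = display.frame2_sub_frame_split
            events.append(FeatureEvent(a, t2, d, pos, 1))
            events.append(FeatureEvent(b, t2 + d, d, pos, 1))
        else:
            events.append(FeatureEvent(pol, t2, display.frame2_duration, pos, 1))
    return tuple(sorted(events, key=lambda e: (e.onset, e.position)))


def stream_events(
    source: StimulusSequence | TernusDisplay,
    stream: CorrespondenceMap | str,
    attended_position: int | None = None,
) -> tuple[FeatureEvent, ...]:
    """Events lying on the motion stream through the attended element.

    Feature integration is stream specific: only these events feed the
    integrators for the attended element.  Two call forms:

    * ``stream_events(sequence, stream_id)`` — filter a
      :class:`StimulusSequence` to the events carrying ``stream_id``.
    * ``stream_events(display, correspondence_map, attended_position)``
      — resolve, via the Ternus correspondences, which frame-1 element
      binds to the attended frame-2 position and return that chain.

    Output is ordered by onset and is always a subsequence of the input.
    """
    if isinstance(source, StimulusSequence):
        if not isinstance(stream, str):
            raise TypeError("for a StimulusSequence, pass a stream_id string")
        train = tuple(e for e in source.events if e.stream_id == stream)
        if not train:
            raise ValueError(f"no events on stream {stream!r}")
        return train

    if not isinstance(stream, CorrespondenceMap):
        raise TypeError("for a TernusDisplay, pass a CorrespondenceMap")
    if attended_position not in source.frame2_polarities:
        raise ValueError(
            f"attended position {attended_position} is not present in frame 2"
        )
    src = stream.source_of(attended_position)
    sid = f"{src}->{attended_position}" if src is not None else f"->{attended_position}"
    train = [
        replace(e, stream_id=sid)
        for e in ternus_events(source)
        if (e.frame_index == 0 and e.position == src)
        or (e.frame_index == 1 and e.position == attended_position)
    ]
    return tuple(train)


# ---------------------------------------------------------------------------
# Manipulations: saccades, occlusion, removal
# ---------------------------------------------------------------------------


def apply_saccade(
    sequence: StimulusSequence, saccade_time: float, position_shift: int
) -> StimulusSequence:
    """Shift retinotopic positions of all events from ``saccade_time`` on.

    Models an eye movement during the stream: the retinal location of
    later elements changes by ``position_shift`` while stream identities
    (and hence non-retinotopic integration) are untouched.
    """
    if not (0 < saccade_time < sequence.total_duration):
        raise ValueError("saccade_time must fall strictly inside the sequence")
    shifted = tuple(
        replace(e, position=e.position + position_shift) if e.onset >= saccade_time else e
        for e in sequence.events
    )
    return replace(sequence, events=shifted)


def occlude_event(sequence: StimulusSequence, index: int) -> StimulusSequence:
    """Occlude one element: no drive, but the stream stays continuous."""
    events = list(sequence.events)
    events[index] = replace(events[index], occluded=True)
    return replace(sequence, events=tuple(events))


def remove_event(sequence: StimulusSequence, index: int) -> StimulusSequence:
    """Delete one element, splitting its motion stream at the gap.

    Events on the same stream after the removed element are relabelled
    ``'<stream_id>:post-gap'``: with the element gone there is no motion
    correspondence bridging the gap, so the later elements form a new
    stream (whereas occlusion preserves the stream, see
    :func:`occlude_event`).
    """
    events = list(sequence.events)
    removed = events.pop(index)
    out = []
    for e in events:
        if e.stream_id == removed.stream_id and e.onset > removed.onset:
            e = replace(e, stream_id=f"{e.stream_id}:post-gap")
        out.append(e)
    return replace(sequence, events=tuple(out))


# ---------------------------------------------------------------------------
# Condition-battery files
# ---------------------------------------------------------------------------

BATTERY_COLUMNS = [
    "condition_id",
    "spec",
    "frame_ms",
    "isi_ms",
    "percept",
    "n_trials",
    "k_accordant",
]


def write_battery(battery: pd.DataFrame, path) -> None:
    """Write a condition battery to CSV (columns :data:`BATTERY_COLUMNS`)."""
    missing = [c for c in BATTERY_COLUMNS if c not in battery.columns]
    if missing:
        raise ValueError(f"battery is missing columns {missing}")
    battery.loc[:, BATTERY_COLUMNS].to_csv(path, index=False)


def read_battery(path) -> pd.DataFrame:
    """Read a condition battery CSV; blank counts stay as NaN."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in BATTERY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"battery file {path} is missing columns {missing}")
    df["condition_id"] = df["condition_id"].astype(str)
    df["spec"] = df["spec"].astype(str)
    df["percept"] = df["percept"].astype(str)
    return df.loc[:, BATTERY_COLUMNS]
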