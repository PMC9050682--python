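"""Counterbalanced rapid-serial design generation for overlaid-orientation sequences.

Each sequence is a rapid stream of briefly flashed stimuli, every stimulus a
pair of overlaid oriented line patches in two colours (blue and orange).  One
colour is cued for the whole sequence; the observer responds when the cued
colour shows the sequence's target orientation.  Only the 104 fully
counterbalanced non-target presentations per sequence enter analysis: target
events, foil events (target orientation in the uncued colour) and padding
presentations around events and sequence boundaries are flagged
non-analysable.

All stimulus timing lives on a 60 Hz display frame grid: inter-stimulus
intervals are stored as integer frame counts so that the counterbalanced ISI
values (100–300 ms in 1000/60 ms steps) never accumulate floating-point
drift.  Millisecond values are derived views.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

#: Orientations (degrees) used for analysable non-target stimuli.
ORIENTATIONS: tuple[float, ...] = (22.5, 67.5, 112.5, 157.5)
#: Orientation pairs defining the two orthogonal analysis groups.
GROUP1_ORIENTATIONS: tuple[float, float] = (22.5, 112.5)
GROUP2_ORIENTATIONS: tuple[float, float] = (67.5, 157.5)
#: Possible sequence target orientations and their paired orientations.
TARGET_ORIENTATIONS: tuple[float, float] = (0.0, 90.0)
EVENT_OTHER_ORIENTATIONS: tuple[float, float] = (45.0, 135.0)

COLOURS: tuple[str, str] = ("blue", "orange")
ISI_CONDITIONS: tuple[str, str] = ("constant", "varied")

#: Duration of one display frame at the 60 Hz refresh rate, in ms.
FRAME_MS: float = 1000.0 / 60.0
#: Stimulus duration: 100 ms = 6 frames.
STIM_FRAMES: int = 6
STIM_DURATION_MS: float = 100.0

#: Analysable presentations per sequence.
N_NONTARGET: int = 104
#: Padding presentations at sequence start and end.
N_EDGE_PADDING: int = 4
#: Padding presentations before / after each target or foil event.
N_PAD_BEFORE_EVENT: int = 3
N_PAD_AFTER_EVENT: int = 4

EVENTS_TSV_COLUMNS = [
    "onset",
    "duration",
    "trial_type",
    "role",
    "blue_orientation",
    "orange_orientation",
    "cued_colour",
    "cued_orientation",
    "uncued_orientation",
    "isi_before_ms",
    "isi_condition",
    "sequence_id",
    "analysable",
]


class Role(str, Enum):
    """Role of one presentation within a sequence."""

    NON_TARGET = "non_target"
    TARGET = "target"
    FOIL = "foil"
    PADDING = "padding"


def angular_difference(a: float, b: float) -> float:
    """Smallest angle between two orientations, in degrees on [0, 90]."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


@dataclass(frozen=True)
class StimulusType:
    """One of the 8 analysable blue/orange orientation combinations."""

    id: int
    blue_orientation: float
    orange_orientation: float

    def orientation(self, colour: str) -> float:
        if colour == "blue":
            return self.blue_orientation
        if colour == "orange":
            return self.orange_orientation
        raise ValueError(f"unknown colour: {colour!r}")


@dataclass(frozen=True)
class EventStimulus:
    """A target or foil presentation.

    The sequence's target orientation (0 or 90 deg) is shown in the cued
    colour for a target and in the uncued colour for a foil; the other colour
    carries a 45 or 135 deg patch.
    """

    target_colour_orientation: float
    other_colour_orientation: float
    is_target: bool

    def __post_init__(self) -> None:
        if self.target_colour_orientation not in TARGET_ORIENTATIONS:
            raise ValueError("target orientation must be 0 or 90 degrees")
        if self.other_colour_orientation not in EVENT_OTHER_ORIENTATIONS:
            raise ValueError("paired orientation must be 45 or 135 degrees")

    def orientation(self, colour: str, cued_colour: str) -> float:
        """Orientation shown in `colour` given which colour is cued."""
        shows_target = (colour == cued_colour) == self.is_target
        return (
            self.target_colour_orientation
            if shows_target
            else self.other_colour_orientation
        )


Stimulus = Union[StimulusType, EventStimulus]


@dataclass(frozen=True)
class StimulusEvent:
    """One presentation within a sequence."""

    stimulus: Stimulus
    isi_before_frames: int
    role: Role
    index_in_sequence: int
    onset_frames: int

    duration_ms: float = STIM_DURATION_MS

    @property
    def isi_before_ms(self) -> float:
        return self.isi_before_frames * FRAME_MS

    @property
    def onset_ms(self) -> float:
        return self.onset_frames * FRAME_MS

    @property
    def analysable(self) -> bool:
        return self.role is Role.NON_TARGET


@dataclass
class SequenceSpec:
    """An ordered stimulus sequence with its sequence-level attributes."""

    events: list[StimulusEvent]
    cued_colour: str
    target_orientation: float
    isi_condition: str
    n_targets: int
    n_foils: int
    sequence_id: int = 0

    @property
    def analysable_events(self) -> list[StimulusEvent]:
        return [e for e in self.events if e.analysable]

    @property
    def uncued_colour(self) -> str:
        return "orange" if self.cued_colour == "blue" else "blue"

    @property
    def duration_frames(self) -> int:
        last = self.events[-1]
        return last.onset_frames + STIM_FRAMES

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class SessionSpec:
    """A participant's full set of sequences."""

    sequences: list[SequenceSpec]
    participant_id: str
    rng_seed: int

    def __len__(self) -> int:
        return len(self.sequences)


def make_stimulus_set() -> list[StimulusType]:
    """Enumerate the 8 blue/orange orientation combinations.

    The two overlaid orientations always differ by 45 degrees (modulo 180),
    so each of the 4 possible orientations in one colour co-occurs with
    exactly 2 orientations in the other colour.  Ordering is deterministic by
    (blue_orientation, orange_orientation).
    """
    combos = [
        (b, o)
        for b, o in itertools.product(ORIENTATIONS, ORIENTATIONS)
        if angular_difference(b, o) == 45.0
    ]
    combos.sort()
    return [
        StimulusType(id=i + 1, blue_orientation=b, orange_orientation=o)
        for i, (b, o) in enumerate(combos)
    ]


def isi_grid_frames(condition: str) -> list[int]:
    """Allowed inter-stimulus intervals as integer 60 Hz frame counts."""
    if condition == "constant":
        return [12]  # 200 ms
    if condition == "varied":
        return list(range(6, 19))  # 100 .. 300 ms in 1000/60 ms steps
    raise ValueError(f"unknown ISI condition: {condition!r}")


def isi_grid(condition: str) -> list[float]:
    """Allowed inter-stimulus intervals in milliseconds."""
    return [k * FRAME_MS for k in isi_grid_frames(condition)]


def generate_nontarget_stream(
    isi_condition: str, rng: np.random.Generator
) -> list[tuple[StimulusType, int]]:
    """Generate the 104 counterbalanced non-target presentations.

    In the varied condition every (ISI, stimulus type) cell of the 13 x 8
    table occurs exactly once; in the constant condition every type occurs 13
    times at the single 200 ms ISI.  Order is a seeded random permutation.

    Returns a list of (StimulusType, isi_before_frames) pairs.
    """
    types = make_stimulus_set()
    frames = isi_grid_frames(isi_condition)
    if isi_condition == "varied":
        cells = [(t, f) for f in frames for t in types]
    else:
        cells = [(t, frames[0]) for t in types for _ in range(13)]
    order = rng.permutation(len(cells))
    return [cells[i] for i in order]


def _draw_padding_block(
    k: int, frames_grid: Sequence[int], rng: np.random.Generator
) -> list[tuple[StimulusType, int]]:
    """Draw k padding stimuli without replacement from the 8 types.

    Without-replacement applies within each contiguous padding block (all
    blocks have at most 4 stimuli, so the draw is always feasible); ISIs are
    drawn uniformly from the condition's grid.
    """
    types = make_stimulus_set()
    idx = rng.choice(len(types), size=k, replace=False)
    return [(types[i], int(rng.choice(frames_grid))) for i in idx]


def _infer_isi_condition(stream: Sequence[tuple[StimulusType, int]]) -> str:
    frames = {f for _, f in stream}
    return "constant" if frames == {12} else "varied"


def insert_events_and_padding(
    stream: Sequence[tuple[StimulusType, int]],
    n_targets: int,
    n_foils: int,
    cued_colour: str,
    target_orientation: float,
    rng: np.random.Generator,
    sequence_id: int = 0,
) -> SequenceSpec:
    """Assemble a full sequence from a non-target stream.

    Adds 4 padding presentations at each sequence boundary and wraps every
    target/foil event in 3 padding presentations before and 4 after.  Event
    blocks are placed uniformly at random in distinct gaps between
    consecutive non-targets, so no block touches the boundary padding and no
    two blocks merge.  Everything except the 104 non-targets is flagged
    non-analysable.
    """
    if n_targets not in (1, 2) or n_foils not in (1, 2):
        raise ValueError("n_targets and n_foils must be 1 or 2")
    if cued_colour not in COLOURS:
        raise ValueError(f"unknown colour: {cued_colour!r}")
    stream = list(stream)
    n_events = n_targets + n_foils
    isi_condition = _infer_isi_condition(stream)
    frames_grid = isi_grid_frames(isi_condition)

    # Distinct gaps strictly inside the non-target stream (between item i-1
    # and item i), so event blocks can neither overlap each other nor touch
    # the start/end padding.
    if len(stream) < n_events + 1:
        raise ValueError("stream too short to place all event blocks")
    gaps = sorted(rng.choice(np.arange(1, len(stream)), n_events, replace=False))
    roles = [Role.TARGET] * n_targets + [Role.FOIL] * n_foils
    roles = [roles[i] for i in rng.permutation(n_events)]
    gap_to_role = dict(zip(gaps, roles))

    items: list[tuple[Stimulus, int, Role]] = []

    def add_padding(k: int) -> None:
        for stim, fr in _draw_padding_block(k, frames_grid, rng):
            items.append((stim, fr, Role.PADDING))

    add_padding(N_EDGE_PADDING)
    for i, (stim, fr) in enumerate(stream):
        if i in gap_to_role:
            add_padding(N_PAD_BEFORE_EVENT)
            ev = EventStimulus(
                target_colour_orientation=target_orientation,
                other_colour_orientation=float(
                    rng.choice(EVENT_OTHER_ORIENTATIONS)
                ),
                is_target=gap_to_role[i] is Role.TARGET,
            )
            items.append((ev, int(rng.choice(frames_grid)), gap_to_role[i]))
            add_padding(N_PAD_AFTER_EVENT)
        items.append((stim, fr, Role.NON_TARGET))
    add_padding(N_EDGE_PADDING)

    events: list[StimulusEvent] = []
    onset = 0
    for index, (stim, fr, role) in enumerate(items):
        onset = (onset + STIM_FRAMES + fr) if index else fr
        events.append(
            StimulusEvent(
                stimulus=stim,
                isi_before_frames=fr,
                role=role,
                index_in_sequence=index,
                onset_frames=onset,
            )
        )
    return SequenceSpec(
        events=events,
        cued_colour=cued_colour,
        target_orientation=float(target_orientation),
        isi_condition=isi_condition,
        n_targets=n_targets,
        n_foils=n_foils,
        sequence_id=sequence_id,
    )


def _session_cells(n_sequences: int) -> list[tuple]:
    """Ordered design cells such that short prefixes stay near-balanced.

    The full session is 64 sequences: the 32 cells of cued colour (2) x
    target orientation (2) x ISI condition (2) x event counts (4), each
    twice.  The ISI condition alternates fastest so that reduced sessions
    (used for simulation studies) keep an even constant/varied split.
    """
    if not 1 <= n_sequences <= 64:
        raise ValueError("n_sequences must be in 1..64")
    cells = [
        (isi, colour, tori, counts)
        for _rep in range(2)
        for counts in ((1, 1), (1, 2), (2, 1), (2, 2))
        for tori in TARGET_ORIENTATIONS
        for colour in COLOURS
        for isi in ISI_CONDITIONS
    ]
    return cells[:n_sequences]


def generate_session(
    participant_id: str, rng_seed: int, n_sequences: int = 64
) -> SessionSpec:
    """Generate a participant's counterbalanced session.

    At the full 64 sequences every one of the 32 design cells appears
    exactly twice; sequence order is a seeded random permutation.
    """
    rng = np.random.default_rng(rng_seed)
    cells = _session_cells(n_sequences)
    order = rng.permutation(len(cells))
    sequences = []
    for seq_id, cell_idx in enumerate(order):
        isi, colour, tori, (nt, nf) = cells[cell_idx]
        stream = generate_nontarget_stream(isi, rng)
        sequences.append(
            insert_events_and_padding(
                stream, nt, nf, colour, tori, rng, sequence_id=seq_id
            )
        )
    return SessionSpec(
        sequences=sequences, participant_id=str(participant_id), rng_seed=rng_seed
    )


# ---------------------------------------------------------------------------
# BIDS-style events tables


def sequence_to_frame(seq: SequenceSpec) -> pd.DataFrame:
    """Tabulate a sequence as a BIDS-style events table (onsets in seconds)."""
    cued = seq.cued_colour
    uncued = seq.uncued_colour
    rows = []
    for e in seq.events:
        stim = e.stimulus
        if isinstance(stim, StimulusType):
            blue = stim.blue_orientation
            orange = stim.orange_orientation
            trial_type = f"pair{stim.id}"
        else:
            blue = stim.orientation("blue", cued)
            orange = stim.orientation("orange", cued)
            trial_type = e.role.value
        cued_ori = blue if cued == "blue" else orange
        uncued_ori = orange if cued == "blue" else blue
        rows.append(
            {
                "onset": round(e.onset_ms / 1000.0, 4),
                "duration": round(e.duration_ms / 1000.0, 4),
                "trial_type": trial_type,
                "role": e.role.value,
                "blue_orientation": blue,
                "orange_orientation": orange,
                "cued_colour": cued,
                "cued_orientation": cued_ori,
                "uncued_orientation": uncued_ori,
                "isi_before_ms": round(e.isi_before_ms, 2),
                "isi_condition": seq.isi_condition,
                "sequence_id": seq.sequence_id,
                "analysable": int(e.analysable),
            }
        )
    return pd.DataFrame(rows, columns=EVENTS_TSV_COLUMNS)


def session_to_frame(session: SessionSpec) -> pd.DataFrame:
    return pd.concat(
        [sequence_to_frame(s) for s in session.sequences], ignore_index=True
    )


def frame_to_sequence(df: pd.DataFrame) -> SequenceSpec:
    """Reconstruct a SequenceSpec from its events table (lossless)."""
    df = df.reset_index(drop=True)
    cued = str(df.loc[0, "cued_colour"])
    isi_condition = str(df.loc[0, "isi_condition"])
    by_pair = {
        (t.blue_orientation, t.orange_orientation): t for t in make_stimulus_set()
    }
    target_rows = df[df["role"] == Role.TARGET.value]
    if len(target_rows):
        target_orientation = float(target_rows["cued_orientation"].iloc[0])
    else:  # foil rows carry the target orientation in the uncued colour
        target_orientation = float(
            df.loc[df["role"] == Role.FOIL.value, "uncued_orientation"].iloc[0]
        )

    events: list[StimulusEvent] = []
    for index, row in df.iterrows():
        role = Role(row["role"])
        blue = float(row["blue_orientation"])
        orange = float(row["orange_orientation"])
        if role in (Role.TARGET, Role.FOIL):
            is_target = role is Role.TARGET
            tco = float(row["cued_orientation"] if is_target else row["uncued_orientation"])
            other = float(row["uncued_orientation"] if is_target else row["cued_orientation"])
            stim: Stimulus = EventStimulus(
                target_colour_orientation=tco,
                other_colour_orientation=other,
                is_target=is_target,
            )
        else:
            stim = by_pair[(blue, orange)]
        events.append(
            StimulusEvent(
                stimulus=stim,
                isi_before_frames=int(round(float(row["isi_before_ms"]) / FRAME_MS)),
                role=role,
                index_in_sequence=int(index),
                onset_frames=int(round(float(row["onset"]) * 1000.0 / FRAME_MS)),
            )
        )
    return SequenceSpec(
        events=events,
        cued_colour=cued,
        target_orientation=target_orientation,
        isi_condition=isi_condition,
        n_targets=int((df["role"] == Role.TARGET.value).sum()),
        n_foils=int((df["role"] == Role.FOIL.value).sum()),
        sequence_id=int(df.loc[0, "sequence_id"]),
    )


def write_events_tsv(obj: SequenceSpec | SessionSpec, path) -> None:
    df = (
        sequence_to_frame(obj)
        if isinstance(obj, SequenceSpec)
        else session_to_frame(obj)
    )
    df.to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> list[SequenceSpec]:
    """Read an events TSV back into one SequenceSpec per sequence_id."""
    df = pd.read_csv(path, sep="\t")
    return [
        frame_to_sequence(g)
        for _, g in df.groupby("sequence_id", sort=True)
    ]
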