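"""Interval-coded behavioral event logs and sensory-signal state sequences.

Mother-infant interaction sessions are coded as timed behavior intervals
(vocalizing, touching, holding, manipulating an object, the child attending
to the object).  This module parses such logs, sweeps the intervals into a
piecewise-constant timeline over the 8 presence/absence combinations of the
three sensory modalities (auditory, visual, tactile), and collapses the
timeline into the sequence of distinct combination states whose transition
structure the entropy-rate statistic summarises.

Intervals are half-open ``[onset, offset)``: at a shared timestamp an
offset is processed before an onset, so an instantaneous handover between
behaviors never creates a spurious overlap state.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Modality",
    "SignalState",
    "SignalEvent",
    "SessionRecord",
    "StateSequence",
    "TimelineSegment",
    "LogDialect",
    "LogFormatError",
    "LogValidationError",
    "STATE_SPACE",
    "NO_BEHAVIOR",
    "DEFAULT_BEHAVIOR_MAP",
    "read_session_log",
    "build_state_timeline",
    "collapse_to_state_sequence",
    "write_state_sequences",
    "read_state_sequences",
]


class Modality(str, enum.Enum):
    """Sensory channel of a coded behavior."""

    AUDITORY = "auditory"
    TACTILE = "tactile"
    VISUAL_MOTHER = "visual_mother"          # mother presenting/manipulating an object
    VISUAL_CHILD_ATTEND = "visual_child_attend"  # child looking at the mother's activity


#: Default mapping from behavior codes (as exported by observational coding
#: software) to sensory modalities.  Extend or replace via ``LogDialect``.
DEFAULT_BEHAVIOR_MAP: dict[str, Modality] = {
    "vocalization": Modality.AUDITORY,
    "speech": Modality.AUDITORY,
    "laughter": Modality.AUDITORY,
    "touch": Modality.TACTILE,
    "stroking": Modality.TACTILE,
    "holding": Modality.TACTILE,
    "manipulating-object": Modality.VISUAL_MOTHER,
    "showing-object": Modality.VISUAL_MOTHER,
    "attending": Modality.VISUAL_CHILD_ATTEND,
    "child-attending": Modality.VISUAL_CHILD_ATTEND,
}


@dataclass(frozen=True, order=True)
class SignalState:
    """One of the 8 presence/absence combinations of the three modalities.

    ``index`` encodes the triple in binary: auditory*4 + visual*2 + tactile*1.
    """

    auditory: bool
    visual: bool
    tactile: bool

    @property
    def index(self) -> int:
        return 4 * int(self.auditory) + 2 * int(self.visual) + int(self.tactile)

    @classmethod
    def from_index(cls, index: int) -> "SignalState":
        if not 0 <= index <= 7:
            raise ValueError(f"state index must be in 0..7, got {index}")
        return cls(bool(index & 4), bool(index & 2), bool(index & 1))

    def __str__(self) -> str:  # e.g. "A-V" for auditory+visual
        parts = [c for c, on in zip("AVT", (self.auditory, self.visual, self.tactile)) if on]
        return "-".join(parts) if parts else "none"


STATE_SPACE: tuple[SignalState, ...] = tuple(SignalState.from_index(i) for i in range(8))
NO_BEHAVIOR: SignalState = STATE_SPACE[0]


@dataclass(frozen=True)
class SignalEvent:
    """A single coded behavior interval within a session."""

    dyad_id: str
    session_id: str
    modality: Modality
    behavior: str
    onset: float
    offset: float

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise ValueError(
                f"event offset must exceed onset (got [{self.onset}, {self.offset}))"
            )
        if self.onset < 0:
            raise ValueError(f"event onset must be >= 0, got {self.onset}")


@dataclass
class SessionRecord:
    """One coded interaction session: a dyad at one age point."""

    dyad_id: str
    age_point: str
    duration: float
    events: list[SignalEvent] = field(default_factory=list)
    session_id: str = ""

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError(f"session duration must be > 0, got {self.duration}")
        self.events = sorted(self.events, key=lambda e: (e.onset, e.offset))
        for ev in self.events:
            if ev.offset > self.duration + 1e-9:
                raise ValueError(
                    f"event [{ev.onset}, {ev.offset}) extends past session "
                    f"duration {self.duration}"
                )


@dataclass(frozen=True)
class TimelineSegment:
    start: float
    end: float
    state: SignalState


@dataclass
class StateSequence:
    """Ordered distinct-state sequence with consecutive duplicates collapsed."""

    indices: np.ndarray           # int state indices, no two consecutive equal
    dwell_times: np.ndarray       # seconds spent in each visited state

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.dwell_times = np.asarray(self.dwell_times, dtype=float)
        if self.indices.shape != self.dwell_times.shape:
            raise ValueError("indices and dwell_times must have equal length")
        if self.indices.size and np.any(np.diff(self.indices) == 0):
            raise ValueError("consecutive duplicate states are not allowed")
        if self.indices.size and (self.indices.min() < 0 or self.indices.max() > 7):
            raise ValueError("state indices must lie in 0..7")

    @property
    def states(self) -> list[SignalState]:
        return [SignalState.from_index(i) for i in self.indices]

    @property
    def n_transitions(self) -> int:
        return max(len(self.indices) - 1, 0)

    @classmethod
    def from_indices(cls, indices, dwell_times=None, collapse: bool = False) -> "StateSequence":
        indices = np.asarray(indices, dtype=int)
        if dwell_times is None:
            dwell_times = np.ones_like(indices, dtype=float)
        dwell_times = np.asarray(dwell_times, dtype=float)
        if collapse:
            indices, dwell_times = _collapse_runs(indices, dwell_times)
        return cls(indices, dwell_times)


class LogFormatError(ValueError):
    """The log file is structurally unusable (e.g. a required column is missing)."""


class LogValidationError(ValueError):
    """One or more rows violate the event contract; carries (line, message) pairs."""

    def __init__(self, rows: list[tuple[int, str]]):
        self.rows = rows
        detail = "; ".join(f"line {ln}: {msg}" for ln, msg in rows[:20])
        more = "" if len(rows) <= 20 else f" (+{len(rows) - 20} more)"
        super().__init__(f"{len(rows)} invalid row(s): {detail}{more}")


@dataclass
class LogDialect:
    """Column names and code mapping for a delimited event log.

    ``delimiter=None`` sniffs comma vs. tab from the header line.  ``duration``
    fixes the session length in seconds; if ``None`` each session's duration
    is taken as the largest event offset.  In ``strict`` mode an unknown
    behavior code is an error; otherwise the row is skipped with a warning.
    """

    dyad: str = "dyad"
    session: str = "session"
    behavior: str = "behavior"
    onset: str = "onset"
    offset: str = "offset"
    age_point: str = "age_point"   # optional column; absent -> "" on the record
    delimiter: str | None = None
    behavior_map: dict[str, Modality] = field(
        default_factory=lambda: dict(DEFAULT_BEHAVIOR_MAP)
    )
    duration: float | None = None
    strict: bool = False


def read_session_log(path, dialect: LogDialect | None = None) -> list[SessionRecord]:
    """Parse a delimited event log into validated :class:`SessionRecord` objects.

    Rows are validated in bulk; every malformed row (non-numeric time,
    offset <= onset, negative onset, unknown behavior in strict mode) is
    reported with its 1-based file line number in a single
    :class:`LogValidationError`.
    """
    dialect = dialect or LogDialect()
    if dialect.delimiter is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    else:
        sep = dialect.delimiter
    df = pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]

    required = [dialect.dyad, dialect.session, dialect.behavior, dialect.onset, dialect.offset]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise LogFormatError(f"missing required column(s): {', '.join(missing)}")
    has_age = dialect.age_point in df.columns

    bad: list[tuple[int, str]] = []
    events_by_session: dict[tuple[str, str], list[SignalEvent]] = {}
    age_by_session: dict[tuple[str, str], str] = {}
    order: list[tuple[str, str]] = []

    for pos, row in enumerate(df.itertuples(index=False)):
        line_no = pos + 2  # 1-based, after the header line
        rec = dict(zip(df.columns, row))
        try:
            onset = float(rec[dialect.onset])
            offset = float(rec[dialect.offset])
        except (TypeError, ValueError):
            bad.append((line_no, "non-numeric onset/offset"))
            continue
        if not offset > onset:
            bad.append((line_no, f"offset {offset} <= onset {onset}"))
            continue
        if onset < 0:
            bad.append((line_no, f"negative onset {onset}"))
            continue
        behavior = str(rec[dialect.behavior]).strip()
        modality = dialect.behavior_map.get(behavior)
        if modality is None:
            if dialect.strict:
                bad.append((line_no, f"unknown behavior code {behavior!r}"))
            else:
                warnings.warn(
                    f"line {line_no}: skipping unknown behavior code {behavior!r}",
                    stacklevel=2,
                )
            continue
        key = (str(rec[dialect.dyad]).strip(), str(rec[dialect.session]).strip())
        if key not in events_by_session:
            events_by_session[key] = []
            order.append(key)
            age_by_session[key] = str(rec[dialect.age_point]).strip() if has_age else ""
        events_by_session[key].append(
            SignalEvent(key[0], key[1], modality, behavior, onset, offset)
        )

    if bad:
        raise LogValidationError(bad)

    sessions = []
    for key in order:
        evs = events_by_session[key]
        duration = dialect.duration or max(e.offset for e in evs)
        sessions.append(
            SessionRecord(
                dyad_id=key[0],
                session_id=key[1],
                age_point=age_by_session[key],
                duration=duration,
                events=evs,
            )
        )
    return sessions


def build_state_timeline(
    session: SessionRecord,
    attention_mode: str = "conjunction",
    epsilon: float = 0.0,
) -> list[TimelineSegment]:
    """Sweep a session's event intervals into a piecewise-constant state timeline.

    At every instant the auditory (tactile) bit is on iff any auditory
    (touch/hold) event covers it.  The visual bit requires the mother to be
    manipulating an object; under ``attention_mode="conjunction"`` the child
    must simultaneously be attending, under ``"mother_only"`` manipulation
    alone suffices.  Change-points are the union of all onsets and offsets,
    so the number of segments is at most ``2 * n_events + 1``.

    Segments shorter than ``epsilon`` seconds are absorbed into the
    preceding segment (default 0: keep everything).
    """
    if attention_mode not in ("conjunction", "mother_only"):
        raise ValueError(f"unknown attention_mode {attention_mode!r}")

    cuts = {0.0, float(session.duration)}
    for ev in session.events:
        cuts.add(min(ev.onset, session.duration))
        cuts.add(min(ev.offset, session.duration))
    bounds = sorted(cuts)

    segments: list[TimelineSegment] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if not b > a:
            continue
        active = {m: False for m in Modality}
        for ev in session.events:
            if ev.onset <= a < ev.offset:
                active[ev.modality] = True
        aud = active[Modality.AUDITORY]
        tac = active[Modality.TACTILE]
        if attention_mode == "conjunction":
            vis = active[Modality.VISUAL_MOTHER] and active[Modality.VISUAL_CHILD_ATTEND]
        else:
            vis = active[Modality.VISUAL_MOTHER]
        segments.append(TimelineSegment(a, b, SignalState(aud, vis, tac)))

    if epsilon > 0:
        kept: list[TimelineSegment] = []
        for seg in segments:
            if seg.end - seg.start < epsilon and kept:
                prev = kept[-1]
                kept[-1] = TimelineSegment(prev.start, seg.end, prev.state)
            else:
                kept.append(seg)
        segments = kept
    return segments


def _collapse_runs(indices: np.ndarray, dwells: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if indices.size == 0:
        return indices, dwells
    keep = np.concatenate(([True], np.diff(indices) != 0))
    run_id = np.cumsum(keep) - 1
    out_idx = indices[keep]
    out_dwell = np.bincount(run_id, weights=dwells)
    return out_idx, out_dwell


def collapse_to_state_sequence(timeline: list[TimelineSegment]) -> StateSequence:
    """Merge consecutive identical states; dwell times accumulate across the merge."""
    if not timeline:
        return StateSequence(np.empty(0, dtype=int), np.empty(0))
    idx = np.array([seg.state.index for seg in timeline], dtype=int)
    dwell = np.array([seg.end - seg.start for seg in timeline], dtype=float)
    out_idx, out_dwell = _collapse_runs(idx, dwell)
    return StateSequence(out_idx, out_dwell)


def write_state_sequences(
    sequences: list[tuple[str, str, StateSequence]], path, sep: str = "\t"
) -> None:
    """Write ``(dyad, session, sequence)`` triples to the canonical delimited format."""
    rows = []
    for dyad, session, seq in sequences:
        for ordinal, (idx, dwell) in enumerate(zip(seq.indices, seq.dwell_times)):
            rows.append((dyad, session, ordinal, int(idx), float(dwell)))
    pd.DataFrame(
        rows, columns=["dyad", "session", "ordinal", "state_index", "dwell_s"]
    ).to_csv(path, sep=sep, index=False)


def read_state_sequences(path, sep: str = "\t") -> list[tuple[str, str, StateSequence]]:
    """Inverse of :func:`write_state_sequences`."""
    df = pd.read_csv(path, sep=sep)
    out = []
    for (dyad, session), grp in df.groupby(["dyad", "session"], sort=False):
        grp = grp.sort_values("ordinal")
        out.append(
            (
                str(dyad),
                str(session),
                StateSequence(grp["state_index"].to_numpy(), grp["dwell_s"].to_numpy()),
            )
        )
    return out
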