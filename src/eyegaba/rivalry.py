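"""Parsing of binocular-rivalry keypress streams into percept phases.

During binocular rivalry two incompatible images are shown, one to each eye,
and perception alternates between them.  Observers hold down one of three keys
to report the currently perceived grating: clockwise-tilted (``cw``),
counter-clockwise-tilted (``ccw``), or a piecemeal ``mixed`` percept; ``none``
means no key is held.  Which eye sees the clockwise grating is randomised per
run, so the run carries an eye<->orientation mapping that converts key states
into eye labels.

This module turns such an event stream into a sequence of labelled, contiguous
:class:`PerceptPhase` intervals and applies three preprocessing rules before
any duration statistics are computed:

(a) missing data immediately preceding a reported percept is assigned to that
    subsequent percept (the observer was already perceiving it but had not yet
    pressed the key);
(b) eye-percept responses shorter than ``min_duration`` (default 200 ms) are
    removed as key bounces / motor slips — if the two flanking phases share a
    label they merge into one continuous phase, otherwise the vacated interval
    is treated as missing and assigned to the subsequent percept per rule (a);
(c) mixed percepts and residual missing time are excluded from the eye-phase
    output, but their total durations are retained in an accounting record
    because the perceptual-suppression ratio and the mixed-fraction participant
    screen need them.

Rules are applied in the order (a), (b), (c).  Adjacent phases with the same
label are always coalesced: a re-press of the same key, or a key release inside
one percept, is a single continuous phase.  Intervals are half-open
``[onset, offset)`` in seconds from run onset; the final interval of a run is
right-censored by the run end and flagged as such.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .exceptions import EmptySampleError, MalformedInputError, ParameterError

#: key states accepted in raw streams
STATES = ("cw", "ccw", "mixed", "none")

#: phase labels
LEFT_EYE = "left_eye"
RIGHT_EYE = "right_eye"
MIXED = "mixed"
MISSING = "missing"
EYE_LABELS = (LEFT_EYE, RIGHT_EYE)


@dataclass(frozen=True)
class KeypressEvent:
    """A key-state change at ``time`` seconds from run onset.

    The state holds from ``time`` until the next event (or the run end).
    """

    time: float
    state: str


@dataclass(frozen=True)
class RivalryRun:
    """One rivalry run: an event stream plus its eye<->orientation mapping.

    Parameters
    ----------
    events : sequence of KeypressEvent, strictly ascending in time
    duration : run length in seconds
    cw_eye : ``"left"`` or ``"right"`` — the eye that saw the clockwise grating
    """

    events: tuple
    duration: float
    cw_eye: str
    subject_id: str = "unknown"
    run_id: str | int = 0

    def __post_init__(self):
        object.__setattr__(self, "events", tuple(self.events))
        if not self.duration > 0:
            raise ParameterError(f"run duration must be positive, got {self.duration}")
        if self.cw_eye not in ("left", "right"):
            raise ParameterError(f"cw_eye must be 'left' or 'right', got {self.cw_eye!r}")


@dataclass(frozen=True)
class PerceptPhase:
    """A contiguous percept interval ``[onset, offset)`` with an eye/mixed/missing
    label; the unit of all rivalry statistics."""

    onset: float
    offset: float
    label: str
    censored: bool = False

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class PhaseAccounting:
    """Bookkeeping of where every second of a preprocessed run went."""

    run_duration: float
    leading_missing_time: float  # initial missing stretch: time before the first
    # informative report (no keypress yet, or an explicit 'none'); merged into
    # the first reported percept by rule (a) when one exists
    kept_eye_time: float
    mixed_time: float
    residual_missing_time: float
    removed_short_count: int
    removed_short_time: float  # raw durations of deleted <min_duration responses
    # (their interval is re-absorbed by neighbours, so it is informational)


@dataclass(frozen=True)
class PreprocessedPhases:
    """Eye phases surviving preprocessing, plus the accounting record."""

    phases: tuple
    accounting: PhaseAccounting


def label_for_state(state: str, cw_eye: str) -> str:
    """Map a key state to a phase label under the run's eye mapping."""
    if state == "cw":
        return LEFT_EYE if cw_eye == "left" else RIGHT_EYE
    if state == "ccw":
        return RIGHT_EYE if cw_eye == "left" else LEFT_EYE
    if state == "mixed":
        return MIXED
    if state == "none":
        return MISSING
    raise MalformedInputError(f"unknown key state {state!r}")


def _coalesce(phases: list) -> list:
    """Merge adjacent phases sharing a label; merged phase inherits the last
    component's censored flag."""
    out: list[PerceptPhase] = []
    for ph in phases:
        if out and out[-1].label == ph.label and abs(out[-1].offset - ph.onset) < 1e-12:
            out[-1] = PerceptPhase(out[-1].onset, ph.offset, ph.label, ph.censored)
        else:
            out.append(ph)
    return out


def segment_stream(run: RivalryRun) -> list:
    """Segment an event stream into raw contiguous percept intervals.

    Returns phases covering ``[0, duration)``: time before the first event is
    labelled missing, each event's state holds until the next event, and the
    final interval (truncated by the run end) is flagged censored.  An empty
    event list yields an empty phase sequence.

    Raises
    ------
    MalformedInputError
        on unsorted or duplicate-time events, unknown states, or event times
        outside ``[0, duration)``.
    """
    events = run.events
    if len(events) == 0:
        return []
    times = [e.time for e in events]
    for t in times:
        if not 0 <= t < run.duration:
            raise MalformedInputError(
                f"event time {t} outside [0, {run.duration})"
            )
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise MalformedInputError("event times must be strictly ascending")
    labels = [label_for_state(e.state, run.cw_eye) for e in events]

    phases: list[PerceptPhase] = []
    if times[0] > 0:
        phases.append(PerceptPhase(0.0, times[0], MISSING))
    for i, lab in enumerate(labels):
        end = times[i + 1] if i + 1 < len(times) else run.duration
        phases.append(PerceptPhase(times[i], end, lab))
    phases = _coalesce(phases)
    last = phases[-1]
    phases[-1] = PerceptPhase(last.onset, last.offset, last.label, censored=True)
    return phases


def preprocess_phases(
    phases: Sequence, min_duration: float = 0.200
) -> PreprocessedPhases:
    """Apply the preprocessing rules (a)-(c) to raw segmented phases.

    See the module docstring for the rules.  The returned eye phases carry the
    final durations used for statistics; mixed and residual missing time are
    reported in the accounting record rather than as phases.

    Raises
    ------
    ParameterError
        if ``min_duration`` is negative.
    """
    if min_duration < 0:
        raise ParameterError(f"min_duration must be >= 0, got {min_duration}")
    if len(phases) == 0:
        acc = PhaseAccounting(0.0, 0.0, 0.0, 0.0, 0.0, 0, 0.0)
        return PreprocessedPhases((), acc)

    run_duration = phases[-1].offset
    leading_missing = phases[0].duration if phases[0].label == MISSING else 0.0

    # rule (a): fold each missing stretch into the subsequent labelled phase
    work: list[PerceptPhase] = []
    pending_start: float | None = None
    for ph in phases:
        if ph.label == MISSING:
            if pending_start is None:
                pending_start = ph.onset
            pending_censored = ph.censored
            continue
        onset = pending_start if pending_start is not None else ph.onset
        work.append(PerceptPhase(onset, ph.offset, ph.label, ph.censored))
        pending_start = None
    if pending_start is not None:  # trailing missing has no subsequent percept
        work.append(
            PerceptPhase(pending_start, run_duration, MISSING, pending_censored)
        )
    work = _coalesce(work)

    # rule (b): delete sub-threshold eye responses, earliest first
    removed_n = 0
    removed_t = 0.0
    while True:
        idx = next(
            (
                i
                for i, ph in enumerate(work)
                if ph.label in EYE_LABELS and ph.duration < min_duration
            ),
            None,
        )
        if idx is None:
            break
        victim = work[idx]
        removed_n += 1
        removed_t += victim.duration
        prev = work[idx - 1] if idx > 0 else None
        nxt = work[idx + 1] if idx + 1 < len(work) else None
        if prev is not None and nxt is not None and prev.label == nxt.label:
            merged = PerceptPhase(prev.onset, nxt.offset, nxt.label, nxt.censored)
            work[idx - 1 : idx + 2] = [merged]
        elif nxt is not None:
            work[idx : idx + 2] = [
                PerceptPhase(victim.onset, nxt.offset, nxt.label, nxt.censored)
            ]
        else:
            # final phase: vacated interval becomes residual missing
            work[idx] = PerceptPhase(
                victim.onset, victim.offset, MISSING, victim.censored
            )
            work = _coalesce(work)

    # rule (c): split eye phases from mixed/missing accounting
    kept = tuple(ph for ph in work if ph.label in EYE_LABELS)
    mixed_time = sum(ph.duration for ph in work if ph.label == MIXED)
    missing_time = sum(ph.duration for ph in work if ph.label == MISSING)
    acc = PhaseAccounting(
        run_duration=run_duration,
        leading_missing_time=leading_missing,
        kept_eye_time=sum(ph.duration for ph in kept),
        mixed_time=mixed_time,
        residual_missing_time=missing_time,
        removed_short_count=removed_n,
        removed_short_time=removed_t,
    )
    return PreprocessedPhases(kept, acc)


def preprocess_run(run: RivalryRun, min_duration: float = 0.200) -> PreprocessedPhases:
    """Convenience: ``preprocess_phases(segment_stream(run))``."""
    return preprocess_phases(segment_stream(run), min_duration=min_duration)


@dataclass(frozen=True)
class PooledDurations:
    """Per-eye duration samples pooled across one subject's runs."""

    left: np.ndarray
    right: np.ndarray

    def sample(self, eye: str) -> np.ndarray:
        arr = self.left if eye == "left" else self.right
        if arr.size == 0:
            raise EmptySampleError(f"no surviving phases for the {eye} eye")
        return arr


def pool_durations(
    preprocessed: Iterable, include_censored: bool = False
) -> PooledDurations:
    """Concatenate surviving eye-phase durations across a subject's runs.

    Censored (run-end truncated) phases are excluded by default because a
    truncated duration biases the median downward; pass
    ``include_censored=True`` to keep them.
    """
    left: list[float] = []
    right: list[float] = []
    for pp in preprocessed:
        for ph in pp.phases:
            if ph.censored and not include_censored:
                continue
            (left if ph.label == LEFT_EYE else right).append(ph.duration)
    return PooledDurations(np.asarray(left, dtype=float), np.asarray(right, dtype=float))


def normalize_pooled_durations(durations, d_de: float) -> np.ndarray:
    """Durations divided by the dominant-eye median ``d_de``, for pooled
    histogram reporting (the dominant-eye sample then has median 1)."""
    if not d_de > 0:
        raise ParameterError(f"d_de must be positive, got {d_de}")
    return np.asarray(durations, dtype=float) / d_de
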