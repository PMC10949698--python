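"""Session engine: phase state machine, event log, discontinuation rule.

A session walks each level through a fixed phase order —

    presentation -> immediate_recall -> distraction -> delayed_recall
    -> counter_selection -> service -> level_end

— and at ``level_end`` applies the discontinuation rule: the session
stops early when a level's accuracy falls strictly below the threshold
(default 50%) on **all four** metrics (immediate recall, delayed recall,
recognition, and serving, where serving requires table and customer both
correct).  Otherwise play continues to the next level, or the session
ends after the last one.

Every transition emits a timestamped :class:`SessionEvent`; simulated
sessions advance a deterministic clock by fixed per-phase durations, so
replaying identical inputs yields an identical log.
"""

from __future__ import annotations

import enum
import time
from dataclasses import dataclass, field, replace
from typing import Any, Mapping, Optional, Sequence

from .errors import (
    IncompleteInputError,
    ProtocolOrderError,
    ResponseReferenceError,
)
from .protocol import LevelScript, SessionScript

__all__ = [
    "Phase",
    "ResponseSet",
    "SessionEvent",
    "SessionOutcome",
    "SessionLog",
    "SessionState",
    "SimulatedClock",
    "WallClock",
    "start_session",
    "submit_phase",
    "finalize_level",
    "run_scripted_session",
]


class Phase(str, enum.Enum):
    PRESENTATION = "presentation"
    IMMEDIATE_RECALL = "immediate_recall"
    DISTRACTION = "distraction"
    DELAYED_RECALL = "delayed_recall"
    COUNTER_SELECTION = "counter_selection"
    SERVICE = "service"
    LEVEL_END = "level_end"
    SESSION_END = "session_end"


#: legal within-level order; LEVEL_END loops to the next level's PRESENTATION
PHASE_ORDER = (
    Phase.PRESENTATION,
    Phase.IMMEDIATE_RECALL,
    Phase.DISTRACTION,
    Phase.DELAYED_RECALL,
    Phase.COUNTER_SELECTION,
    Phase.SERVICE,
    Phase.LEVEL_END,
)

#: phases whose submissions carry scoreable responses
RESPONSE_PHASES = (
    Phase.IMMEDIATE_RECALL,
    Phase.DELAYED_RECALL,
    Phase.COUNTER_SELECTION,
    Phase.SERVICE,
)


@dataclass(frozen=True)
class ResponseSet:
    """What a respondent did in each scored phase of one level.

    A phase counts as *attempted* when at least one response was
    submitted in it; un-attempted phases score zero.
    """

    level: int
    immediate_recall: tuple[str, ...] = ()
    delayed_recall: tuple[str, ...] = ()
    counter_selection: tuple[str, ...] = ()
    service: Mapping[str, tuple[int, int]] = field(default_factory=dict)

    def attempted(self, phase: Phase) -> bool:
        return len(self.payload_for(phase)) > 0

    def payload_for(self, phase: Phase):
        if phase is Phase.IMMEDIATE_RECALL:
            return self.immediate_recall
        if phase is Phase.DELAYED_RECALL:
            return self.delayed_recall
        if phase is Phase.COUNTER_SELECTION:
            return self.counter_selection
        if phase is Phase.SERVICE:
            return self.service
        raise ValueError(f"{phase} carries no responses")

    @classmethod
    def empty(cls, level: int) -> "ResponseSet":
        return cls(level=level)

    @classmethod
    def perfect(cls, level_script: LevelScript) -> "ResponseSet":
        """Fully correct responses for a level's ground truth."""
        items = level_script.ordered_item_ids
        return cls(
            level=level_script.level,
            immediate_recall=items,
            delayed_recall=items,
            counter_selection=items,
            service={i: level_script.seat_of(i) for i in items},
        )


@dataclass(frozen=True)
class SessionEvent:
    timestamp: float  # seconds since session start
    phase: Phase
    level: int
    payload: Any = None


@dataclass(frozen=True)
class SessionOutcome:
    status: str  # "completed" | "discontinued"
    discontinued_at: Optional[int] = None

    @property
    def completed(self) -> bool:
        return self.status == "completed"


@dataclass(frozen=True)
class SessionLog:
    """Immutable record of one played session."""

    script_seed: int
    protocol_hash: str
    events: tuple[SessionEvent, ...]
    responses: Mapping[int, ResponseSet]
    outcome: SessionOutcome

    @property
    def levels_played(self) -> int:
        return max(ev.level for ev in self.events if ev.level > 0)


class SimulatedClock:
    """Deterministic clock advancing by fixed per-phase durations.

    Timing is recorded but never scored, so the defaults only need to be
    plausible: presentation 10 s per table, each recall phase 30 s,
    distraction per the level config (default 120 s), counter and
    service 30 s each.
    """

    RECALL_SECONDS = 30.0
    PRESENTATION_SECONDS_PER_TABLE = 10.0
    COUNTER_SECONDS = 30.0
    SERVICE_SECONDS = 30.0

    def __init__(self) -> None:
        self._t = 0.0

    def now(self) -> float:
        return self._t

    def advance_for(self, phase: Phase, level_script: LevelScript) -> None:
        cfg = level_script.config
        dt = {
            Phase.PRESENTATION: self.PRESENTATION_SECONDS_PER_TABLE * cfg.n_tables,
            Phase.IMMEDIATE_RECALL: self.RECALL_SECONDS,
            Phase.DISTRACTION: cfg.distraction_seconds,
            Phase.DELAYED_RECALL: self.RECALL_SECONDS,
            Phase.COUNTER_SELECTION: self.COUNTER_SECONDS,
            Phase.SERVICE: self.SERVICE_SECONDS,
        }.get(phase, 0.0)
        self._t += dt


class WallClock:
    """Real-time clock for interactive play; log format is identical."""

    def __init__(self) -> None:
        self._t0 = time.monotonic()

    def now(self) -> float:
        return time.monotonic() - self._t0

    def advance_for(self, phase: Phase, level_script: LevelScript) -> None:
        pass  # real time passes on its own


@dataclass
class SessionState:
    """Mutable in-flight session."""

    script: SessionScript
    clock: SimulatedClock | WallClock
    current_level: int = 1
    phase_index: int = 0  # index into PHASE_ORDER
    events: list[SessionEvent] = field(default_factory=list)
    responses: dict[int, dict[Phase, Any]] = field(default_factory=dict)
    outcome: Optional[SessionOutcome] = None

    @property
    def current_phase(self) -> Phase:
        if self.outcome is not None:
            return Phase.SESSION_END
        return PHASE_ORDER[self.phase_index]

    @property
    def level_script(self) -> LevelScript:
        return self.script.level(self.current_level)

    def _emit(self, phase: Phase, payload: Any = None, level: Optional[int] = None) -> None:
        self.events.append(
            SessionEvent(
                timestamp=self.clock.now(),
                phase=phase,
                level=self.current_level if level is None else level,
                payload=payload,
            )
        )

    def response_set(self, level: int) -> ResponseSet:
        stored = self.responses.get(level, {})
        return ResponseSet(
            level=level,
            immediate_recall=tuple(stored.get(Phase.IMMEDIATE_RECALL, ())),
            delayed_recall=tuple(stored.get(Phase.DELAYED_RECALL, ())),
            counter_selection=tuple(stored.get(Phase.COUNTER_SELECTION, ())),
            service=dict(stored.get(Phase.SERVICE, {})),
        )


def start_session(
    script: SessionScript, clock: Optional[SimulatedClock | WallClock] = None
) -> SessionState:
    """Open a session at level 1 presentation and emit the start event."""
    state = SessionState(script=script, clock=clock or SimulatedClock())
    state._emit(Phase.PRESENTATION)
    return state


def _validate_payload(state: SessionState, phase: Phase, payload: Any) -> Any:
    lvl = state.level_script
    if phase in (Phase.IMMEDIATE_RECALL, Phase.DELAYED_RECALL):
        return tuple(str(i) for i in payload)
    if phase is Phase.COUNTER_SELECTION:
        picks = tuple(str(i) for i in payload)
        unknown = set(picks) - set(lvl.counter_lineup)
        if unknown:
            raise ResponseReferenceError(
                f"counter selection refers to items not in the level "
                f"{lvl.level} lineup: {sorted(unknown)}"
            )
        return picks
    if phase is Phase.SERVICE:
        picks = set(state.responses.get(lvl.level, {}).get(Phase.COUNTER_SELECTION, ()))
        service: dict[str, tuple[int, int]] = {}
        for item_id, seat in dict(payload).items():
            if item_id not in picks:
                raise ResponseReferenceError(
                    f"cannot serve {item_id!r}: it was not selected at the counter"
                )
            t, c = int(seat[0]), int(seat[1])
            if not (1 <= t <= lvl.config.n_tables and 1 <= c <= lvl.config.customers_per_table):
                raise ResponseReferenceError(
                    f"service destination ({t}, {c}) outside the level "
                    f"{lvl.level} table layout"
                )
            service[str(item_id)] = (t, c)
        return service
    return payload  # presentation / distraction payloads are free-form


def submit_phase(state: SessionState, phase: Phase, payload: Any = None) -> SessionState:
    """Record a phase's payload and advance to the next phase.

    The submitted phase must equal the state's current expected phase;
    anything else raises :class:`ProtocolOrderError`.
    """
    expected = state.current_phase
    if phase is not expected or phase in (Phase.LEVEL_END, Phase.SESSION_END):
        raise ProtocolOrderError(
            f"expected phase {expected.value!r} at level {state.current_level}, "
            f"got {getattr(phase, 'value', phase)!r}"
        )
    clean = _validate_payload(state, phase, payload if payload is not None else ())
    if phase in RESPONSE_PHASES:
        state.responses.setdefault(state.current_level, {})[phase] = clean
    state.clock.advance_for(phase, state.level_script)
    state._emit(phase, payload=clean)
    state.phase_index += 1
    return state


def finalize_level(state: SessionState):
    """Close the current level and apply the discontinuation rule.

    Returns ``(level_score, decision)`` where decision is ``"continue"``
    or ``"discontinue"``.  Discontinuation fires only when all four
    accuracies are strictly below the protocol threshold.
    """
    from .scoring import accuracies as _accuracies
    from .scoring import score_level

    if state.current_phase is not Phase.LEVEL_END:
        raise ProtocolOrderError(
            f"finalize_level called at phase {state.current_phase.value!r}; "
            "all phases of the level must be submitted first"
        )
    level = state.current_level
    level_score = score_level(state.level_script, state.response_set(level))
    accs = _accuracies(level_score)
    thr = state.script.protocol.discontinuation_threshold
    discontinue = all(a < thr for a in accs)
    decision = "discontinue" if discontinue else "continue"
    state._emit(Phase.LEVEL_END, payload={"accuracies": accs, "decision": decision})
    if discontinue:
        state.outcome = SessionOutcome("discontinued", discontinued_at=level)
        state._emit(Phase.SESSION_END, level=level)
    elif level >= state.script.protocol.n_levels:
        state.outcome = SessionOutcome("completed")
        state._emit(Phase.SESSION_END, level=level)
    else:
        state.current_level = level + 1
        state.phase_index = 0
    return level_score, decision


def _to_log(state: SessionState) -> SessionLog:
    played = sorted(state.responses)
    responses = {lvl: state.response_set(lvl) for lvl in played}
    return SessionLog(
        script_seed=state.script.seed,
        protocol_hash=state.script.protocol.config_hash(),
        events=tuple(state.events),
        responses=responses,
        outcome=state.outcome or SessionOutcome("completed"),
    )


def run_scripted_session(
    script: SessionScript,
    responses: Sequence[ResponseSet],
    clock: Optional[SimulatedClock | WallClock] = None,
) -> SessionLog:
    """Replay prepared per-level responses through the state machine.

    ``responses`` holds one :class:`ResponseSet` per level in order; it
    may be shorter than the protocol only if the discontinuation rule
    ends the session before the missing levels are reached.
    """
    if not responses:
        raise IncompleteInputError("responses must cover at least level 1")
    by_level = {rs.level: rs for rs in responses}
    state = start_session(script, clock=clock)
    while state.outcome is None:
        level = state.current_level
        rs = by_level.get(level)
        if rs is None:
            raise IncompleteInputError(
                f"session continued into level {level} but no responses were provided"
            )
        submit_phase(state, Phase.PRESENTATION)
        submit_phase(state, Phase.IMMEDIATE_RECALL, rs.immediate_recall)
        submit_phase(state, Phase.DISTRACTION)
        submit_phase(state, Phase.DELAYED_RECALL, rs.delayed_recall)
        submit_phase(state, Phase.COUNTER_SELECTION, rs.counter_selection)
        submit_phase(state, Phase.SERVICE, rs.service)
        finalize_level(state)
    return _to_log(state)
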