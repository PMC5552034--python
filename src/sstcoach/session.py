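"""The five-step training session as an explicit state machine.

A session walks through instruction → modeling → role-play → feedback →
homework → done.  The role-play is a one-minute monologue ("please describe
something fun you did recently"); it ends only when the configured duration
elapses.  From the feedback step the user may repeat modeling and role-play
any number of times before homework is assigned.  The avatar, speech
recognition and synthesis are replaced by this transport-agnostic event
interface; the transition table is the testable contract.

``advance`` is a pure function of (state, event, config): it returns a new
state and never mutates its input.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable, Optional

__all__ = [
    "Step",
    "Event",
    "SessionState",
    "SessionConfig",
    "TransitionError",
    "EVENTS",
    "advance",
    "run_roleplay",
    "attach_report",
    "SimulatedClock",
    "write_session_log",
]


class Step(str, Enum):
    INSTRUCTION = "instruction"
    MODELING = "modeling"
    ROLEPLAY = "roleplay"
    FEEDBACK = "feedback"
    HOMEWORK = "homework"
    DONE = "done"


class Event(str, Enum):
    START = "start"
    USER_START_ROLEPLAY = "user_start_roleplay"
    ROLEPLAY_TIMEOUT = "roleplay_timeout"
    FEEDBACK_VIEWED = "feedback_viewed"
    REPEAT = "repeat"
    ASSIGN_HOMEWORK = "assign_homework"
    FINISH = "finish"


EVENTS = tuple(Event)


class TransitionError(RuntimeError):
    """An event was raised in a step where it is not allowed."""


@dataclass(frozen=True)
class SessionConfig:
    """Session parameters; the role-play lasts one minute by default."""

    roleplay_duration_s: float = 60.0
    prompts: tuple[str, ...] = (
        "Please describe something fun you did recently.",
    )
    allow_repeats: bool = True
    model_videos: tuple[str, ...] = ()
    nod_interval_s: float = 8.0
    homework_text: str = "Tell a story to others throughout the week."

    def __post_init__(self):
        if self.roleplay_duration_s <= 0:
            raise ValueError("roleplay_duration_s must be > 0")


@dataclass(frozen=True)
class SessionState:
    """Immutable snapshot of a session."""

    step: Step = Step.INSTRUCTION
    elapsed_in_step_s: float = 0.0
    artifacts: tuple[dict, ...] = ()  # recording metadata, report refs
    repeats: tuple[tuple[str, int], ...] = ()
    log: tuple[dict, ...] = ()
    homework: Optional[str] = None

    def repeat_count(self, step: Step) -> int:
        return dict(self.repeats).get(step.value, 0)

    @property
    def completed_roleplays(self) -> int:
        return sum(1 for a in self.artifacts if a.get("kind") == "roleplay_recording")

    @property
    def reports(self) -> tuple[dict, ...]:
        return tuple(a for a in self.artifacts if a.get("kind") == "feedback_report")


# transition table: (step, event) -> next step
_TRANSITIONS: dict[tuple[Step, Event], Step] = {
    (Step.INSTRUCTION, Event.START): Step.MODELING,
    (Step.MODELING, Event.USER_START_ROLEPLAY): Step.ROLEPLAY,
    (Step.ROLEPLAY, Event.ROLEPLAY_TIMEOUT): Step.FEEDBACK,
    (Step.FEEDBACK, Event.FEEDBACK_VIEWED): Step.FEEDBACK,
    (Step.FEEDBACK, Event.REPEAT): Step.MODELING,
    (Step.FEEDBACK, Event.ASSIGN_HOMEWORK): Step.HOMEWORK,
    (Step.HOMEWORK, Event.FINISH): Step.DONE,
}


def advance(
    state: SessionState, event: Event | str, config: SessionConfig | None = None
) -> SessionState:
    """Apply one event to the session; returns the successor state.

    Raises
    ------
    TransitionError
        If the event is not allowed in the current step (with an explanation
        of which events are).
    """
    config = config or SessionConfig()
    event = Event(event)
    key = (state.step, event)
    if key not in _TRANSITIONS:
        allowed = sorted(e.value for (s, e) in _TRANSITIONS if s == state.step)
        raise TransitionError(
            f"event {event.value!r} not allowed in step {state.step.value!r}; "
            f"allowed: {allowed or 'none (terminal)'}"
        )
    if event is Event.REPEAT and not config.allow_repeats:
        raise TransitionError("repeats are disabled by configuration")
    nxt = _TRANSITIONS[key]
    repeats = dict(state.repeats)
    if event is Event.REPEAT:
        repeats[nxt.value] = repeats.get(nxt.value, 0) + 1
    entry = {"step": state.step.value, "event": event.value, "next": nxt.value}
    homework = config.homework_text if event is Event.ASSIGN_HOMEWORK else state.homework
    return replace(
        state,
        step=nxt,
        elapsed_in_step_s=0.0,
        repeats=tuple(sorted(repeats.items())),
        log=state.log + (entry,),
        homework=homework,
    )


class SimulatedClock:
    """Deterministic clock for offline sessions; advances on demand."""

    def __init__(self, t0: float = 0.0):
        self.t = float(t0)

    def now(self) -> float:
        return self.t

    def sleep(self, dt: float) -> None:
        self.t += dt


def run_roleplay(
    state: SessionState,
    clock=None,
    landmarks_path: str | None = None,
    wav_path: str | None = None,
    config: SessionConfig | None = None,
    sink: Callable[[dict], None] | None = None,
) -> tuple[SessionState, dict]:
    """Run the role-play step over a (simulated) clock.

    Records start/stop timestamps spanning the configured duration, logs the
    avatar's nod events on the fixed schedule, and attaches the captured
    landmark-CSV and WAV paths for the extraction modules.  If the sink
    raises, the session state is preserved unchanged (failure atomicity).

    Returns the post-timeout state (in ``feedback``) and the recording
    metadata.
    """
    config = config or SessionConfig()
    if state.step is not Step.ROLEPLAY:
        raise TransitionError(f"run_roleplay requires step 'roleplay', got {state.step.value!r}")
    clock = clock or SimulatedClock()
    start = clock.now()
    nods = []
    t = config.nod_interval_s
    while t < config.roleplay_duration_s:
        nods.append(start + t)
        t += config.nod_interval_s
    clock.sleep(config.roleplay_duration_s)
    stop = clock.now()
    meta = {
        "kind": "roleplay_recording",
        "start_s": start,
        "stop_s": stop,
        "duration_s": stop - start,
        "landmarks_csv": landmarks_path,
        "wav": wav_path,
        "nod_times_s": nods,
    }
    if sink is not None:
        sink(meta)  # may raise: state untouched, no artifact recorded
    new_state = replace(state, artifacts=state.artifacts + (meta,))
    new_state = advance(new_state, Event.ROLEPLAY_TIMEOUT, config)
    return new_state, meta


def attach_report(state: SessionState, report_ref: dict) -> SessionState:
    """Record a feedback report; requires a completed role-play."""
    if state.completed_roleplays == 0:
        raise TransitionError("no completed role-play: cannot attach a feedback report")
    artifact = {"kind": "feedback_report", **report_ref}
    return replace(state, artifacts=state.artifacts + (artifact,))


def write_session_log(state: SessionState, path) -> None:
    """Serialize the event log as JSON lines (one event per line)."""
    with open(path, "w") as fh:
        for entry in state.log:
            fh.write(json.dumps({"timestamp": time.time(), **entry}) + "\n")
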