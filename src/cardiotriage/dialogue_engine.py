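"""Deterministic scripted chatbot and check-in scheduler.

The chatbot is a declarative finite-state machine loaded from a YAML/JSON
script: states carry prompt text, an expected-input schema, and transition
rules. There is no free-text understanding — input is matched against the
schema, and invalid input re-prompts without a state change. Message pacing
(per-message delays, tuned so longer prompts stay readable) is emitted as
metadata and never slept, so replays are instant and byte-identical.

The scheduler tracks when each recurring check-in was last completed:
heart checks fall due every 72 hours (or immediately on demand), wellness
checks every 168 hours. A simulated clock is injected everywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import yaml

from .core_model import ValidationError, format_timestamp, parse_timestamp

__all__ = [
    "ScriptError",
    "InputSpec",
    "DialogueNode",
    "DialogueScript",
    "SessionState",
    "BotMessage",
    "PacingConfig",
    "ScheduleState",
    "load_script",
    "load_bundled_script",
    "start_session",
    "step",
    "run_transcript",
    "next_due",
]

INPUT_TYPES = ("yes_no", "choice", "int", "text")
ACTIVITIES = ("heart_check", "wellness_check")


class ScriptError(ValueError):
    """Raised when a dialogue script violates a structural invariant."""


@dataclass(frozen=True)
class InputSpec:
    """Expected-input schema for one state."""

    type: str
    options: tuple[str, ...] = ()
    min: int | None = None
    max: int | None = None

    def __post_init__(self) -> None:
        if self.type not in INPUT_TYPES:
            raise ScriptError(f"unknown input type {self.type!r}")
        if self.type == "choice" and not self.options:
            raise ScriptError("choice input requires options")

    def normalize(self, raw: str) -> str | None:
        """Return the canonical transition token, or None if input invalid."""
        text = str(raw).strip().lower()
        if self.type == "yes_no":
            if text in ("yes", "y"):
                return "yes"
            if text in ("no", "n"):
                return "no"
            return None
        if self.type == "choice":
            token = text.replace(" ", "_").replace("-", "_")
            return token if token in self.options else None
        if self.type == "int":
            try:
                value = int(text)
            except ValueError:
                return None
            if self.min is not None and value < self.min:
                return None
            if self.max is not None and value > self.max:
                return None
            return str(value)
        return text if text else None  # free text


@dataclass(frozen=True)
class DialogueNode:
    state_id: str
    prompts: tuple[str, ...]
    input: InputSpec | None = None
    transitions: Mapping[str, str] = field(default_factory=dict)
    next: str | None = None  # auto-advance for statement states
    terminal: bool = False
    activity: str | None = None
    reprompt: str | None = None


@dataclass(frozen=True)
class DialogueScript:
    states: Mapping[str, DialogueNode]
    start_state: str
    terminal_states: frozenset[str]

    def node(self, state_id: str) -> DialogueNode:
        return self.states[state_id]


@dataclass(frozen=True)
class BotMessage:
    text: str
    delay_ms: int


@dataclass(frozen=True)
class PacingConfig:
    """Per-message pacing: delay = base + per_char * len(message)."""

    base_delay_ms: int = 600
    per_char_ms: int = 35

    def delay_for(self, text: str) -> int:
        return self.base_delay_ms + self.per_char_ms * len(text)


@dataclass(frozen=True)
class SessionState:
    current_state: str
    history: tuple[dict[str, Any], ...] = ()
    pending_activity: str | None = None
    clock: datetime | None = None


def _targets(node: DialogueNode) -> set[str]:
    out = set(node.transitions.values())
    if node.next is not None:
        out.add(node.next)
    return out


def _parse_node(state_id: str, raw: Mapping[str, Any]) -> DialogueNode:
    prompts_raw = raw.get("prompts", raw.get("prompt", []))
    if isinstance(prompts_raw, str):
        prompts_raw = [prompts_raw]
    input_spec = None
    if raw.get("input") is not None:
        spec = raw["input"]
        input_spec = InputSpec(
            type=spec.get("type", "text"),
            options=tuple(spec.get("options", ())),
            min=spec.get("min"),
            max=spec.get("max"),
        )
    activity = raw.get("activity")
    if activity is not None and activity not in ACTIVITIES:
        raise ScriptError(f"state {state_id!r}: unknown activity {activity!r}")
    transitions = {}
    for key, target in dict(raw.get("transitions", {})).items():
        if isinstance(key, bool):  # YAML parses bare yes/no as booleans
            key = "yes" if key else "no"
        transitions[str(key)] = str(target)
    return DialogueNode(
        state_id=state_id,
        prompts=tuple(str(p) for p in prompts_raw),
        input=input_spec,
        transitions=transitions,
        next=raw.get("next"),
        terminal=bool(raw.get("terminal", False)),
        activity=activity,
        reprompt=raw.get("reprompt"),
    )


def _check_coverage(node: DialogueNode) -> None:
    if node.terminal:
        if node.transitions or node.next:
            raise ScriptError(f"terminal state {node.state_id!r} declares transitions")
        return
    if node.input is None:
        if node.next is None:
            raise ScriptError(f"statement state {node.state_id!r} has no next state")
        return
    if node.next is not None:
        raise ScriptError(f"input state {node.state_id!r} may not use next")
    keys = set(node.transitions)
    if "*" in keys:
        return
    if node.input.type == "yes_no":
        missing = {"yes", "no"} - keys
    elif node.input.type == "choice":
        missing = set(node.input.options) - keys
    else:
        missing = {"*"}
    if missing:
        raise ScriptError(
            f"state {node.state_id!r}: transitions do not cover input(s) {sorted(missing)}"
        )


def _validate_graph(script: DialogueScript) -> None:
    states = script.states
    if script.start_state not in states:
        raise ScriptError(f"start state {script.start_state!r} does not exist")
    if not script.terminal_states:
        raise ScriptError("script has no terminal state")
    for node in states.values():
        for target in _targets(node):
            if target not in states:
                raise ScriptError(
                    f"state {node.state_id!r}: dangling transition to {target!r}"
                )
        _check_coverage(node)
    # forward reachability from start
    seen = {script.start_state}
    frontier = [script.start_state]
    while frontier:
        for target in _targets(states[frontier.pop()]):
            if target not in seen:
                seen.add(target)
                frontier.append(target)
    unreachable = set(states) - seen
    if unreachable:
        raise ScriptError(f"unreachable state(s): {sorted(unreachable)}")
    # liveness: every state can reach some terminal (backward search)
    alive = set(script.terminal_states)
    changed = True
    while changed:
        changed = False
        for node in states.values():
            if node.state_id not in alive and _targets(node) & alive:
                alive.add(node.state_id)
                changed = True
    dead = set(states) - alive
    if dead:
        raise ScriptError(f"no terminal state reachable from state(s): {sorted(dead)}")


def load_script(source: str | Path | Mapping[str, Any]) -> DialogueScript:
    """Load and validate a dialogue script from YAML/JSON or a mapping.

    Structural defects (missing start, dangling transition, unreachable
    state, state with no path to a terminal) raise :class:`ScriptError`
    naming the offending state.
    """
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = source
    if not isinstance(raw, Mapping) or "states" not in raw or "start" not in raw:
        raise ScriptError("script must define 'start' and 'states'")
    states = {
        str(sid): _parse_node(str(sid), node_raw) for sid, node_raw in raw["states"].items()
    }
    script = DialogueScript(
        states=states,
        start_state=str(raw["start"]),
        terminal_states=frozenset(s for s, n in states.items() if n.terminal),
    )
    _validate_graph(script)
    return script


def load_bundled_script(name: str = "scenarios") -> DialogueScript:
    """Load a script shipped with the package (default: the 5 test scenarios)."""
    text = resources.files("cardiotriage.data").joinpath(f"{name}.yaml").read_text()
    return load_script(yaml.safe_load(text))


def _emit_state(
    script: DialogueScript,
    session: SessionState,
    pacing: PacingConfig,
) -> tuple[SessionState, list[BotMessage]]:
    """Emit prompts for the current state, auto-advancing statement states."""
    messages: list[BotMessage] = []
    history = list(session.history)
    clock = session.clock
    pending = session.pending_activity
    state_id = session.current_state
    while True:
        node = script.node(state_id)
        if node.activity is not None:
            pending = node.activity
        for prompt in node.prompts:
            delay = pacing.delay_for(prompt)
            clock = clock + timedelta(milliseconds=delay) if clock else clock
            messages.append(BotMessage(text=prompt, delay_ms=delay))
            history.append(
                {
                    "at": format_timestamp(clock) if clock else None,
                    "speaker": "bot",
                    "message": prompt,
                    "delay_ms": delay,
                }
            )
        if node.terminal or node.next is None:
            break
        state_id = node.next
    return (
        SessionState(
            current_state=state_id,
            history=tuple(history),
            pending_activity=pending,
            clock=clock,
        ),
        messages,
    )


def start_session(
    script: DialogueScript,
    now: datetime | str,
    pacing: PacingConfig = PacingConfig(),
) -> tuple[SessionState, list[BotMessage]]:
    """Open a session at the script's start state and emit its prompts."""
    session = SessionState(current_state=script.start_state, clock=parse_timestamp(now))
    return _emit_state(script, session, pacing)


def step(
    script: DialogueScript,
    session: SessionState,
    user_input: str | None,
    now: datetime | str | None = None,
    pacing: PacingConfig = PacingConfig(),
) -> tuple[SessionState, list[BotMessage]]:
    """Advance the dialogue by one user input.

    Input failing the state's schema re-prompts without a state change.
    Stepping a terminal state is an error.
    """
    node = script.node(session.current_state)
    if node.terminal:
        raise ScriptError(f"cannot step terminal state {node.state_id!r}")
    clock = parse_timestamp(now) if now is not None else session.clock
    session = replace(session, clock=clock)
    if node.input is None:
        # statement states auto-advance; an explicit step just re-emits
        return _emit_state(script, session, pacing)
    if user_input is None:
        raise ScriptError(f"state {node.state_id!r} expects input")
    token = node.input.normalize(user_input)
    history = list(session.history)
    history.append(
        {
            "at": format_timestamp(clock) if clock else None,
            "speaker": "user",
            "message": str(user_input),
            "delay_ms": 0,
        }
    )
    if token is None:
        reprompt = node.reprompt or (
            "Sorry, I didn't catch that. " + (node.prompts[-1] if node.prompts else "")
        )
        delay = pacing.delay_for(reprompt)
        clock = clock + timedelta(milliseconds=delay) if clock else clock
        history.append(
            {
                "at": format_timestamp(clock) if clock else None,
                "speaker": "bot",
                "message": reprompt,
                "delay_ms": delay,
            }
        )
        return (
            replace(session, history=tuple(history), clock=clock),
            [BotMessage(text=reprompt, delay_ms=delay)],
        )
    target = node.transitions.get(token, node.transitions.get("*"))
    if target is None:
        raise ScriptError(
            f"state {node.state_id!r}: no transition for token {token!r}"
        )
    session = SessionState(
        current_state=target,
        history=tuple(history),
        pending_activity=session.pending_activity,
        clock=clock,
    )
    return _emit_state(script, session, pacing)


def run_transcript(
    script: DialogueScript,
    inputs: Sequence[str],
    start_at: datetime | str,
    pacing: PacingConfig = PacingConfig(),
) -> list[dict[str, Any]]:
    """Replay a fixed input sequence under a simulated clock.

    Returns the full transcript (JSON-serializable records with timestamp,
    speaker, message, delay_ms). Identical inputs and start time produce a
    byte-identical transcript.
    """
    session, _ = start_session(script, start_at, pacing)
    queue = list(inputs)
    while queue and session.current_state not in script.terminal_states:
        session, _ = step(script, session, queue.pop(0), pacing=pacing)
    return list(session.history)


def transcript_to_jsonl(transcript: Iterable[Mapping[str, Any]]) -> str:
    return "\n".join(json.dumps(rec, sort_keys=True) for rec in transcript)


@dataclass(frozen=True)
class ScheduleState:
    """Last-completed times and cadences for the recurring check-ins."""

    last_heart_check_at: datetime | None = None
    last_wellness_check_at: datetime | None = None
    heart_check_interval_hours: float = 72.0
    wellness_interval_hours: float = 168.0

    def __post_init__(self) -> None:
        if self.heart_check_interval_hours <= 0 or self.wellness_interval_hours <= 0:
            raise ValidationError("check-in intervals must be positive")


def next_due(
    schedule: ScheduleState,
    now: datetime | str,
    on_demand: str | None = None,
) -> frozenset[str]:
    """Which check-ins are due at ``now``.

    A heart check is due when never completed, when its interval has fully
    elapsed, or immediately when requested on demand. A wellness check is
    due when never completed or when its interval has elapsed.
    """
    if on_demand not in (None, "heart_check"):
        raise ValidationError(f"unknown on-demand activity {on_demand!r}")
    now = parse_timestamp(now)
    due: set[str] = set()
    hc_last = schedule.last_heart_check_at
    if (
        on_demand == "heart_check"
        or hc_last is None
        or (now - hc_last).total_seconds() >= schedule.heart_check_interval_hours * 3600
    ):
        due.add("heart_check")
    wc_last = schedule.last_wellness_check_at
    if wc_last is None or (
        (now - wc_last).total_seconds() >= schedule.wellness_interval_hours * 3600
    ):
        due.add("wellness_check")
    return frozenset(due)
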