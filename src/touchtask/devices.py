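"""Device interface: input sources, simulated actuators, sync-pulse stub.

The engine pulls :class:`~touchtask.core.TouchEvent`s from an
:class:`InputDevice` one at a time, bounded by the end of the current
trial phase. Before scanning each phase the runner publishes a
:class:`PhaseContext` via ``set_context`` so that closed-loop sources
(the synthetic agent) can react to what is on the screen; passive
sources (a recorded script, a real touchscreen driver) ignore it.

Output devices receive commands with timestamps and log every actuation
together with its trigger, so a session record can be audited for
orphan rewards. Real hardware drivers are drop-in replacements for the
simulators here — the contracts carry no simulation-specific state.
"""

from __future__ import annotations

import platform
from dataclasses import dataclass, field
from typing import Optional

from pydantic import BaseModel, Field

from .core import TouchEvent


@dataclass
class PhaseContext:
    """What the subject currently sees: phase, its window, and regions."""

    phase: str  # "iti" | "stimulus" | "reward_delay"
    start: float
    end: float
    region_map: Optional[object] = None  # protocols.RegionMap
    plan: Optional[object] = None  # protocols.TrialPlan


class InputDevice:
    """Pull-based source of time-ordered touch events."""

    identity: str = "input"

    def descriptor(self) -> dict:
        return {"identity": self.identity, "class": type(self).__name__}

    def set_context(self, ctx: PhaseContext) -> None:  # noqa: B027
        """Phase notification; passive sources ignore it."""

    def next_event(self, limit: float) -> Optional[TouchEvent]:
        """Return (and consume) the next event with t < limit, else None."""
        raise NotImplementedError


class ScriptedTouchSource(InputDevice):
    """Replays a pre-written, time-ordered event script (test double for
    the touchscreen). Exhaustion yields silence."""

    identity = "scripted_touchscreen"

    def __init__(self, script: list[TouchEvent]):
        for a, b in zip(script, script[1:]):
            if b.t < a.t:
                raise ValueError(
                    f"script events must be non-decreasing in t: {b.t} < {a.t}"
                )
        self._script = list(script)
        self._cursor = 0

    def next_event(self, limit: float) -> Optional[TouchEvent]:
        if self._cursor < len(self._script) and self._script[self._cursor].t < limit:
            ev = self._script[self._cursor]
            self._cursor += 1
            return ev
        return None


def scripted_touch_source(script: list[TouchEvent]) -> ScriptedTouchSource:
    """Build a replay input device from a time-ordered event list."""
    return ScriptedTouchSource(script)


class RewardActuation(BaseModel):
    """One reward dispensation: time, volume, spout-retraction time."""

    t: float
    volume_ul: float = Field(gt=0.0)
    retract_at: float
    trigger: str = "on_correct"


class OutputDevice:
    """Actuator contract: accepts a command + timestamp, logs an ack."""

    identity: str = "output"

    def descriptor(self) -> dict:
        return {"identity": self.identity, "class": type(self).__name__,
                "log": self.log_entries()}

    def actuate(self, t: float, trigger: str) -> dict:
        raise NotImplementedError

    def log_entries(self) -> list:
        return []


class SimRewardDispenser(OutputDevice):
    """Simulated solenoid reward dispenser.

    Dispenses a fixed volume per actuation and logs a spout retraction
    ``retract_after_s`` later (log-only; retraction never gates touch
    classification). Cumulative dispensed volume is queryable.
    """

    identity = "sim_reward_dispenser"

    def __init__(self, volume_ul: float = 10.0, retract_after_s: float = 1.0):
        if volume_ul <= 0:
            raise ValueError(f"reward volume must be > 0, got {volume_ul}")
        self.volume_ul = volume_ul
        self.retract_after_s = retract_after_s
        self.actuations: list[RewardActuation] = []

    def actuate(self, t: float, trigger: str = "on_correct") -> dict:
        act = RewardActuation(
            t=t, volume_ul=self.volume_ul,
            retract_at=t + self.retract_after_s, trigger=trigger,
        )
        self.actuations.append(act)
        return {"ack": True, "t": t, "volume_ul": self.volume_ul}

    @property
    def cumulative_ul(self) -> float:
        return sum(a.volume_ul for a in self.actuations)

    def log_entries(self) -> list:
        return [a.model_dump() for a in self.actuations]


def sim_reward_dispenser(volume_ul: float = 10.0, retract_after_s: float = 1.0) -> SimRewardDispenser:
    return SimRewardDispenser(volume_ul, retract_after_s)


class SyncPulseStub(OutputDevice):
    """Stand-in for a GPIO synchronization line: records pulse timestamps
    into the device log, no hardware side effect.

    ``schedule`` selects which session hooks fire a pulse; explicit
    ``pulse`` calls are also allowed.
    """

    identity = "sync_pulse_stub"

    def __init__(self, schedule: tuple[str, ...] = ("session_start", "trial_start")):
        self.schedule = tuple(schedule)
        self.pulses: list[dict] = []

    def actuate(self, t: float, trigger: str) -> dict:
        if trigger in self.schedule:
            self.pulses.append({"t": t, "trigger": trigger})
        return {"ack": True, "t": t}

    def pulse(self, t: float, label: str = "manual") -> None:
        self.pulses.append({"t": t, "trigger": label})

    def log_entries(self) -> list:
        return list(self.pulses)


def sync_pulse_stub(schedule: tuple[str, ...] = ("session_start", "trial_start")) -> SyncPulseStub:
    return SyncPulseStub(schedule)


def host_descriptor() -> dict:
    """Describe the host machine for session metadata."""
    return {
        "platform": platform.platform(),
        "python": platform.python_version(),
        "machine": platform.machine(),
        "node": platform.node(),
    }
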