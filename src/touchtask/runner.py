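"""Session engine: clocks, the run loop, live snapshots, resilience.

The engine is headless and pull-based. In ``accelerated`` mode the
clock jumps straight to the next scheduled event, so a 30-minute
session completes in milliseconds; ``realtime`` mode sleeps instead,
which is what an actual rig would run. Both produce identical records
for the same seed and input, because all behavioural timing is derived
from event timestamps, never from wall-clock reads.

Live analytics are a *pull* interface: :func:`snapshot` is a pure
function of the partial trial log, so any number of consumers (the
status API, a polling dashboard) can attach or detach without
perturbing the session.
"""

from __future__ import annotations

import time
import uuid
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable, Optional, Sequence

from pydantic import BaseModel

from .core import ProtocolConfig, ScreenGeometry, SessionRecord, TrialOutcome, TrialRecord
from .devices import InputDevice, OutputDevice, SyncPulseStub, host_descriptor
from .protocols import OutcomeHooks, run_protocol


class ClockError(RuntimeError):
    pass


class SessionClock:
    """Monotone session clock; ``now`` is seconds since session start."""

    mode = "abstract"

    @property
    def now(self) -> float:
        raise NotImplementedError

    def advance_to(self, t: float) -> None:
        raise NotImplementedError


class AcceleratedClock(SessionClock):
    """Jumps instantly to the next scheduled time (the default for tests
    and simulation)."""

    mode = "accelerated"

    def __init__(self, start: float = 0.0):
        self._now = float(start)

    @property
    def now(self) -> float:
        return self._now

    def advance_to(self, t: float) -> None:
        if t < self._now - 1e-12:
            raise ClockError(f"clock regression: {t} < {self._now}")
        self._now = max(self._now, float(t))


class RealtimeClock(SessionClock):
    """Wall-clock pacing: ``advance_to`` sleeps until the target time."""

    mode = "realtime"

    def __init__(self) -> None:
        self._t0 = time.monotonic()
        self._now = 0.0

    @property
    def now(self) -> float:
        return max(self._now, time.monotonic() - self._t0)

    def advance_to(self, t: float) -> None:
        if t < self._now - 1e-12:
            raise ClockError(f"clock regression: {t} < {self._now}")
        remaining = t - (time.monotonic() - self._t0)
        if remaining > 0:
            time.sleep(remaining)
        self._now = max(self._now, float(t))


class LiveSnapshot(BaseModel):
    """Point-in-time view of a running session for polling consumers."""

    elapsed_s: float
    counts: dict[str, int]
    current_trial_index: int
    rolling_engagement: Optional[float] = None


def snapshot(trials: Sequence[TrialRecord], elapsed_s: float,
             window: int = 20) -> LiveSnapshot:
    """Pure summary of a (partial) trial log.

    ``rolling_engagement`` is responses / cued trials over the last
    ``window`` cued trials (None until the first cued trial).
    """
    counts = {o.value: 0 for o in TrialOutcome}
    for tr in trials:
        counts[tr.outcome.value] += 1
    cued = [tr for tr in trials
            if tr.outcome in (TrialOutcome.CORRECT, TrialOutcome.INCORRECT, TrialOutcome.MISS)]
    recent = cued[-window:]
    engagement = None
    if recent:
        responded = sum(1 for tr in recent if tr.outcome is not TrialOutcome.MISS)
        engagement = responded / len(recent)
    return LiveSnapshot(
        elapsed_s=elapsed_s,
        counts=counts,
        current_trial_index=len(trials),
        rolling_engagement=engagement,
    )


def run_session(
    cfg: ProtocolConfig,
    protocol_name: str,
    input_device: InputDevice,
    output_devices: Sequence[OutputDevice] = (),
    clock: Optional[SessionClock] = None,
    *,
    screen: Optional[ScreenGeometry] = None,
    hooks: Optional[OutcomeHooks] = None,
    observers: Sequence[Callable[[list[TrialRecord], float], None]] = (),
    session_id: Optional[str] = None,
    animal_id: str = "subject",
    start_timestamp: Optional[str] = None,
    flush_path: Optional[str] = None,
) -> SessionRecord:
    """Run a full session and return its record.

    Output devices are wired to outcome hooks: reward dispensers fire on
    every correct trial, sync stubs pulse at session start and each
    trial start. ``observers`` are read-only callbacks invoked with the
    partial trial log after every trial; they can never alter the
    record. If the engine faults mid-session the partial record is
    flushed to ``flush_path`` (JSON, ``complete: false``) before the
    error propagates.
    """
    clock = clock or AcceleratedClock()
    screen = screen or ScreenGeometry()
    hooks = hooks or OutcomeHooks()
    session_id = session_id or uuid.uuid4().hex[:12]
    if start_timestamp is None:
        start_timestamp = datetime.now(timezone.utc).isoformat(timespec="seconds")

    dispensers = [d for d in output_devices if hasattr(d, "cumulative_ul")]
    sync_stubs = [d for d in output_devices if isinstance(d, SyncPulseStub)]

    user_correct = hooks.on_correct
    user_trial_start = hooks.on_trial_start
    user_trial_end = hooks.on_trial_end
    trials_view: list[TrialRecord] = []

    def on_correct(event) -> None:
        t = event.t if event is not None else clock.now
        for d in dispensers:
            d.actuate(t, trigger="on_correct")
        user_correct(event)

    def on_trial_start(t: float) -> None:
        for s in sync_stubs:
            s.actuate(t, trigger="trial_start")
        user_trial_start(t)

    def on_trial_end(rec: TrialRecord) -> None:
        trials_view.append(rec)
        user_trial_end(rec)
        for obs in observers:
            obs(list(trials_view), clock.now)

    wired = OutcomeHooks(
        on_trial_start=on_trial_start,
        on_stimulus_start=hooks.on_stimulus_start,
        on_correct=on_correct,
        on_incorrect=hooks.on_incorrect,
        on_uncued=hooks.on_uncued,
        on_miss=hooks.on_miss,
        on_trial_end=on_trial_end,
    )

    for s in sync_stubs:
        s.actuate(clock.now, trigger="session_start")

    def device_meta() -> dict:
        return {
            "host": host_descriptor(),
            "peripherals": [input_device.descriptor()]
            + [d.descriptor() for d in output_devices],
        }

    try:
        record = run_protocol(
            protocol_name, cfg, wired, input_device, clock,
            screen=screen, session_id=session_id, animal_id=animal_id,
            start_timestamp=start_timestamp,
        )
    except Exception:
        if flush_path is not None:
            from . import io_export

            partial = SessionRecord(
                session_id=session_id, animal_id=animal_id,
                protocol_name=protocol_name,
                protocol_params=cfg.model_dump(mode="json"),
                screen=screen, start_timestamp=start_timestamp,
                duration_s=cfg.session_duration_s, trials=list(trials_view),
                events=[], device_metadata=device_meta(), complete=False,
            )
            io_export.write_json(partial, Path(flush_path))
        raise
    # refresh peripheral descriptors so actuation logs land in metadata
    record = record.model_copy(update={"device_metadata": device_meta()})
    return record
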