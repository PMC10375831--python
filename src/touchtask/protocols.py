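"""Trial state machine and the three out-of-box task structures.

A session is a loop of ``trial_block`` calls until the configured
duration expires. Each trial walks an explicit phase timeline:

    ITI  ->  stimulus  ->  (reward delay | punishment timeout)  ->  end

* Any ``down`` contact during the ITI is an *uncued touch*: it fires
  ``on_uncued`` and restarts a fresh, full ITI of the same planned
  duration (uncued touches are never otherwise punished).
* During the stimulus window the first ``down`` contact inside the
  target region is *correct*, inside the distractor region *incorrect*;
  contacts in the dead zone or outside all regions are ignored. A trial
  with no classified contact for the whole window is a *miss* (never
  punished; on Go/NoGo NoGo trials, withholding is the *correct*
  rejection).
* A correct response dispenses the reward and pauses for the reward
  delay before the next trial's ITI.

Shipped protocols: ``single_target`` (shaping: whole screen is the
target), ``twoafc`` (target grating vs isoluminant-gray distractor on
left/right halves separated by a central dead zone), ``gonogo``
(target-present Go trials vs distractor-only NoGo trials).

After an incorrect 2AFC choice (with corrections enabled) the next
trial is a *correction trial*: the same stimulus placement repeats,
bypassing the side planner, until a correct response ends the chain.
Misses inside a chain keep it alive. Correction trials are flagged on
the record so analytics can exclude them from d' without re-deriving
chains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterator, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict

from .core import (
    ProtocolConfig,
    ScreenGeometry,
    SessionRecord,
    Side,
    TouchEvent,
    TrialOutcome,
    TrialRecord,
    mm_to_px,
    validate_config,
)
from .devices import InputDevice, PhaseContext
from . import stimuli

PHASE_ITI = "iti"
PHASE_STIMULUS = "stimulus"
PHASE_REWARD_DELAY = "reward_delay"


class ProtocolFault(RuntimeError):
    """Engine-level contract violation (e.g. event-time regression)."""


class Rect(BaseModel):
    """Axis-aligned pixel rectangle, half-open: [x, x+w) x [y, y+h)."""

    model_config = ConfigDict(frozen=True)

    x: int
    y: int
    w: int
    h: int

    def contains(self, px: float, py: float) -> bool:
        return self.x <= px < self.x + self.w and self.y <= py < self.y + self.h


class RegionMap(BaseModel):
    """Touch-classification geometry for one trial.

    ``target_region`` and ``distractor_region`` are disjoint; the
    ``dead_zone`` is the central no-touch strip of the 2AFC layout
    whose pixel width is the mm dead-zone width converted through the
    screen geometry.
    """

    model_config = ConfigDict(frozen=True)

    target_region: Optional[Rect] = None
    distractor_region: Optional[Rect] = None
    dead_zone: Optional[Rect] = None


class TrialPlan(BaseModel):
    """Planned parameters of one upcoming trial."""

    model_config = ConfigDict(frozen=True)

    target_side: Side
    iti_duration: float
    is_correction: bool = False
    go: Optional[bool] = None
    stimulus_spec: Optional[dict] = None
    distractor_spec: Optional[dict] = None


def _noop(*args, **kwargs) -> None:
    return None


@dataclass
class OutcomeHooks:
    """Side-effect callbacks; they never alter classification.

    Outcome hooks receive the classified event (or the decision time for
    ``on_miss``); epoch hooks receive the epoch time.
    """

    on_trial_start: Callable = _noop
    on_stimulus_start: Callable = _noop
    on_correct: Callable = _noop
    on_incorrect: Callable = _noop
    on_uncued: Callable = _noop
    on_miss: Callable = _noop
    on_trial_end: Callable = _noop


def sample_iti(iti_range: tuple[float, float], rng: np.random.Generator) -> float:
    """Draw one inter-trial interval, uniform and continuous on the range.

    A degenerate range [c, c] (the fixed-length shaping ITI) always
    returns c without consuming randomness, so fixed-ITI sessions are
    reproducible independent of draw order.
    """
    lo, hi = iti_range
    if not (0 < lo <= hi):
        raise ValueError(f"invalid ITI range [{lo}, {hi}]")
    if lo == hi:
        return float(lo)
    return float(rng.uniform(lo, hi))


def plan_sides(n_trials: int, rng: np.random.Generator) -> list[str]:
    """Pseudo-random left/right ordering in shuffled balanced blocks of 2.

    Each block contains one left and one right in random order, so
    counts differ by at most 1 overall and no run of a single side
    exceeds 2 within a block pair. Correction trials bypass this planner
    entirely (they repeat the previous placement).
    """
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    sides: list[str] = []
    for _ in range((n_trials + 1) // 2):
        block = ["left", "right"]
        if rng.random() < 0.5:
            block.reverse()
        sides.extend(block)
    return sides[:n_trials]


def classify_touch(event: TouchEvent, region_map: RegionMap, phase: str,
                   screen: Optional[ScreenGeometry] = None) -> str:
    """Classify one touch event given the phase and the trial's regions.

    Returns one of ``uncued`` / ``correct`` / ``incorrect`` / ``ignored``.
    Only ``down`` contacts classify; drag and release samples are ignored.
    Events outside the screen are rejected.
    """
    if screen is not None and not screen.contains(event.x, event.y):
        raise ValueError(
            f"touch event out of screen bounds: ({event.x}, {event.y})"
        )
    if event.phase != "down":
        return "ignored"
    if phase == PHASE_ITI:
        return "uncued"
    if phase == PHASE_REWARD_DELAY:
        return "ignored"
    if phase != PHASE_STIMULUS:
        raise ValueError(f"unknown trial phase {phase!r}")
    if region_map.dead_zone is not None and region_map.dead_zone.contains(event.x, event.y):
        return "ignored"
    if region_map.target_region is not None and region_map.target_region.contains(event.x, event.y):
        return "correct"
    if region_map.distractor_region is not None and region_map.distractor_region.contains(event.x, event.y):
        return "incorrect"
    return "ignored"


def make_region_map(protocol_name: str, plan: TrialPlan, cfg: ProtocolConfig,
                    screen: ScreenGeometry) -> RegionMap:
    """Build the touch-classification geometry for one trial.

    * single_target: the whole screen is the target.
    * twoafc: left/right halves flanking a centred dead-zone strip of
      the configured mm width; the target occupies ``plan.target_side``.
    * gonogo: the whole screen is the target on Go trials and the
      distractor on NoGo trials.
    """
    full = Rect(x=0, y=0, w=screen.width_px, h=screen.height_px)
    if protocol_name == "single_target":
        return RegionMap(target_region=full)
    if protocol_name == "gonogo":
        if plan.go is False:
            return RegionMap(distractor_region=full)
        return RegionMap(target_region=full)
    if protocol_name == "twoafc":
        dz_w = mm_to_px(cfg.dead_zone_mm, screen, axis="x")
        side_w = (screen.width_px - dz_w) // 2
        left = Rect(x=0, y=0, w=side_w, h=screen.height_px)
        right = Rect(x=screen.width_px - side_w, y=0, w=side_w, h=screen.height_px)
        dead = (
            Rect(x=side_w, y=0, w=screen.width_px - 2 * side_w, h=screen.height_px)
            if screen.width_px - 2 * side_w > 0
            else None
        )
        if plan.target_side == "left":
            return RegionMap(target_region=left, distractor_region=right, dead_zone=dead)
        if plan.target_side == "right":
            return RegionMap(target_region=right, distractor_region=left, dead_zone=dead)
        raise ValueError(f"twoafc trial needs target_side left/right, got {plan.target_side!r}")
    raise KeyError(
        f"unknown protocol {protocol_name!r}; available: {sorted(PROTOCOLS)}"
    )


def trial_block(
    plan: TrialPlan,
    cfg: ProtocolConfig,
    region_map: RegionMap,
    source: InputDevice,
    hooks: OutcomeHooks,
    clock,
    *,
    index: int = 1,
    deadline: float = math.inf,
    screen: Optional[ScreenGeometry] = None,
    event_log: Optional[list[TouchEvent]] = None,
    rng: Optional[np.random.Generator] = None,
) -> TrialRecord:
    """Run one trial against the event source and return its record.

    ``deadline`` is the absolute time (session duration + grace) past
    which an unresolved trial is aborted and marked ``truncated``; a
    trial whose classification happened before the deadline keeps its
    outcome even if its tail (reward delay) is clipped.
    """
    t_start = clock.now
    hooks.on_trial_start(t_start)
    uncued_count = 0
    log = event_log if event_log is not None else []

    def pull(limit: float) -> Optional[TouchEvent]:
        ev = source.next_event(limit)
        if ev is None:
            return None
        if ev.t < clock.now - 1e-12:
            raise ProtocolFault(
                f"event source time regression: event at t={ev.t} "
                f"behind clock {clock.now}"
            )
        log.append(ev)
        clock.advance_to(max(ev.t, clock.now))
        return ev

    # --- ITI phase: uncued touches reset a fresh full interval -------------
    iti = plan.iti_duration
    window_start = t_start
    iti_end = window_start + iti
    truncated_in_iti = False
    while True:
        limit = min(iti_end, deadline)
        source.set_context(PhaseContext(PHASE_ITI, window_start, limit, region_map, plan))
        ev = pull(limit)
        if ev is None:
            if iti_end > deadline:
                truncated_in_iti = True
                clock.advance_to(deadline)
            else:
                clock.advance_to(iti_end)
            break
        if classify_touch(ev, region_map, PHASE_ITI, screen) == "uncued":
            hooks.on_uncued(ev)
            uncued_count += 1
            window_start = ev.t
            if cfg.iti_reset_redraw and rng is not None:
                iti = sample_iti(cfg.iti_range_s, rng)
            iti_end = ev.t + iti

    if truncated_in_iti:
        rec = TrialRecord(
            index=index, outcome=TrialOutcome.TRUNCATED,
            target_side=plan.target_side, is_correction=plan.is_correction,
            go=plan.go, iti_duration=plan.iti_duration,
            trial_start_t=t_start, stimulus_onset_t=None,
            trial_end_t=deadline, uncued_touch_count=uncued_count,
        )
        hooks.on_trial_end(rec)
        return rec

    # --- stimulus phase ----------------------------------------------------
    onset = clock.now
    hooks.on_stimulus_start(onset)
    stim_end = onset + cfg.stimulus_duration_s
    clipped = stim_end > deadline
    limit = min(stim_end, deadline)
    response: Optional[TouchEvent] = None
    outcome: Optional[TrialOutcome] = None
    source.set_context(PhaseContext(PHASE_STIMULUS, onset, limit, region_map, plan))
    while True:
        ev = pull(limit)
        if ev is None:
            break
        cls = classify_touch(ev, region_map, PHASE_STIMULUS, screen)
        if cls == "correct":
            response, outcome = ev, TrialOutcome.CORRECT
            break
        if cls == "incorrect":
            response, outcome = ev, TrialOutcome.INCORRECT
            break
        # ignored (dead zone / off-region / move / up): keep scanning

    reward_volume = 0.0
    if response is not None:
        end = response.t
        if outcome is TrialOutcome.CORRECT:
            hooks.on_correct(response)
            reward_volume = cfg.reward_volume_ul
            end = response.t + cfg.reward_delay_s
        else:
            hooks.on_incorrect(response)
            end = response.t + cfg.punishment_timeout_s
        end = min(end, deadline)
        # consume (and log) any contacts during the post-response pause
        source.set_context(PhaseContext(PHASE_REWARD_DELAY, response.t, end, region_map, plan))
        while pull(end) is not None:
            pass
        clock.advance_to(end)
    elif clipped:
        outcome = TrialOutcome.TRUNCATED
        clock.advance_to(deadline)
        end = deadline
    elif plan.go is False:
        # NoGo trial: withholding for the whole window is a correct rejection
        outcome = TrialOutcome.CORRECT
        hooks.on_correct(None)
        reward_volume = cfg.reward_volume_ul
        end = min(stim_end + cfg.reward_delay_s, deadline)
        source.set_context(PhaseContext(PHASE_REWARD_DELAY, stim_end, end, region_map, plan))
        while pull(end) is not None:
            pass
        clock.advance_to(end)
    else:
        outcome = TrialOutcome.MISS
        hooks.on_miss(stim_end)
        end = stim_end

    rec = TrialRecord(
        index=index, outcome=outcome, target_side=plan.target_side,
        is_correction=plan.is_correction, go=plan.go,
        iti_duration=plan.iti_duration, trial_start_t=t_start,
        stimulus_onset_t=onset,
        response_t=response.t if response is not None else None,
        response_xy=(response.x, response.y) if response is not None else None,
        trial_end_t=end, uncued_touch_count=uncued_count,
        reward_volume_ul=reward_volume,
    )
    hooks.on_trial_end(rec)
    return rec


class _SidePlanner:
    """Streams sides from shuffled balanced blocks of two."""

    def __init__(self, rng: np.random.Generator):
        self._rng = rng
        self._buffer: list[str] = []

    def next(self) -> str:
        if not self._buffer:
            self._buffer = plan_sides(2, self._rng)
        return self._buffer.pop(0)


def _default_specs(cfg: ProtocolConfig) -> tuple[dict, Optional[dict]]:
    target = cfg.target_stimulus or stimuli.grating_preset().model_dump()
    distractor = cfg.distractor_stimulus or stimuli.gray_preset().model_dump()
    return target, distractor


def _plan_single(cfg: ProtocolConfig, rng: np.random.Generator,
                 planner: _SidePlanner) -> TrialPlan:
    target, _ = _default_specs(cfg)
    return TrialPlan(target_side="single", iti_duration=sample_iti(cfg.iti_range_s, rng),
                     stimulus_spec=target)


def _plan_twoafc(cfg: ProtocolConfig, rng: np.random.Generator,
                 planner: _SidePlanner) -> TrialPlan:
    target, distractor = _default_specs(cfg)
    return TrialPlan(target_side=planner.next(),
                     iti_duration=sample_iti(cfg.iti_range_s, rng),
                     stimulus_spec=target, distractor_spec=distractor)


def _plan_gonogo(cfg: ProtocolConfig, rng: np.random.Generator,
                 planner: _SidePlanner) -> TrialPlan:
    target, distractor = _default_specs(cfg)
    go = planner.next() == "left"  # balanced 50/50 go/nogo via the same blocks
    return TrialPlan(target_side="single", go=go,
                     iti_duration=sample_iti(cfg.iti_range_s, rng),
                     stimulus_spec=target if go else None,
                     distractor_spec=None if go else distractor)


PROTOCOLS: dict[str, Callable] = {
    "single_target": _plan_single,
    "twoafc": _plan_twoafc,
    "gonogo": _plan_gonogo,
}


def run_protocol(
    name: str,
    cfg: ProtocolConfig,
    hooks: OutcomeHooks,
    source: InputDevice,
    clock,
    *,
    screen: Optional[ScreenGeometry] = None,
    session_id: str = "session",
    animal_id: str = "subject",
    start_timestamp: str = "",
    device_metadata: Optional[dict] = None,
) -> SessionRecord:
    """Loop ``trial_block`` until the session duration expires.

    Correction logic: with corrections enabled, an incorrect trial makes
    the next plan a correction with the same placement (fresh ITI draw);
    the chain persists through misses and ends on a correct response.
    """
    if name not in PROTOCOLS:
        raise KeyError(
            f"unknown protocol {name!r}; available: {sorted(PROTOCOLS)}"
        )
    screen = screen or ScreenGeometry()
    problems = validate_config(cfg, screen)
    if problems:
        raise ValueError("invalid protocol config: " + "; ".join(problems))

    rng = np.random.default_rng(cfg.rng_seed)
    planner = _SidePlanner(rng)
    plan_fn = PROTOCOLS[name]
    deadline = cfg.session_duration_s + cfg.grace_s

    trials: list[TrialRecord] = []
    events: list[TouchEvent] = []
    pending_correction: Optional[TrialPlan] = None
    index = 1
    while clock.now < cfg.session_duration_s:
        if cfg.max_trials is not None and len(trials) >= cfg.max_trials:
            break
        if pending_correction is not None:
            plan = pending_correction.model_copy(
                update={"iti_duration": sample_iti(cfg.iti_range_s, rng),
                        "is_correction": True}
            )
        else:
            plan = plan_fn(cfg, rng, planner)
        region_map = make_region_map(name, plan, cfg, screen)
        rec = trial_block(
            plan, cfg, region_map, source, hooks, clock,
            index=index, deadline=deadline, screen=screen,
            event_log=events, rng=rng,
        )
        trials.append(rec)
        index += 1
        if cfg.corrections_enabled and name == "twoafc":
            if rec.outcome is TrialOutcome.INCORRECT:
                pending_correction = plan
            elif rec.outcome is TrialOutcome.CORRECT:
                pending_correction = None
            # miss / truncated: chain state unchanged

    return SessionRecord(
        session_id=session_id,
        animal_id=animal_id,
        protocol_name=name,
        protocol_params=cfg.model_dump(mode="json"),
        screen=screen,
        start_timestamp=start_timestamp,
        duration_s=cfg.session_duration_s,
        trials=trials,
        events=events,
        device_metadata=device_metadata or {},
    )
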