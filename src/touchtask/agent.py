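"""Closed-loop simulated subject standing in for the mouse.

The agent is an :class:`~touchtask.devices.InputDevice`: the engine
publishes each trial phase (and what is on the screen) through
``set_context`` and the agent answers with touch events, so sessions it
produces flow through exactly the same engine path as a live animal.

Behavioural model (memoryless within a session, so the closed forms
used in tests stay exact):

* On each cued trial the agent responds with probability ``p_respond``;
  otherwise the trial is a miss.
* A response lands on the target region centre with probability
  ``accuracy`` and on the distractor centre otherwise, jittered by an
  isotropic Gaussian with spread ``touch_scatter_sd_mm`` and clipped to
  the screen. On NoGo trials (no target shown) a touch is emitted with
  probability ``p_respond * (1 - accuracy)`` — the agent mostly
  withholds when it "knows" the stimulus.
* Response latency is a truncated normal (> 0.05 s).
* Spontaneous ITI contacts arrive as a Poisson process at
  ``uncued_rate`` events/s, uniformly placed on the screen (each one
  resets the ITI, closing the loop).

Between sessions a curriculum applies saturating ramps: ``p_respond``
and ``accuracy`` increase by their per-session increments up to their
ceilings (emulating multi-day learning curves), and in sessions tagged
``response_modality="reaching"`` the touch scatter shrinks by the
multiplicative ``scatter_shrink`` (reach stereotypy is a property of
motor learning in the reaching phase; nose-poke scatter is held
constant).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .core import ProtocolConfig, ScreenGeometry, SessionRecord, TouchEvent
from .devices import InputDevice, PhaseContext, SimRewardDispenser, SyncPulseStub
from .presets import load_preset
from .runner import AcceleratedClock, run_session


class AgentParams(BaseModel):
    """Tunable parameters of the simulated subject.

    Defaults describe a naive subject at the start of shaping; the
    ramps carry it through the curriculum.
    """

    model_config = ConfigDict(frozen=True)

    p_respond: float = Field(default=0.35, ge=0.0, le=1.0)
    p_respond_ramp: float = Field(default=0.15, ge=0.0)
    p_respond_ceiling: float = Field(default=0.95, ge=0.0, le=1.0)
    accuracy: float = Field(default=0.55, ge=0.0, le=1.0)
    accuracy_ramp: float = Field(default=0.06, ge=0.0)
    accuracy_ceiling: float = Field(default=0.97, ge=0.0, le=1.0)
    uncued_rate: float = Field(default=0.02, ge=0.0, description="events/s")
    latency_mean: float = Field(default=1.0, gt=0.0, description="s")
    latency_sd: float = Field(default=0.5, ge=0.0)
    touch_scatter_sd_mm: float = Field(default=3.6, ge=0.0)
    scatter_shrink: float = Field(default=0.9, gt=0.0, le=1.0)
    side_bias: float = Field(default=0.0, ge=0.0, le=1.0,
                             description="probability of a left response regardless of target")
    seed: int = 0


_MIN_LATENCY = 0.05


class SyntheticAgent(InputDevice):
    """Closed-loop event source driven by :class:`AgentParams`."""

    identity = "synthetic_agent"

    def __init__(self, params: AgentParams, screen: Optional[ScreenGeometry] = None,
                 rng: Optional[np.random.Generator] = None):
        self.params = params
        self.screen = screen or ScreenGeometry()
        self.rng = rng if rng is not None else np.random.default_rng(params.seed)
        self._buffer: list[TouchEvent] = []
        self._gen_until = 0.0
        self._last_stim_onset: Optional[float] = None

    def descriptor(self) -> dict:
        return {
            "identity": self.identity,
            "class": type(self).__name__,
            "params": self.params.model_dump(),
        }

    # -- event generation ---------------------------------------------------

    def _push(self, ev: TouchEvent) -> None:
        self._buffer.append(ev)
        self._buffer.sort(key=lambda e: e.t)

    def _uniform_point(self) -> tuple[float, float]:
        return (
            float(self.rng.uniform(0, self.screen.width_px)),
            float(self.rng.uniform(0, self.screen.height_px)),
        )

    def _latency(self) -> float:
        while True:
            lat = self.rng.normal(self.params.latency_mean, self.params.latency_sd)
            if lat > _MIN_LATENCY:
                return float(lat)

    def _aim(self, region) -> tuple[float, float]:
        cx = region.x + region.w / 2.0
        cy = region.y + region.h / 2.0
        sd_x = self.params.touch_scatter_sd_mm * self.screen.px_per_mm_x
        sd_y = self.params.touch_scatter_sd_mm * self.screen.px_per_mm_y
        x = cx + self.rng.normal(0.0, sd_x) if sd_x > 0 else cx
        y = cy + self.rng.normal(0.0, sd_y) if sd_y > 0 else cy
        x = min(max(x, 0.0), self.screen.width_px - 1e-6)
        y = min(max(y, 0.0), self.screen.height_px - 1e-6)
        return float(x), float(y)

    def _gen_iti(self, start: float, end: float) -> None:
        t = max(start, self._gen_until)
        if self.params.uncued_rate > 0:
            while True:
                t += float(self.rng.exponential(1.0 / self.params.uncued_rate))
                if t >= end:
                    break
                x, y = self._uniform_point()
                self._push(TouchEvent(x=x, y=y, t=t, phase="down"))
        self._gen_until = max(self._gen_until, end)

    def _gen_stimulus(self, ctx: PhaseContext) -> None:
        if ctx.start == self._last_stim_onset:
            return  # already decided for this trial
        self._last_stim_onset = ctx.start
        rmap = ctx.region_map
        p = self.params
        target = getattr(rmap, "target_region", None)
        distractor = getattr(rmap, "distractor_region", None)
        if target is None:
            # NoGo trial: touch (a false alarm) only on a response *and* a lapse
            if distractor is None:
                return
            if self.rng.random() >= p.p_respond * (1.0 - p.accuracy):
                return
            aim_region = distractor
        else:
            if self.rng.random() >= p.p_respond:
                return  # miss
            if distractor is not None:
                if p.side_bias > 0 and self.rng.random() < p.side_bias:
                    # biased responder: always the left-hand region
                    aim_region = target if target.x < distractor.x else distractor
                else:
                    aim_region = target if self.rng.random() < p.accuracy else distractor
            else:
                aim_region = target
        x, y = self._aim(aim_region)
        self._push(TouchEvent(x=x, y=y, t=ctx.start + self._latency(), phase="down"))

    # -- InputDevice contract -----------------------------------------------

    def set_context(self, ctx: PhaseContext) -> None:
        if ctx.phase == "iti":
            self._gen_iti(ctx.start, ctx.end)
        elif ctx.phase == "stimulus":
            self._gen_stimulus(ctx)
        # reward_delay: the simulated subject is busy consuming the reward

    def next_event(self, limit: float) -> Optional[TouchEvent]:
        if self._buffer and self._buffer[0].t < limit:
            return self._buffer.pop(0)
        return None


def agent_step(ctx: PhaseContext, params: AgentParams,
               rng: np.random.Generator,
               screen: Optional[ScreenGeometry] = None) -> list[TouchEvent]:
    """One-shot view of the agent's response to a single phase context
    (convenience for tests and docs; sessions use :class:`SyntheticAgent`)."""
    agent = SyntheticAgent(params, screen=screen, rng=rng)
    agent.set_context(ctx)
    out = []
    while (ev := agent.next_event(ctx.end)) is not None:
        out.append(ev)
    return out


DEFAULT_CURRICULUM: list[tuple[str, int]] = [
    ("phase1_shaping", 4),
    ("phase2_2afc", 10),
    ("phase3_reaching", 8),
]
"""Shipped three-phase training course: shaping, 2AFC nose poke, 2AFC reaching."""


def _ramped(params: AgentParams) -> AgentParams:
    return params.model_copy(update={
        "p_respond": min(params.p_respond + params.p_respond_ramp,
                         params.p_respond_ceiling),
        "accuracy": min(params.accuracy + params.accuracy_ramp,
                        params.accuracy_ceiling),
    })


def run_curriculum(
    phases: Optional[Sequence[tuple[str, int]]] = None,
    params: Optional[AgentParams] = None,
    *,
    base_seed: int = 0,
    screen: Optional[ScreenGeometry] = None,
    animal_id: str = "sim-mouse",
    config_overrides: Optional[dict] = None,
    with_reward_device: bool = True,
) -> list[SessionRecord]:
    """Run the training curriculum with a learning agent.

    Sessions run in listed order on the accelerated clock, through the
    same ``run_session`` path as any experiment. Between sessions the
    agent's response probability and accuracy ramp up (saturating), and
    its touch scatter shrinks during reaching-tagged sessions.
    """
    phases = list(phases) if phases is not None else list(DEFAULT_CURRICULUM)
    params = params or AgentParams()
    screen = screen or ScreenGeometry()
    seeds = np.random.SeedSequence(base_seed).generate_state(
        sum(n for _, n in phases) * 2
    ) % (2**31)

    records: list[SessionRecord] = []
    k = 0
    for preset_name, n_sessions in phases:
        for _ in range(n_sessions):
            protocol_name, cfg = load_preset(preset_name)
            updates = dict(config_overrides or {})
            updates["rng_seed"] = int(seeds[2 * k])
            cfg = cfg.model_copy(update=updates)
            agent = SyntheticAgent(
                params.model_copy(update={"seed": int(seeds[2 * k + 1])}),
                screen=screen,
            )
            outputs = []
            if with_reward_device:
                outputs = [SimRewardDispenser(cfg.reward_volume_ul),
                           SyncPulseStub()]
            rec = run_session(
                cfg, protocol_name, agent, outputs,
                clock=AcceleratedClock(), screen=screen,
                session_id=f"{preset_name}-{k:03d}", animal_id=animal_id,
                start_timestamp="1970-01-01T00:00:00+00:00",
            )
            records.append(rec)
            params = _ramped(params)
            if cfg.response_modality == "reaching":
                params = params.model_copy(update={
                    "touch_scatter_sd_mm":
                        params.touch_scatter_sd_mm * params.scatter_shrink,
                })
            k += 1
    return records
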