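"""Shared data model for touchscreen operant sessions.

Every other module consumes these types: touch events, trial records,
session records, screen geometry and protocol configuration.

Conventions
-----------
* Screen coordinates are 0-based pixels, origin top-left, x rightward and
  y downward, half-open ranges ``[0, width_px)`` / ``[0, height_px)`` —
  the convention of mainstream touch APIs.
* All within-session times are float seconds relative to session start.
  The single wall-clock anchor (``start_timestamp``) lives in session
  metadata as an ISO-8601 string.
* Physical screen size is carried in millimetres so behavioural
  quantities (dead-zone width, reach scatter) can be reported in mm
  independently of the panel resolution.
"""

from __future__ import annotations

import enum
import math
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field

SPEC_VERSION = "1.0.0"
"""Schema version written into every serialized session (semantic versioning)."""

Side = Literal["left", "right", "single"]
TouchPhase = Literal["down", "move", "up"]


class TouchEvent(BaseModel):
    """One screen contact sample.

    ``phase`` distinguishes initial contact (``down``) from drag samples
    (``move``) and release (``up``); only ``down`` events are ever
    classified by the protocol logic.
    """

    model_config = ConfigDict(frozen=True)

    x: float
    y: float
    t: float = Field(ge=0.0)
    phase: TouchPhase = "down"


class ScreenGeometry(BaseModel):
    """Logical resolution and physical size of the touch panel.

    Defaults map an 800x480 px logical surface onto a 97x58 mm panel
    (a compact integrated touchscreen of the kind used in mouse operant
    arenas); both are configurable.
    """

    model_config = ConfigDict(frozen=True)

    width_px: int = Field(default=800, gt=0)
    height_px: int = Field(default=480, gt=0)
    width_mm: float = Field(default=97.0, gt=0)
    height_mm: float = Field(default=58.0, gt=0)

    @property
    def px_per_mm_x(self) -> float:
        return self.width_px / self.width_mm

    @property
    def px_per_mm_y(self) -> float:
        return self.height_px / self.height_mm

    def contains(self, x: float, y: float) -> bool:
        return 0 <= x < self.width_px and 0 <= y < self.height_px


class TrialOutcome(str, enum.Enum):
    """Outcome of one completed trial.

    Uncued touches are events, not outcomes: they reset the ITI and are
    tallied per trial in ``TrialRecord.uncued_touch_count``.
    """

    CORRECT = "correct"
    INCORRECT = "incorrect"
    MISS = "miss"
    TRUNCATED = "truncated"


class TrialRecord(BaseModel):
    """One trial: outcome, timing epochs, stimulus placement, correction flag.

    ``response_t``/``response_xy`` are present iff the trial was resolved
    by a screen contact (``correct`` or ``incorrect``); a Go/NoGo correct
    rejection is recorded as ``correct`` with no response, mirroring how
    withholding is the rewarded action on NoGo trials.
    ``stimulus_onset_t`` is absent when the session expired during the ITI.
    """

    index: int = Field(ge=1, description="1-based trial number")
    outcome: TrialOutcome
    target_side: Side
    is_correction: bool = False
    go: Optional[bool] = None
    iti_duration: float = Field(ge=0.0)
    trial_start_t: float = Field(ge=0.0)
    stimulus_onset_t: Optional[float] = None
    response_t: Optional[float] = None
    response_xy: Optional[tuple[float, float]] = None
    trial_end_t: float = Field(ge=0.0)
    uncued_touch_count: int = Field(default=0, ge=0)
    reward_volume_ul: float = Field(default=0.0, ge=0.0)


class ProtocolConfig(BaseModel):
    """Tunable parameters of a behavioural session.

    Invariants are deliberately *not* enforced at construction so that
    arbitrary user config files can be loaded and then checked with
    :func:`validate_config`, which reports all violations at once.
    """

    session_duration_s: float = 1800.0
    iti_range_s: tuple[float, float] = (3.0, 3.0)
    stimulus_duration_s: float = 10.0
    reward_delay_s: float = 1.0
    dead_zone_mm: float = 0.0
    corrections_enabled: bool = False
    reward_volume_ul: float = 10.0
    rng_seed: int = 0
    # engine extras
    grace_s: float = 0.0
    max_trials: Optional[int] = None
    punishment_timeout_s: float = 0.0
    iti_reset_redraw: bool = False
    response_modality: str = "nose_poke"
    target_stimulus: Optional[dict] = None
    distractor_stimulus: Optional[dict] = None


class SessionRecord(BaseModel):
    """Full record of one behavioural session.

    Holds metadata, the configured parameter snapshot, the ordered trial
    log and the raw touch-event log. Serialization (io_export) round-trips
    this record losslessly.
    """

    session_id: str
    animal_id: str
    protocol_name: str
    protocol_params: dict
    screen: ScreenGeometry = ScreenGeometry()
    start_timestamp: str = ""
    duration_s: float = 0.0
    trials: list[TrialRecord] = Field(default_factory=list)
    events: list[TouchEvent] = Field(default_factory=list)
    device_metadata: dict = Field(default_factory=dict)
    spec_version: str = SPEC_VERSION
    complete: bool = True

    def outcome_counts(self) -> dict[str, int]:
        counts = {o.value: 0 for o in TrialOutcome}
        for tr in self.trials:
            counts[tr.outcome.value] += 1
        return counts


def validate_config(cfg: ProtocolConfig, screen: ScreenGeometry) -> list[str]:
    """Check a protocol configuration against its invariants.

    Returns a list of human-readable violations, each naming the offending
    field; an empty list means the configuration is valid. Never raises.
    """
    violations: list[str] = []
    lo, hi = cfg.iti_range_s
    if not (0 < lo <= hi):
        violations.append(
            f"iti_range_s: require 0 < min <= max, got [{lo}, {hi}]"
        )
    if not cfg.stimulus_duration_s > 0:
        violations.append(
            f"stimulus_duration_s: must be > 0, got {cfg.stimulus_duration_s}"
        )
    if cfg.reward_delay_s < 0:
        violations.append(
            f"reward_delay_s: must be >= 0, got {cfg.reward_delay_s}"
        )
    if cfg.dead_zone_mm < 0:
        violations.append(f"dead_zone_mm: must be >= 0, got {cfg.dead_zone_mm}")
    if cfg.dead_zone_mm > screen.width_mm:
        violations.append(
            f"dead_zone_mm: exceeds screen width {screen.width_mm} mm"
        )
    if cfg.session_duration_s < 0:
        violations.append(
            f"session_duration_s: must be >= 0, got {cfg.session_duration_s}"
        )
    if cfg.reward_volume_ul < 0:
        violations.append(
            f"reward_volume_ul: must be >= 0, got {cfg.reward_volume_ul}"
        )
    if cfg.grace_s < 0:
        violations.append(f"grace_s: must be >= 0, got {cfg.grace_s}")
    if cfg.punishment_timeout_s < 0:
        violations.append(
            f"punishment_timeout_s: must be >= 0, got {cfg.punishment_timeout_s}"
        )
    if cfg.max_trials is not None and cfg.max_trials < 0:
        violations.append(f"max_trials: must be >= 0, got {cfg.max_trials}")
    return violations


def mm_to_px(d_mm: float, screen: ScreenGeometry, axis: str = "x") -> int:
    """Convert a physical distance to pixels along one screen axis.

    Uses that axis' resolution / physical-size ratio and rounds to the
    nearest pixel. Rejects non-finite input.
    """
    if not math.isfinite(d_mm):
        raise ValueError(f"mm_to_px: non-finite distance {d_mm!r}")
    if axis == "x":
        scale = screen.px_per_mm_x
    elif axis == "y":
        scale = screen.px_per_mm_y
    else:
        raise ValueError(f"mm_to_px: axis must be 'x' or 'y', got {axis!r}")
    return int(round(d_mm * scale))


def px_to_mm(d_px: float, screen: ScreenGeometry, axis: str = "x") -> float:
    """Inverse of :func:`mm_to_px` (exact, no rounding)."""
    if not math.isfinite(d_px):
        raise ValueError(f"px_to_mm: non-finite distance {d_px!r}")
    if axis == "x":
        return d_px / screen.px_per_mm_x
    if axis == "y":
        return d_px / screen.px_per_mm_y
    raise ValueError(f"px_to_mm: axis must be 'x' or 'y', got {axis!r}")
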