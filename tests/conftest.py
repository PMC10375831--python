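import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from touchtask.core import (
    ProtocolConfig,
    ScreenGeometry,
    SessionRecord,
    TouchEvent,
    TrialRecord,
)


@pytest.fixture
def screen() -> ScreenGeometry:
    return ScreenGeometry()


@pytest.fixture
def phase1_cfg() -> ProtocolConfig:
    """Shaping: fixed 3 s ITI, 10 s stimulus, 1 s reward delay."""
    return ProtocolConfig(
        session_duration_s=1800.0, iti_range_s=(3.0, 3.0),
        stimulus_duration_s=10.0, reward_delay_s=1.0, reward_volume_ul=10.0,
    )


@pytest.fixture
def twoafc_cfg() -> ProtocolConfig:
    """2AFC: 4-6 s ITI, 10 mm dead zone, corrections on."""
    return ProtocolConfig(
        session_duration_s=1800.0, iti_range_s=(4.0, 6.0),
        stimulus_duration_s=10.0, reward_delay_s=1.0,
        dead_zone_mm=10.0, corrections_enabled=True,
    )


def make_trial(index=1, outcome="correct", side="left", correction=False,
               start=0.0, onset=3.0, resp=3.5, end=4.5, xy=(100.0, 200.0),
               uncued=0, reward=10.0, go=None) -> TrialRecord:
    from touchtask.core import TrialOutcome

    responded = outcome in ("correct", "incorrect") and resp is not None
    return TrialRecord(
        index=index, outcome=TrialOutcome(outcome), target_side=side,
        is_correction=correction, go=go, iti_duration=3.0,
        trial_start_t=start, stimulus_onset_t=onset if outcome != "truncated" else None,
        response_t=resp if responded else None,
        response_xy=xy if responded else None,
        trial_end_t=end, uncued_touch_count=uncued,
        reward_volume_ul=reward if outcome == "correct" else 0.0,
    )


def random_session(rng: np.random.Generator, n_trials=None) -> SessionRecord:
    """Property generator: a schema-valid session with randomized content."""
    n = int(rng.integers(0, 25)) if n_trials is None else n_trials
    trials = []
    t = 0.0
    for i in range(1, n + 1):
        outcome = rng.choice(["correct", "incorrect", "miss", "truncated"],
                             p=[0.5, 0.2, 0.2, 0.1])
        onset = t + float(rng.uniform(3, 6))
        resp = onset + float(rng.uniform(0.1, 9.9))
        end = resp + 1.0 if outcome in ("correct", "incorrect") else onset + 10.0
        trials.append(make_trial(
            index=i, outcome=outcome,
            side=rng.choice(["left", "right", "single"]),
            correction=bool(rng.random() < 0.2), start=t, onset=onset,
            resp=resp, end=end,
            xy=(float(rng.uniform(0, 800)), float(rng.uniform(0, 480))),
            uncued=int(rng.integers(0, 4)),
            go=None if rng.random() < 0.5 else bool(rng.integers(0, 2)),
        ))
        t = end
    events = []
    te = 0.0
    for _ in range(int(rng.integers(0, 40))):
        te += float(rng.uniform(0, 2))
        events.append(TouchEvent(
            x=float(rng.uniform(0, 800)), y=float(rng.uniform(0, 480)),
            t=te, phase=rng.choice(["down", "move", "up"], p=[0.8, 0.1, 0.1]),
        ))
    return SessionRecord(
        session_id=f"rs{rng.integers(1e6)}",
        animal_id=f"m{rng.integers(100)}",
        protocol_name=rng.choice(["single_target", "twoafc", "gonogo"]),
        protocol_params=ProtocolConfig(rng_seed=int(rng.integers(1000))).model_dump(mode="json"),
        start_timestamp="2024-01-01T09:00:00+00:00",
        duration_s=float(t + 10),
        trials=trials, events=events,
        device_metadata={"host": {"platform": "test"},
                         "peripherals": [{"identity": "scripted"}]},
    )
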