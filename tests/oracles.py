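"""Independent oracles used to cross-check the engine.

Everything here is deliberately written without touching the package's
own state machine or scipy's quantile function, in the plainest style
possible, so agreement with the implementation is evidence and not
tautology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional


# --- normal quantile by bisection on an independently coded CDF ------------

def normal_cdf(x: float) -> float:
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


def normal_quantile(p: float, lo: float = -12.0, hi: float = 12.0,
                    tol: float = 1e-12) -> float:
    """Invert the standard-normal CDF by bisection."""
    if not 0.0 < p < 1.0:
        raise ValueError(p)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if normal_cdf(mid) < p:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def dprime_oracle(H: float, FA: float) -> float:
    return (normal_quantile(H) - normal_quantile(FA)) / math.sqrt(2.0)


# --- linear event-replay oracle for one trial ------------------------------

@dataclass
class ReplayResult:
    outcome: str  # correct | incorrect | miss | truncated
    uncued_count: int
    onset: Optional[float]
    response_t: Optional[float]
    end_t: float


def _in_rect(rect, x: float, y: float) -> bool:
    if rect is None:
        return False
    x0, y0, w, h = rect
    return x0 <= x < x0 + w and y0 <= y < y0 + h


def replay_trial(
    events,
    iti: float,
    stim_dur: float,
    reward_delay: float,
    *,
    target=None,
    distractor=None,
    dead=None,
    t0: float = 0.0,
    deadline: float = math.inf,
    punishment: float = 0.0,
    nogo: bool = False,
) -> ReplayResult:
    """Walk a time-ordered event list through one trial's phase timeline.

    Rectangles are plain (x, y, w, h) tuples. Down events before the
    stimulus onset are uncued touches, each restarting a full ITI; the
    first down inside target/distractor during the stimulus window
    resolves the trial; dead-zone and off-region downs are ignored.
    """
    downs = [e for e in events if e.phase == "down"]
    downs.sort(key=lambda e: e.t)

    onset = t0 + iti
    uncued = 0
    i = 0
    while i < len(downs) and downs[i].t < min(onset, deadline):
        uncued += 1
        onset = downs[i].t + iti
        i += 1
    if onset > deadline:
        return ReplayResult("truncated", uncued, None, None, deadline)

    stim_end = onset + stim_dur
    limit = min(stim_end, deadline)
    response = None
    verdict = None
    while i < len(downs) and downs[i].t < limit:
        ev = downs[i]
        i += 1
        if _in_rect(dead, ev.x, ev.y):
            continue
        if _in_rect(target, ev.x, ev.y):
            response, verdict = ev, "correct"
            break
        if _in_rect(distractor, ev.x, ev.y):
            response, verdict = ev, "incorrect"
            break

    if response is not None:
        pause = reward_delay if verdict == "correct" else punishment
        end = min(response.t + pause, deadline)
        return ReplayResult(verdict, uncued, onset, response.t, end)
    if stim_end > deadline:
        return ReplayResult("truncated", uncued, onset, None, deadline)
    if nogo:
        return ReplayResult("correct", uncued, onset, None,
                            min(stim_end + reward_delay, deadline))
    return ReplayResult("miss", uncued, onset, None, stim_end)
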