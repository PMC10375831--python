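"""Behavioural analytics: signal detection, engagement, reach scatter.

Discriminability
----------------
The 2AFC discriminability index is

    d' = (Z(H) - Z(FA)) / sqrt(2)

with Z the standard-normal quantile, H the hit rate and FA the
false-alarm rate. For the side-choice task we adopt the standard
left-as-signal convention: H is the probability of a left response on
left-target trials, FA on right-target trials. The mapping is symmetric
under relabelling up to the sign of d'. Correction trials and misses
are excluded so repeated placements cannot bias the index.

Extreme rates are handled by log-linear (add one half) clamping:
H = (hits + 1/2) / (n_signal + 1), which keeps d' finite and is less
biased at small n than substituting 1/(2N).

Reach scatter is the mean Euclidean distance over all unordered pairs
of touch positions, reported in millimetres. For an isotropic Gaussian
scatter with axis spread sigma the expectation is sigma * sqrt(pi)
(the mean norm of a difference of two independent isotropic Gaussians),
which makes the programmed scatter of the synthetic subject directly
recoverable.
"""

from __future__ import annotations

import math
from typing import Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel
from scipy import stats
from scipy.spatial.distance import pdist

from .core import ScreenGeometry, SessionRecord, TrialOutcome, TrialRecord


class InsufficientDataError(ValueError):
    pass


class SessionMetrics(BaseModel):
    """Per-session summary statistics."""

    n_correct: int
    n_incorrect: int
    n_miss: int
    n_truncated: int
    n_uncued: int
    H: Optional[float] = None
    FA: Optional[float] = None
    dprime: Optional[float] = None
    engagement: Optional[float] = None
    mean_pairwise_dist_mm: Optional[float] = None
    reward_total_ul: float = 0.0


class CriterionRule(BaseModel):
    """A phase-advancement rule over a series of sessions."""

    kind: Literal["reward_count", "dprime"]
    threshold: float
    consecutive_sessions: int = 1


def dprime(H: float, FA: float) -> float:
    """d' = (Z(H) - Z(FA)) / sqrt(2).

    Requires rates strictly inside (0, 1); pass counts through
    :func:`rates_from_counts` first to get clamped rates.
    """
    if not (0.0 < H < 1.0) or not (0.0 < FA < 1.0):
        raise ValueError(
            f"H and FA must lie strictly in (0, 1), got H={H}, FA={FA}; "
            "use rates_from_counts for clamped rates"
        )
    return float((stats.norm.ppf(H) - stats.norm.ppf(FA)) / math.sqrt(2.0))


def _is_left_response(tr: TrialRecord) -> bool:
    # left response = correct on a left target, or incorrect on a right target
    return (tr.target_side == "left") == (tr.outcome is TrialOutcome.CORRECT)


def rates_from_counts(trials: Sequence[TrialRecord]) -> tuple[float, float]:
    """Clamped (H, FA) from a 2AFC trial log, left target as signal.

    Correction trials and misses are excluded; rates use the log-linear
    correction (x + 1/2) / (n + 1).
    """
    scored = [
        tr for tr in trials
        if not tr.is_correction
        and tr.target_side in ("left", "right")
        and tr.outcome in (TrialOutcome.CORRECT, TrialOutcome.INCORRECT)
    ]
    left = [tr for tr in scored if tr.target_side == "left"]
    right = [tr for tr in scored if tr.target_side == "right"]
    if not left or not right:
        raise InsufficientDataError(
            "need at least one left-target and one right-target scored trial "
            f"(got {len(left)} left, {len(right)} right)"
        )
    hits = sum(1 for tr in left if _is_left_response(tr))
    fas = sum(1 for tr in right if _is_left_response(tr))
    H = (hits + 0.5) / (len(left) + 1)
    FA = (fas + 0.5) / (len(right) + 1)
    return H, FA


def engagement(trials: Sequence[TrialRecord], include_corrections: bool = True) -> float:
    """Responses / cued trials.

    Cued trials are those that reached a full stimulus window (correct,
    incorrect or miss); truncated trials are excluded. Correction trials
    are included by default (flag to exclude).
    """
    cued = [
        tr for tr in trials
        if tr.outcome in (TrialOutcome.CORRECT, TrialOutcome.INCORRECT, TrialOutcome.MISS)
        and (include_corrections or not tr.is_correction)
    ]
    if not cued:
        raise InsufficientDataError("no cued trials")
    responded = sum(1 for tr in cued if tr.outcome is not TrialOutcome.MISS)
    return responded / len(cued)


def sessions_to_criterion(values: Sequence[float], rule: CriterionRule) -> Optional[int]:
    """First 1-based session index at which the rule is met, else None.

    ``reward_count``: the first index i such that the last
    ``consecutive_sessions`` values through i all exceed the threshold.
    ``dprime``: same windowed scan (the shipped d' rule uses a window
    of 1, i.e. the first session with d' above threshold).
    """
    if rule.threshold <= 0:
        raise ValueError("criterion threshold must be > 0")
    if rule.consecutive_sessions < 1:
        raise ValueError("consecutive_sessions must be >= 1")
    k = rule.consecutive_sessions
    run = 0
    for i, v in enumerate(values, start=1):
        run = run + 1 if v > rule.threshold else 0
        if run >= k:
            return i
    return None


def mean_pairwise_distance(points_px: Sequence[tuple[float, float]],
                           screen: ScreenGeometry) -> float:
    """Mean Euclidean distance over all unordered pairs, in millimetres.

    Pixel coordinates are converted to mm per axis before the distance,
    so anisotropic pixel pitch cannot distort the metric.
    """
    pts = np.asarray(points_px, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise InsufficientDataError(
            f"need at least 2 points, got {0 if pts.ndim != 2 else pts.shape[0]}"
        )
    mm = np.column_stack([
        pts[:, 0] / screen.px_per_mm_x,
        pts[:, 1] / screen.px_per_mm_y,
    ])
    return float(pdist(mm).mean())


def bootstrap_ci(
    values: Sequence[float],
    n_samples: int = 10_000,
    replicate_size: int = 50,
    level: float = 0.95,
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, float, float]:
    """Mean with a bootstrapped confidence interval.

    Each bootstrap sample is the mean of ``replicate_size`` draws with
    replacement from ``values``; the CI is the (1-level)/2 and
    1-(1-level)/2 percentiles of the ``n_samples`` sample means.
    Deterministic under a fixed generator.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise InsufficientDataError("bootstrap_ci requires non-empty input")
    rng = rng or np.random.default_rng()
    draws = rng.choice(vals, size=(n_samples, replicate_size), replace=True)
    means = draws.mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(vals.mean()), float(lo), float(hi)


def response_points(rec: SessionRecord, relative_to_target: bool = False,
                    side: Optional[str] = None) -> list[tuple[float, float]]:
    """Touch positions of responded trials, in pixels.

    With ``relative_to_target`` the centre of the *touched* region
    (target on correct trials, distractor on incorrect ones) is
    subtracted, so all touches pool into a single scatter cloud around
    their aimed centre (absolute 2AFC positions are bimodal across
    left/right placements and would measure screen geometry, not reach
    spread).
    """
    from .protocols import TrialPlan, make_region_map
    from .core import ProtocolConfig

    cfg = ProtocolConfig(**{
        k: v for k, v in rec.protocol_params.items()
        if k in ProtocolConfig.model_fields
    })
    pts = []
    for tr in rec.trials:
        if tr.response_xy is None:
            continue
        if side is not None and tr.target_side != side:
            continue
        x, y = tr.response_xy
        if relative_to_target:
            plan = TrialPlan(target_side=tr.target_side, iti_duration=0.0, go=tr.go)
            try:
                rmap = make_region_map(rec.protocol_name, plan, cfg, rec.screen)
            except (KeyError, ValueError):
                # log does not match a shipped layout; fall back to the
                # screen centre as the common reference
                rmap = make_region_map(
                    "single_target", plan, cfg, rec.screen
                )
            if tr.outcome is TrialOutcome.INCORRECT and rmap.distractor_region is not None:
                region = rmap.distractor_region
            else:
                region = rmap.target_region or rmap.distractor_region
            x -= region.x + region.w / 2.0
            y -= region.y + region.h / 2.0
        pts.append((x, y))
    return pts


def session_metrics(rec: SessionRecord,
                    include_corrections_in_engagement: bool = True) -> SessionMetrics:
    """Compute the full per-session summary.

    H/FA/d' are populated only when the log supports them (a 2AFC
    session with scored trials on both sides); reach scatter uses
    target-relative response offsets pooled over sides.
    """
    counts = rec.outcome_counts()
    H = FA = dp = None
    try:
        H, FA = rates_from_counts(rec.trials)
        dp = dprime(H, FA)
    except InsufficientDataError:
        pass
    try:
        eng = engagement(rec.trials, include_corrections_in_engagement)
    except InsufficientDataError:
        eng = None
    pts = response_points(rec, relative_to_target=True)
    try:
        dist = mean_pairwise_distance(pts, rec.screen)
    except InsufficientDataError:
        dist = None
    return SessionMetrics(
        n_correct=counts["correct"],
        n_incorrect=counts["incorrect"],
        n_miss=counts["miss"],
        n_truncated=counts["truncated"],
        n_uncued=sum(tr.uncued_touch_count for tr in rec.trials),
        H=H, FA=FA, dprime=dp, engagement=eng,
        mean_pairwise_dist_mm=dist,
        reward_total_ul=sum(tr.reward_volume_ul for tr in rec.trials),
    )


def scatter_shift_test(early_points_mm: Sequence[float],
                       late_points_mm: Sequence[float]) -> tuple[float, float]:
    """Rank-sum comparison of early vs late pairwise-distance samples.

    Returns (statistic, p-value) of the Wilcoxon rank-sum test on the
    two within-session pairwise-distance populations.
    """
    res = stats.ranksums(np.asarray(early_points_mm), np.asarray(late_points_mm))
    return float(res.statistic), float(res.pvalue)


def learning_curve(sessions: Sequence[SessionRecord]):
    """Per-session metrics table (one row per session, in order)."""
    import pandas as pd

    rows = []
    for i, rec in enumerate(sessions, start=1):
        m = session_metrics(rec)
        rows.append({
            "session": i,
            "session_id": rec.session_id,
            "protocol": rec.protocol_name,
            "n_trials": len(rec.trials),
            "n_correct": m.n_correct,
            "n_incorrect": m.n_incorrect,
            "n_miss": m.n_miss,
            "n_uncued": m.n_uncued,
            "H": m.H,
            "FA": m.FA,
            "dprime": m.dprime,
            "engagement": m.engagement,
            "mean_pairwise_dist_mm": m.mean_pairwise_dist_mm,
            "reward_total_ul": m.reward_total_ul,
        })
    return pd.DataFrame(rows)
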