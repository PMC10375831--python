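# Methods

This note documents the behavioural model the engine implements, the
defaults and why they were chosen, what the simulated subject does and
does not emulate, and the numerical choices that affect results.

## Trial state machine

A trial is a deterministic walk over phases, driven entirely by event
timestamps (never by wall-clock reads, so accelerated and realtime
clocks produce identical records):

```
trial_start ── ITI ──> stimulus ──> {correct → reward delay,
                                     incorrect → (optional timeout),
                                     miss} ──> trial_end
```

* **Uncued touches.** A `down` contact during the ITI fires
  `on_uncued` and restarts a *full* ITI of the same planned duration.
  We deliberately re-use the planned duration rather than redrawing:
  redrawing would couple the subject's behaviour to the RNG stream and
  break replay determinism. A `iti_reset_redraw` flag provides the
  alternative. Uncued touches and misses are never punished; a
  configurable punishment timeout exists and defaults to 0 s.
* **Classification.** Only `down` events classify; drag (`move`) and
  release (`up`) samples are logged but ignored. The first qualifying
  `down` wins; ties at identical timestamps resolve by stream order.
  Dead-zone and off-region contacts are ignored without ending the
  trial. Contacts during the reward delay are logged and ignored
  (whether they should reset anything is left open by the task
  definition; ignoring is the least surprising choice).
* **Correction trials.** With corrections enabled, an incorrect 2AFC
  choice makes the next plan a correction: same placement, fresh ITI
  draw, side planner bypassed. A miss during a correction keeps the
  chain alive — we read a miss as a non-response, not a resolution —
  and only a correct response ends it. The flag is stored per trial so
  analytics can exclude corrections without re-deriving chains.
* **Session expiry.** A trial still unresolved at
  `session_duration_s + grace_s` (grace defaults to 0) is aborted and
  marked `truncated`; a trial whose classification landed before the
  deadline keeps its outcome even if its reward delay is clipped.
* **Go/NoGo.** Go and NoGo trials alternate through the same balanced
  block planner (50/50; the ratio is not otherwise specified anywhere
  authoritative). Withholding for the whole stimulus window on a NoGo
  trial is a correct rejection: outcome `correct`, no response fields,
  and the reward is dispensed — the record invariant "reward iff
  correct" is kept uniform across protocols.

## Geometry

The default screen maps 800×480 logical pixels onto a 97×58 mm panel
(a compact integrated touchscreen of the kind used in mouse arenas;
the resolution is a package default, the physical size matches the
panel class). Coordinates are 0-based, origin top-left, half-open
ranges, matching mainstream touch APIs. mm↔px conversion is per-axis
(`width_px/width_mm`, `height_px/height_mm`) and rounds to the nearest
pixel; pairwise distances convert points to mm per axis *before*
taking norms so anisotropic pixel pitch cannot distort them. The 2AFC
dead zone is a centred strip of width `mm_to_px(dead_zone_mm)` (82 px
for 10 mm at the default geometry), flanked by equal-width choice
regions.

## Stimuli

The drifting grating is
`L(x,y,t) = L0 · (1 + c · sin(2π(f_s·x′ − f_t·t)))`, clipped to [0,1],
with `x′` the position along the orientation axis in *degrees* of
visual angle (`px / px_per_degree`). Orientation 0° means vertical
bars drifting horizontally, aligned with the left/right choice axis.
Because a freely moving mouse has no fixed viewing distance,
`px_per_degree` is an explicit nominal config (default 10 px/deg)
rather than a derived quantity. Mean luminance defaults to 0.5 so that
100 % contrast spans [0,1] exactly; the isoluminant gray distractor is
a uniform field at the grating's mean, so brightness alone cannot
guide choice. The default grating preset is 100 % contrast, 1 Hz
drift, 30 cyc/deg; 30 cyc/deg is far above the mouse acuity limit and
will alias at the default pixel scale — the number is implemented as
configured and its interpretation is left to the user. Image stimuli
are loaded once, converted to [0,1] luminance, and letterboxed into
their region with preserved aspect.

## Analytics

* **d′** = (Z(H) − Z(FA))/√2. The side-choice task needs an
  operational H/FA convention: we designate *left targets as signal*,
  so H is the left-response rate on left-target trials and FA on
  right-target trials. The mapping is symmetric under relabelling up
  to the sign of d′. Correction trials and misses are excluded.
* **Rate clamping.** Log-linear `(x + ½)/(n + 1)` rather than the
  `1/(2N)` substitution: it keeps d′ defined at extreme counts and is
  less biased at small n, and it makes the expected d′ of a symmetric
  responder with accuracy *a* exactly
  `(Z(a′) − Z(1 − a′))/√2` with `a′ = (n·a + ½)/(n + 1)` — the closed
  form the recovery tests use.
* **Engagement** = responses / cued trials (correct + incorrect +
  miss); truncated trials are excluded. Correction trials are included
  by default (they are real cued trials the subject worked through); a
  flag excludes them.
* **Reach scatter** = mean Euclidean distance over all unordered pairs
  of touch positions, in mm. Session-level scatter uses offsets
  relative to the centre of the *touched* region pooled over sides;
  absolute 2AFC positions are bimodal across left/right placements and
  would measure screen geometry, not reach spread. For isotropic
  Gaussian scatter with axis spread σ the expectation is σ√π.
* **Criterion rules** scan a session series for the first index where
  the last *k* values all exceed the threshold (strictly), covering
  both the ">70 rewards for 2 consecutive sessions" shaping rule and
  the "d′ > 1.5" discrimination rule (k = 1).
* **Bootstrap CIs**: each of 10,000 bootstrap samples is the mean of
  50 draws with replacement; the CI is the 2.5/97.5 percentile of the
  sample means. With replicate size fixed at 50 the half-width is
  ≈1.96·sd/√50 regardless of input length — it characterises the
  statistic, not the n.
* The early-vs-late scatter comparison uses a Wilcoxon rank-sum test
  on the two pairwise-distance populations; the choice of test for
  this comparison is not standardised in the literature, so the
  default is the least parametric common option.

## The simulated subject

The agent closes the loop through the same device interface a real
touchscreen driver would use: the runner publishes each phase (and the
current region map) and the agent answers with timed touch events. It
is deliberately *memoryless within a session* so closed forms stay
exact; learning lives in between-session parameter ramps.

Per cued trial: respond with probability `p_respond`; a response aims
at the target centre with probability `accuracy`, else the distractor
centre, jittered by isotropic Gaussian scatter (`touch_scatter_sd_mm`,
converted to px per axis, clipped to the screen) at a truncated-normal
latency (> 0.05 s). Spontaneous ITI contacts form a Poisson process
(`uncued_rate`), uniformly placed — each one genuinely resets the ITI,
so the closed loop is exercised, not simulated away. On NoGo trials
the agent touches with probability `p_respond·(1 − accuracy)`.
Response side is independent of target side given accuracy (no side
bias by default); a `side_bias` parameter exists to exercise the
clamping path.

Defaults describe a naive mouse entering shaping and were chosen once
to emulate the magnitudes seen in real training curves: `p_respond`
0.35 ramping by 0.15/session to 0.95 (low initial engagement rising to
the >90 % typical of water-restricted subjects), `accuracy` 0.55
ramping by 0.06/session to 0.97 (chance-ish discrimination crossing
the d′ = 1.5 level a handful of sessions into the 2AFC phase),
`uncued_rate` 0.02 events/s, latency 1.0 ± 0.5 s, scatter 3.6 mm
(giving ≈6.4 mm mean pairwise distance early in reaching) shrinking by
×0.9 per *reaching* session (ending near 3 mm after eight sessions).
Scatter shrinkage applies only in sessions tagged
`response_modality: reaching` because reach stereotypy is a motor-
learning phenomenon of the reaching phase; nose-poke scatter is held
constant. The agent is not a biomechanical or reinforcement-learning
model, and no parameter was fitted to published animal data: the
curriculum reproduces the *shape* of learning (rewards up, misses
down, d′ crossing its criterion, scatter shrinking), not any animal's
numbers — which is also exactly what passing tests demonstrate about
real data: the procedures are correct, not that mice behave like the
agent.

## Sessions, determinism, decoupling

All within-session times are float seconds from session start; the
single wall-clock anchor is an ISO-8601 string in metadata. With a
fixed config seed and a fixed agent/script, records are byte-identical
apart from that anchor and the session id (both injectable). The
accelerated clock jumps to the next scheduled event, so a 30-minute
session runs in milliseconds; the realtime clock sleeps instead. Live
monitoring is pull-only: the runner appends to an observer-visible
partial log, and the stdlib-HTTP status API reads snapshots from a
thread-safe buffer, so attaching, polling or killing a consumer cannot
perturb the session (verified by diffing paired runs). An engine fault
mid-session flushes the partial record (`complete: false`) before the
error propagates.

## Export formats

JSON is canonical, human-readable and versioned (semantic versioning;
readers accept same-major files and report missing fields by JSON
pointer). HDF5 stores `/session` attributes plus columnar `/trials`
and `/events`. The NWB export writes the NWB 2.x HDF5 layout directly
with h5py — trials as an `/intervals/trials` table
(`start_time`/`stop_time`/`outcome`/`target_side`/`is_correction` plus
the remaining trial fields), subject under `/general/subject`, raw
touches under `/acquisition/touch_events`; outcomes are table columns
rather than time series since no physiology is recorded. CSV writes
one row per trial with `%.17g` floats (bit-exact round trip) plus
`_events` and `_session` sidecars; its single documented lossy field
is nested device metadata. Missing optional values map to NaN (floats)
or −1 (the tri-state go flag) and back bijectively.

## Problem sizes used in verification

The test suite and `scripts/acceptance.py` run entirely on the
accelerated clock with simulated subjects. Sizes were chosen as the
smallest that make each check statistically meaningful: an exhaustive
261-stream grid for the state-machine/oracle comparison; 1,000
randomized sessions (≤30 trials each) for the conservation and
correction-chain laws; a 99×99 (H, FA) grid at 1e-9 for d′; 10,000
draws for the ITI KS test; 2,000 points for the σ√π scatter check
(±3 Monte-Carlo SE); five 200-trial sessions per accuracy level for
d′ recovery (±0.15 of the closed form); 200 property-generated
sessions for format round-trips; and a 22-session curriculum at ≤120
trials/session for the qualitative learning-curve shape.

## Known limitations

* No rendering, display driver, gamma correction, audio, or hardware
  GPIO/serial drivers — the device interfaces are shaped so real
  drivers drop in where the simulators stand.
* No within-session learning, lapses-over-time, or motivational
  dynamics in the agent; no multi-animal interleaving in a session.
* The NWB writer targets the common 2.x core layout; files carry the
  standard structure but are produced without the reference validator
  in the loop.
* Timestamp fidelity claims stop at monotone, internally consistent
  session-relative times; no sub-millisecond synchronisation is
  attempted or tested.
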