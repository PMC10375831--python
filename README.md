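# touchtask

A headless, extensible engine for touchscreen operant-conditioning tasks
in rodents: trial-structured visual tasks with pluggable stimuli,
protocols and devices, deterministic session logging with JSON / CSV /
HDF5 / NWB export, signal-detection analytics, and a closed-loop
simulated subject so the entire system runs — and is tested — without
animals or hardware.

## Who this is for

Touchscreen assays (stimulus → screen contact → reward) are a standard
tool for probing perception, decision-making and sensorimotor learning
in mice. Rig software for these tasks is usually entangled with its
display and GPIO hardware, which makes the *behavioural logic* —
exactly the part that determines what the animal experienced — hard to
test. `touchtask` inverts that: the trial state machine, the stimuli,
the analytics and the data formats are a pure library, and hardware
(or a simulated mouse) plugs in behind narrow device interfaces.

## The task model

A session is a loop of trials until the configured duration expires.
Each trial is an explicit phase timeline:

1. **ITI** — blank screen for a fixed or uniformly drawn interval
   (e.g. 3 s for shaping; 4–6 s for the 2AFC task). Any contact is an
   *uncued touch*: it is logged and restarts a full ITI, and is never
   otherwise punished.
2. **Stimulus** — e.g. a full-contrast drifting grating (1 Hz,
   30 cyc/deg) for up to 10 s. The first `down` contact in the target
   region is **correct** (10 µl reward, then a 1 s consumption delay);
   in the distractor region, **incorrect**; in the central 10 mm *dead
   zone* or off-region, ignored. No contact at all is a **miss**
   (unpunished).
3. In the 2AFC task an incorrect choice makes the next trial a
   **correction trial** — the same placement repeats until a correct
   response — preventing side bias; correction trials are flagged and
   excluded from d′.

Shipped protocols: `single_target` (shaping), `twoafc` (grating vs an
isoluminant gray distractor on pseudo-randomly ordered sides, balanced
in blocks of two), `gonogo` (withholding on distractor-only trials is
the rewarded correct rejection).

Discrimination is summarised with the signal-detection index

$$d' = \frac{Z(H) - Z(FA)}{\sqrt{2}}$$

where $Z$ is the standard-normal quantile, $H$ the left-response rate
on left-target trials and $FA$ on right-target trials, with log-linear
$(x + \tfrac12)/(n+1)$ clamping. Reach stereotypy is quantified as the
mean pairwise distance (mm) between touch positions; engagement as
responses / cued trials; summary statistics carry bootstrapped 95 % CIs
(10,000 samples, 50 replicates per sample).

## Worked example

A 30-minute 2AFC session with a well-trained simulated subject, on the
accelerated clock (finishes in well under a second of wall time):

```python
from touchtask import (ProtocolConfig, run_session, AcceleratedClock,
                       AgentParams, SyntheticAgent)
from touchtask.analytics import session_metrics

cfg = ProtocolConfig(session_duration_s=1800, iti_range_s=(4, 6),
                     dead_zone_mm=10, corrections_enabled=True, rng_seed=7)
agent = SyntheticAgent(AgentParams(p_respond=0.95, accuracy=0.9, seed=7))
rec = run_session(cfg, "twoafc", agent, clock=AcceleratedClock())
m = session_metrics(rec)
print(f"trials={len(rec.trials)} correct={m.n_correct} "
      f"incorrect={m.n_incorrect} miss={m.n_miss}")
print(f"H={m.H:.3f} FA={m.FA:.3f} dprime={m.dprime:.2f} "
      f"engagement={m.engagement:.3f}")
print(f"scatter={m.mean_pairwise_dist_mm:.2f} mm reward={m.reward_total_ul:.0f} ul")
```

prints

```
trials=258 correct=217 incorrect=25 miss=15
H=0.888 FA=0.117 dprime=1.70 engagement=0.942
scatter=6.40 mm reward=2170 ul
```

i.e. 258 trials fit the half hour, the subject discriminated well above
the d′ = 1.5 criterion, responded on 94 % of cued trials, collected
2.17 ml of water, and its touch positions scattered 6.4 mm apart on
average (its programmed 3.6 mm spread × √π).

The same thing from the shell, plus format conversion and analytics:

```sh
touchtask run --preset phase2_2afc --out sessions --seed 7
touchtask export sessions/<id>.json --to nwb
touchtask simulate --out course --seed 1          # full 3-phase curriculum
touchtask analyze course/*.json --out metrics.csv --plot curves.png
touchtask validate-config my_protocol.yaml
```

`simulate` runs the shipped training course — Phase I shaping, Phase II
2AFC nose poke, Phase III 2AFC reaching — with a learning agent whose
response probability and accuracy ramp between sessions and whose reach
scatter shrinks during the reaching phase; `analyze` renders the
resulting learning curves (rewards rising past the >70-rewards
criterion, misses falling, d′ crossing 1.5, pairwise distance
shrinking).

## Layout

| module | contents |
|---|---|
| `touchtask.core` | data model (events, trials, sessions, config), mm↔px |
| `touchtask.stimuli` | drifting gratings, solids, images; lifecycle + registry |
| `touchtask.protocols` | trial state machine, region maps, samplers, 3 protocols |
| `touchtask.devices` | input/output contracts, scripted touch source, simulated dispenser, sync stub |
| `touchtask.runner` | clocks (realtime / accelerated), session loop, live snapshots |
| `touchtask.io_export` | canonical JSON schema; CSV / HDF5 / NWB exporters + readers |
| `touchtask.analytics` | d′, engagement, criterion rules, pairwise distance, bootstrap CIs |
| `touchtask.agent` | closed-loop simulated subject and training curriculum |
| `touchtask.cli`, `touchtask.service` | `touchtask` CLI and read-only HTTP status API |

Design notes, parameter defaults and known limitations are documented
in [`docs/methods.md`](docs/methods.md).
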