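# atcgaze

Eye-tracking analytics for simulated en route air-traffic control: session-level
mental-workload (MWL) indices from ocular behavior, and gaze–action coupling
around scripted loss-of-separation conflicts.

The package is written for human-factors researchers who run radar-scope
simulator studies with a remote eye tracker and want a tested, scriptable
implementation of the full analysis chain — plus a synthetic study generator so
every stage can be exercised end to end without access to raw recordings.

## What it computes

**Gaze events.** From a 30 Hz sample stream (per-eye validity, screen position
in cm, per-eye pupil diameter), blinks are maximal runs of *simultaneous*
two-eye data loss whose duration lies in the closed band 100–600 ms (longer
runs are track loss), and fixations come from the dispersion-threshold (I-DT)
algorithm: a window of consecutive tracked samples grows while its maximum
pairwise extent stays within 1° of visual angle, and is emitted once it spans
at least 100 ms. The angular bound is applied in screen units through
θ = 2·atan(extent / 2d): at d = 60 cm the 27.5 × 20.5 cm active sector subtends
25.81° × 19.39°, and 1° is 1.047 cm.

**AOI accounting.** Fixations are tallied over a three-region static partition
of the 61 × 34 cm display (central active sector, top-right flight-plan sheet,
out-of-sector remainder) and over dynamic AOIs — equal-sized rectangles that
translate with each aircraft's projected position. Trailing 10 s sliding
windows give per-aircraft attention-share time series.

**Workload statistics.** Per participant × condition sessions (2 traffic ×
3 complexity within-subject design): mean pupil diameter, blink count and mean
duration, AOI fixation times/counts, the mean of eight ISA ratings (1–7) and
the raw NASA-TLX sum (6–120). Effects are tested with 2 × 3 repeated-measures
ANOVAs (Mauchly sphericity check, Huynh–Feldt correction, partial η²),
Bonferroni-adjusted pairwise follow-ups, and Spearman correlations of the six
condition means.

**Conflict detection & resolution.** Separation is lost when two aircraft are
simultaneously closer than 5 NM laterally and 1,000 ft vertically; a scripted
conflict is *solved* when the participant's clearances (altitude changes at a
finite climb/descent rate, proportional speed changes) keep separation intact
on a 1 s grid for the whole scenario. Solver vs non-solver contrasts use
Mann–Whitney U; the contribution of gaze and intervention variables to success
is assessed with a forward-stepwise (score-test entry, Wald removal) binomial
logistic regression reporting McFadden R² and VIF.

**Synthetic study.** `atcgaze.simulate` generates the whole 24-participant
study: six 960 s scenarios (the 12-aircraft high-complexity one embeds an Easy
two-aircraft conflict violating separation at 140 s and a Difficult
three-aircraft conflict violating at 240 s, both placed by a conflict
scheduler and verified by the separation checker), renewal-process gaze streams
with condition-dependent pupil baselines, blink statistics and attention
weights, intervention logs that verifiably solve or fail each conflict, and
subjective scores.

## Worked example

```bash
python examples/02_conflict_simulation.py
```

```
aircraft in scenario: 12
easy conflict ('POB456', 'HYG532'): first loss of separation at 140 s if unresolved
difficult conflict ('REV756', 'KET456', 'GPL751'): first loss of separation at 240 s if unresolved

with an altitude clearance on HYG532 at t=80 s: easy conflict solved = True
with the same clearance issued at t=300 s (after the violation): solved = False
```

The two scripted conflicts lose separation exactly at their programmed times
when left unresolved; an altitude clearance on the climbing aircraft issued
before closure restores the 1,000 ft margin, while the same clearance after
the violation cannot change the outcome. The other examples cover event
detection (`01`), workload statistics (`03`) and solver inference (`04`);
for instance `04` prints

```
easy conflict: 3 solvers, 9 non-solvers
  total_time_s         solved  33.24 vs unsolved  16.37  (U = 27, p = 0.0091)
  altitude_HYG532      solved   1.00 vs unsolved   0.00  (U = 27, p = 0.0014)
```

— solvers accumulate roughly twice the fixation time on the converging pair
before the violation and are the only group issuing the altitude clearances
that resolve it.

A thin CLI wraps the same pipeline (`atcgaze simulate | events | aoi |
workload | cdr | all`); see `atcgaze --help`.

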