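# Methods

## Track metrics and the behavior rule set

A track is the timed planar trajectory of one cell within one field of
view (FOV). Coordinates are micrometres from maximum-intensity-projection
movies; a `z_um` column, if present in an export, is read and ignored with
a warning because projected data carries no usable depth. Time is seconds
from movie start; when an export carries frame indices instead, the reader
requires an explicit frame interval — intravital frame rates vary between
rigs, so no default is assumed.

**Track speed mean** is defined as path length divided by track duration.
This equals the unweighted mean of per-step speeds only for evenly spaced
frames; the duration-weighted form is used because it is robust to dropped
frames and is applied identically to real and synthetic tables. An exact
identity test (`speed == Σ(vᵢΔtᵢ)/ΣΔtᵢ`) pins this definition down.

**Single-point tracks** have zero duration and an undefined speed. They are
retained by the readers but excluded from metric and classification stages
with a logged count; no minimum track length beyond two points is imposed.

**Classification** uses only duration `D` and mean speed `v̄`, evaluated in
the order tethering → adherent → crawling → patrolling:

| order | class | rule (defaults) |
|---|---|---|
| 1 | tethering | `D < 150 s` |
| 2 | adherent | `v̄ ≤ 0.03 μm/s` |
| 3 | crawling | `D ≥ 600 s` |
| 4 | patrolling | otherwise |

The published verbal rules leave the boundary equalities open and overlap
for short slow tracks. The conventions chosen here: `D = 150 s` is not
tethering ("under" read strictly), `v̄ = 0.03 μm/s` is adherent (the rule
is printed with ≤), and `D = 600 s` is crawling (ties to the more
persistent class). The ordered tree makes the rule set total — every
(duration, speed) pair receives exactly one class — and the test suite
checks 100% agreement with an independently coded predicate table,
including these boundaries. Narrative cues about entering or leaving the
FOV are treated as descriptive, not as extra predicates. The 600-s crawling
cut corresponds to half of a 20-min movie; thresholds are a dataclass, so a
1-h macrophage movie uses `long_duration_s=1800`.

## Synthetic movies

Each mode is a correlated random walk: step lengths are gamma-distributed
(positive, unimodal) with mean `speed × Δt` and configured spread; headings
evolve by wrapped-normal turning with standard deviation `π(1 − p)` for
persistence `p` (p = 0 falls back to uniform re-orientation, p = 1 is a
straight line). Track lifetime is uniform on the mode's duration range, and
the start time is placed uniformly so the track fits in the movie. Arrested
modes (adherent, crawling) reflect at the FOV borders; transiting modes
(patrolling, tethering) are clipped to the border and terminated once past
their minimum lifetime, emulating FOV exit. One top-level seed spawns an
independent substream per (mode, track index), so changing one mode's count
never perturbs other tracks.

Defaults: frame interval 10 s and a 400 × 400 μm FOV (order-of-magnitude
realistic for a 20× objective); mode presets adherent 0.005 μm/s at
1000–1200 s, crawling 0.12 μm/s at 700–1100 s, patrolling 0.15 μm/s at
200–500 s, tethering 0.2 μm/s at 60–120 s. These are deliberately well
separated from the classifier cuts: passing recovery tests demonstrates
that the pipeline wiring is correct, *not* that the classifier would
resolve real tracks whose metrics sit near the thresholds. Real intravital
data also contains tracking errors, gaps and within-track behavior
switches that the generator does not emulate.

The three-arm preset (control / exposure / ablated) encodes only the
qualitative structure used by the integration test: the exposure-like arm
has the most tracks, mostly arrested; the ablated-like arm has fewer but
faster motile tracks, hence a higher median total displacement. These
orderings are properties of the configuration, not biological claims.

## Calcium trace scoring

Traces are F340/F380 ratio series sampled every 3–4 s. All scoring runs by
default on the 15-s maximum-compressed trace (half-open bins
`[k·15, (k+1)·15)`, timestamps at bin start, empty bins omitted), matching
how such recordings are condensed for evaluation; a flag scores the raw
trace instead. Compression is idempotent by construction.

**Amplitude** = peak ratio over `[window start, window end + pad]` divided
by the mean ratio over the 30 s before stimulation. Two points were
genuinely open and are fixed as documented choices rather than guesses at
authorial intent:

- *Baseline* is the mean (not an instantaneous value) over the 30-s
  pre-stimulus interval — noise-robust and well-defined at any sampling
  phase.
- *Peak search* extends 30 s past the window end (calcium peaks can lag
  washout), capped at the next stimulus onset; configurable.

For an ascending concentration series delivered back-to-back (windows
sharing edges, as in a 10/30/100 μM agonist series), every window of the
series is scored against the single baseline preceding the first window,
since later windows have no clean local baseline.

**Responder threshold**: no numeric criterion is published; the default is
amplitude ≥ 1.2 (a 20% rise over baseline), exposed as `--threshold`, and
the CLI writes a small threshold-sensitivity table (±10% around the chosen
threshold) alongside the responder fractions so the dependence of the
readout on this choice is always visible. Cells enter denominators only if
they respond to the terminal KCl depolarization (viability gate); a
protocol without a KCl window is a configuration error when gating is on.

**Aggregation**: per-dish mean amplitude is computed over responders only
(dishes with zero responders are excluded with a warning); per-dish
responder fractions are computed among KCl-included cells and normalized to
the mean vehicle fraction of the same batch, which makes the vehicle mean 1
by construction.

## Synthetic traces

A simulated neuron is baseline level plus i.i.d. Gaussian noise; each true
response adds a transient that rises linearly across the stimulus window to
`baseline × (amplitude − 1)` and decays exponentially afterwards — the
simplest shape whose peak lands inside the search window, making noise-free
recovery exact to floating precision. Defaults: baseline ratio 0.8, noise
SD 0.03, decay τ 20 s, 3-s sampling, KCl responder rate 0.95, amplitude
1.5 (KCl 2.0) — plausible Fura-2 ratio scales, all configurable. The
generator records per-cell, per-window truth labels. It does not emulate
photobleaching, baseline drift, or dose-dependent amplitudes across a
concentration series, so recovery results quantify the scoring logic, not
robustness to those artifacts.

## Statistics

"Nested" comparison of neurons within dishes is implemented as dish-mean
aggregation followed by ordinary one-way ANOVA on the dish means — the
reading consistent with plotting per-dish averages; a full mixed model is
out of scope. The F statistic is computed from the classical
between/within sums of squares and the t statistic from the pooled-variance
formula (Welch available by flag), with p-values from the corresponding
scipy distributions; the test suite cross-checks both against
`scipy.stats.f_oneway` / `ttest_ind` to 1e-10 on random designs, keeping
implementation and oracle separate. Bonferroni multiplies each pairwise
Student-t p-value by the number of comparisons (capped at 1); Tukey's HSD
delegates to the studentized-range implementation in scipy. SEM uses the
n−1 denominator. Degenerate inputs (a group with fewer than two values,
zero pooled variance) raise instead of returning NaN.

Reports are JSON with sorted keys and floats rounded to 10 digits, so a
rerun on identical inputs is byte-identical.

## Problem sizes

Validation runs use 400 tracks for label recovery, 100 random tracks for
invariance checks, 200 synthetic neurons for responder recovery, and 100
random designs for the statistical oracle comparisons — sizes at which the
binomial/oracle bands quoted in the tests are meaningful while the whole
suite stays interactive (a few seconds end to end).

## Known limitations

- One behavior per track: within-track switching is not modeled.
- Planar metrics only; no mean-squared-displacement or diffusion fitting.
- The responder criterion is a documented default, not a published value;
  conclusions sensitive to it should consult the sensitivity table.
- The synthetic generators validate pipeline correctness, not performance
  on tracking artifacts or drifting baselines.
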