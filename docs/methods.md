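# Methods

This note documents the models, conventions and numerical choices behind
`freezekit`, in the order data flows through the pipeline.

## Protocol schedules

All sessions last 1020 s. A tone block (CS) is 30 beeps of 100 ms at a
1 s period (7 kHz, 80 dB SPL, 5 ms rise time; 2 ms available as an
override for early-experiment configurations), giving a nominal 30-s
block. Foot shocks (US) last 1 s at 0.6 mA in the short protocols and
0.4 mA in the prolonged ones. Event times are continuous seconds from
session onset and every interval is half-open `[start, end)`.

**"End of CS" convention.** The CS-end→US interval is measured from the
*onset of the last beep* (block start + 29 s for the default block), not
from the end of the last beep or the nominal block end. This is the only
convention under which the tabulated short-protocol event times yield the
published interval column [55, 35, 75, 45, 25, 65] s, so it is adopted
throughout. For paired (fear) training, the shock instead starts at the
*offset* of the last beep (start + 29.1 s), which is the physical "end of
the tone".

**Prolonged protocols.** The two-training-session variants keep the same
structural rules — five shocks, CS-end→US intervals drawn from [25, 75] s,
a constant 60 s US-offset→CS gap — but their exact event times are not
tabulated anywhere. They are generated deterministically from a seed (an
integer-valued jitter per interval, default seed 73, configurable), with
the two training sessions of one protocol receiving different draws.

The variant set covers every cohort the analysis needs, including
`us_only_fear` (US-only training at the tabulated US times, recall in the
novel context B): that cohort is required for the pooled
external-inhibition analysis (its recall is the only low-contextual-
freezing condition among the US-only controls).

## Movement index and freezing classification

The optional video front-end computes the standard frame-differencing
measure: index\[t\] = number of pixels whose absolute intensity change
from frame t−1 exceeds a per-pixel cutoff; frame 0 has no predecessor and
is assigned 0. The scale is arbitrary units; only relative behavior is
asserted, and the cutoff should be chosen so traces straddle the
classifier threshold.

Freezing: a sample is frozen iff it belongs to a maximal run of samples
with index **strictly below** 40 a.u. whose duration is at least 0.5 s.
Boundary choices, each stated because the alternative is defensible:

* samples exactly at the threshold are *moving* (literal "below");
* the minimum run length in samples is `ceil(0.5 × rate)` — exactly 15 at
  30 Hz;
* runs touching the trace boundaries are eligible;
* a trailing partial bin in the 10-s binning is normalized by its own
  sample count and flagged, not dropped.

## Startle correction

A candidate is a maximal run of supra-threshold samples. It is a startle
event iff its first sample lies within `[beep_onset, beep_onset + 0.2 s]`
(both endpoints inclusive — "initiated within") for some beep, and its
duration is strictly below 0.9 s ("shorter than"). A run already ongoing
at beep onset was not initiated by it and never qualifies. If several
beeps could claim one run (impossible at the standard 1 Hz beep period,
possible in custom configurations) the earliest qualifying beep does.

Blanking writes index 0 — not threshold − ε — over the event samples that
fall inside 30-s CS periods, so downstream classification is independent
of the threshold value; samples outside CS periods are never modified.
Re-classifying the blanked trace merges the freezing runs flanking each
blanked span, with the minimum-duration rule applied to the merged run.
Consequences used as test invariants: corrected CS freezing ≥ raw CS
freezing, preCS windows are bit-identical before/after, and the whole
correction is idempotent.

## Window analysis

For tone block *k*: preCS window = `[start_k − 30 s, start_k)`, CS window
= `[start_k, start_k + 30 s)`. The CS value used in all downstream
analysis is startle-corrected; the raw value is retained alongside.
preCS values are never corrected (no beeps there — the correction is
restricted to CS periods by construction). The CS-induced difference is
`corrected CS − preCS` per mouse and block; the per-mouse session summary
is the mean over all six blocks, and group summaries report mean ± SEM
(sample SD / √N) across mice. Missing windows propagate as dropped
records with a logged warning.

External-inhibition points: for each (US-only cohort, recall session,
tone block), the across-mouse mean preCS freezing is paired with the
negated across-mouse mean difference. The granularity is one point per
group-session-block (not per mouse), and the four US-only cohorts pool to
6 + 12 + 12 + 6 = 36 points; both recall sessions of the prolonged
protocols contribute. Supplying a non-US-only table is an error, since
tone-experienced cohorts would confound the readout with learned effects.

## Statistics

The two-way repeated-measures ANOVA (univariate formulation, each
within-subject factor tested against its own subject-by-factor error
term) is delegated to `pingouin.rm_anova`; the test suite checks it
against an explicit cell-mean sums-of-squares decomposition. No
sphericity correction is applied by default; Greenhouse–Geisser corrected
p-values are available behind a flag. t-tests and Shapiro–Wilk wrap
`scipy.stats`; zero-variance inputs raise instead of returning 0. All
tests are two-sided; significance stars (0.05/0.01/0.001) are
presentation-layer only.

## The behavioral simulator

A two-state (active/frozen) continuous-time Markov chain sampled at
30 Hz, the minimal generative model consistent with the phenomenology the
pipeline must handle; freezing bouts are therefore geometric-like in
duration, which is adequate because every pipeline readout is an
occupancy (no bout-duration statistic is analyzed). Transition
probabilities per step are exact, `1 − exp(−rate·dt)`.

Hazards by session phase (defaults; all rates per second):

| phase | entry (→frozen) | exit (→active) |
|---|---|---|
| habituation | 0.006 | 0.15 |
| training | 0.01 + 0.048 × shocks delivered | 0.15 |
| recall | plateau level × (1 − e^(−t/30 s)) | 0.15 |

* Training entry accumulates across sessions (prolonged protocols start
  day 2 at an elevated level), and each shock forces the active state for
  12 s (the post-shock running/jumping burst).
* The recall plateau entry level is `exit × f/(1−f)` for a target
  occupancy `f`: 70 % in the training context, 30 % residual in the novel
  context. With the 30-s entry ramp and a ~2-s relaxation time the
  occupancy reaches its plateau within ~100 s of session onset.
* During CS periods the exit hazard is multiplied by
  `1 + k·f_local + safety_effect`, where `f_local` is an exponential
  moving average of the state (30-s time constant) — external inhibition
  as freezing-level-dependent movement initiation, acting on freezing
  *interruption* rather than entry. Default slope k = 4 places the
  simulated suppression in the tens-of-percentage-points regime at high
  contextual freezing and near-nil at residual freezing, strong enough
  that the pooled 36-point correlation is recovered reliably at the
  study's cohort sizes (N = 5, 6, 6, 5). The entry hazard is multiplied
  by `learned_fear_boost` (1 by default; > 1 models CS+ recall).
* Beep-locked startles: while stably frozen (≥ 0.5 s of immobility on
  both sides), each beep triggers with probability 0.3 a supra-threshold
  transient with onset uniform in [0, 0.2] s after the beep and duration
  0.15–0.30 s. The underlying state stays frozen — the startle is a
  measurement artifact, which is exactly why the correction is justified
  in counting it as freezing. The ≤ 0.30 s duration cap guarantees that
  even consecutive beep-locked startles leave ≥ 0.5 s of immobility
  between them, so blanking arithmetic is exact under the minimum-bout
  rule.

Movement-index values are drawn per state from log-normals (frozen:
median 8 a.u., σ = 0.30; active: median 200 a.u., σ = 0.35), putting
≈ 5 log-SD between each median and the 40 a.u. threshold: per-sample
misclassification is ~10⁻⁸, so the thresholded state equals the
ground-truth state in practice. The overlap is a configuration knob for
robustness experiments.

Seeding: every quantity derives from one master seed via
`SeedSequence([master, mouse_index, session_index])`, so any single
mouse-session is reproducible in isolation. The chain inner loop is
numba-compiled with a pure-Python fallback.

## What the simulator does and does not establish

The generator reproduces the *structure* of the real data — occupancy
dynamics, event timing, artifact geometry — not its microstructure: bout
durations are memoryless, the movement index is a clean two-component
mixture without tracking noise, drift or grooming-like intermediate
values, and the inhibition mechanism is the one the analysis assumes.
Passing recovery tests therefore shows the pipeline is *correct* (it
measures what it claims to measure, to known tolerance), not that the
biological effect sizes are realistic. Published group-level values from
real recordings (e.g. a specific correlation coefficient) depend on the
deposited raw data and are deliberately not targets of the synthetic
validation; the CSV trace dialect provides the ingestion path for such
deposits.

## Validation problem sizes

The shipped checks use 1,000 random traces (≤ 3,000 samples) for the
classifier oracle; 20 sessions for the stationary-occupancy and
startle-arithmetic checks; 100 seeded mice for the null-effect check; and
100 replicates of the pooled US-only study (34 recall sessions each) for
the correlation-recovery rate. The blanked-fraction equality is checked
on a continuously frozen background (entry 5 /s, exit 0), where every
blanked sample is attributable to an injected transient; under realistic
dynamics the gain is additionally checked to be bounded below by the
injected fraction, since genuine short beep-locked movement bouts are
then also (correctly) blanked.
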