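# Methods

## The experiment the simulator emulates

The pipeline targets a face-classification experiment recorded with
microwires: in each session a participant views 120 distinct synthetic faces —
30 clearly White, 30 clearly Black, and 60 intermediate morphs split evenly
into AmbiguousWhite and AmbiguousBlack — each presented 6 times (720 trials).
A face is on screen for 1 s and is followed by a 2 s response period. The
dependent measure for every statistical stage is the number of spikes a
sorted unit fires in the 200–1000 ms window after onset; the reference
condition is the count in the matched-length 1000–200 ms window before onset.

The synthetic generator reproduces exactly this design. Trial order is a
uniform seeded shuffle of the 720 presentations. The inter-onset interval is
1 s stimulus + 2 s response + a uniform 0–0.5 s jitter; the recording layer
does not state an inter-trial gap, so the jitter is this package's choice
(it also prevents onset times from aliasing against any periodic structure
in tests). Onsets start at 2 s so the first background window is complete.

Spike trains are piecewise-constant-rate Poisson processes: rate
`baseline_rate_hz` everywhere, multiplied by `gain[category]` inside
`[onset + latency, onset + latency + duration)` of each trial (defaults:
latency 0.2 s, duration 0.8 s, i.e. congruent with the response window).
Generation is exact, by superposition (extra Poisson spikes at rate
`baseline·(gain−1)` where gain > 1) and thinning (keep probability `gain`
where gain < 1) of a homogeneous baseline process. Generating a
continuous-time train rather than per-trial count draws lets the voltage
synthesis/detection stage and the counting stage share one ground truth;
window counts remain exactly Poisson because windows are disjoint. Every
stochastic function takes an explicit integer seed (numpy `default_rng`);
equal seeds give bit-identical output.

Default simulation conditions used throughout the tests: 5 Hz baseline
(typical of medial-temporal units), single-category gain 3 for selective
neurons, 720-trial sessions. Calibration studies use 2000 null neurons;
power studies 500 replicates; breadth-recovery studies 200 neurons with 10%
planted selectivity.

What the generator does *not* emulate: refractoriness and bursting,
rate drift and non-stationarity within a session, cross-neuron correlation,
overlapping waveforms on a channel, and any dependence on the attended
(affect) dimension of the stimuli. Passing tests therefore demonstrate
statistical correctness of the pipeline under Poisson assumptions, not
robustness to every property of real recordings.

## Spike detection

Raw voltage (default sampling rate 29 412 Hz) is bandpassed at 300–3000 Hz
with a 4th-order Butterworth applied forward–backward (`sosfiltfilt`). The
source procedure names only the band; zero phase is chosen so detected event
times stay aligned with injected ground truth. Events are below-to-above
transitions of |signal| across 2.8 × SD of the full filtered record (plain
standard deviation by default; a MAD-based robust estimate behind
`robust_sd=True`). A 1 ms lockout keeps only the first crossing of each
event — no dead time is stated upstream, but without one a single biphasic
spike produces several crossings. Waveforms are 32 samples with the crossing
at the 9th sample (1-based; index 8 internally); events too close to the
record edges are dropped. On noiseless injected templates, detection is
exact to ±1 sample; after bandpassing, the zero-phase filter's symmetric
precursor can move the first crossing a few samples ahead of the peak.

The duplicate screen flags unit pairs recorded on the same channel in
different sessions whose mean rates differ by less than 50% — the base of
the percentage is not stated upstream, so the larger rate is used — with
equal waveform peak signs. Flagged pairs are reported; exclusion is an
option (`exclude_duplicates`), not automatic. Pairs with both rates zero are
logged, not flagged.

## Counting conventions

Windows are half-open `(start, end]` relative to onset, so a spike belongs
to at most one window; the published description writes closed ranges
without resolving boundaries. Response `(0.2, 1.0]` and background
`(−1.0, −0.2]` have identical 0.8 s length, so counts are proportional to
rates and all statistics operate on counts directly. Counting validates
that the response window of one trial cannot reach into the background
window of the next (impossible under the ≥3 s trial clock, but guarded for
arbitrary trial tables).

## Selectivity regression

Observation set per neuron: each trial contributes one record labeled by its
category with predictor = response count, plus one record labeled
`background` with predictor = background count (1440 observations per
default session). A 5-level multinomial logit (intercept + single slope per
category; background = reference) is fit by Newton maximum likelihood
(statsmodels `MNLogit`, max 100 iterations, parameter-change tolerance
1e-8). Per category, a two-sided Wald z-test of slope = 0; significance at
α = 0.05. The normal reference distribution is used for the Wald statistic —
at 1440 observations it is indistinguishable from a t reference.

The predictor is the raw count, not the response/background ratio: the
background reference level already supplies the comparison inside the
multinomial framework, and the count formulation keeps the model a
generalized linear one. A per-trial ratio variant
(`predictor="ratio"`, shrunk ratio `(resp+0.5)/(bg+0.5)` with
category-only labels) is provided for sensitivity analysis; its contrasts
are between categories, not against background.

Separation is flagged when any fitted |slope| exceeds 15 on the log-odds
scale; the criterion deliberately ignores intercepts, which are legitimately
large-negative whenever a category never produces near-zero counts.
Non-converged or separated fits report NaN p-values, make no significance
claims, and remain in population denominators (they can never enter
numerators). No per-neuron correction is applied across the four category
tests; multiplicity is handled at the population stage.

## Changes-from-background test

Statistic: T = Σ over the four categories of (category mean response count −
grand mean background count)². The background mean is the grand mean over
all trials, not per category, because the null is a single background level.
The null distribution is built by pooled resampling under the combined null:
all 2n counts are pooled, and each of the 10 000 default resamples draws,
with replacement, pseudo-groups of the original sizes (four category groups
plus one background group) and recomputes T. A label-permutation variant
(`scheme="permute"`) shuffles the pooled values without replacement instead.
p = (1 + #{T* ≥ T}) / (n_resamples + 1); the add-one rule keeps p > 0 and
makes the null distribution of p uniform on a discrete grid. Resampling is
vectorized in batches of 2000 resamples to bound memory. Seeds are recorded
in every result.

## Population statistics

The expected fraction of significant neurons under the global null is the
per-test level α = 0.05, so per-area (or per-area × category) counts are
tested with the exact upper-tail binomial P(X ≥ k | n, 0.05). The
Benjamini–Hochberg step-up adjustment is applied across the tests of one
batch; the default family is all area × category tests
(`fdr_family="categories"`), with per-category-across-areas
(`"areas"`) available, since the appropriate family depends on which
summary table is being produced. Percentages are rounded half-up to
integers to match conventional table presentation. The per-neuron one-way
ANOVA uses scipy's F-test; it is flagged degenerate only when F is undefined
(all observations identical — zero within-group variance with differing
means gives F = ∞, p = 0, a valid rejection). Fisher's exact test (2×2,
two-sided) compares selective fractions between subject groups.

## Mutual information

I(count; category) is the plug-in estimate on the joint empirical
distribution, counts as raw discrete symbols (no binning), log base 2,
0·log 0 = 0. The estimate is clipped below at 0 and asserted against the
min(H(count), H(category)) bound on every call. The plug-in estimator is
positively biased at finite n; the first-order (Miller–Madow) correction
(K_joint − K_count − K_cat + 1)/(2 n ln 2) is available behind
`bias_correction="miller-madow"` but is off by default, matching a plain
entropy-based estimator. The first-order term is accurate only when joint
cells are well populated; with raw counts at 720 trials it undercorrects,
which is why the bias regression test uses the tail-merging cap
(`max_count`) to work on a small, well-populated alphabet. Per area,
`neurons_to_2_bits = 2 / mean MI` (one decimal place) estimates the
population size needed to identify one of four equiprobable categories;
it assumes additivity and independence across neurons and is therefore an
optimistic lower bound on the required population. Differences in mean MI
across areas are tested with a one-way ANOVA.

## Pipeline and reproducibility

`RunConfig` (pydantic) validates every knob and serializes to JSON;
`run_pipeline` executes counts → selectivity → CBT → population → MI and
writes each table as CSV plus `manifest.json` (config, package version,
seeds, SHA-256 of every file). Per-neuron CBT seeds are `config.seed + i`
so results are independent of neuron processing order. All outputs are
byte-identical across reruns with the same config; wall-clock timings are
written to `run.log`, deliberately outside the hashed outputs so that
determinism is testable. Warnings (non-convergence, degenerate ANOVA,
excluded duplicates) are collected into the QC section of `run.log`.

## Known limitations

- Poisson firing is an idealization; overdispersed or bursty units will make
  the Wald test anticonservative in real data (the regression's calibration
  is verified under Poisson only).
- The pooled-resampling CBT null treats response and background counts as
  exchangeable; slow rate drift across a session violates this.
- The neurons-to-decode figure ignores noise correlations.
- Plug-in MI is biased upward for small samples; comparisons across areas
  with very different trial counts should use the bias-corrected variant.
- Spike sorting is out of scope: the pipeline accepts sorted unit labels and
  begins at detection only when raw voltage is supplied.
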