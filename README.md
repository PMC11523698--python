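# spikesel

Single-neuron category-selectivity analysis for spike-train recordings.

Human microwire recordings (amygdala, anterior cingulate cortex, hippocampus,
ventromedial prefrontal cortex) can ask whether individual neurons change
their firing rate with a perceptual category of the stimulus — for example,
the apparent race of a presented face — even when that category is irrelevant
to the subject's task. `spikesel` implements the complete statistical pipeline
for that question, from raw voltage (optional) to population summary tables,
together with a synthetic-experiment generator so that every stage can be
validated against known ground truth without access to patient data.

## What it computes

Each trial contributes a pair of spike counts for each neuron: the count in a
response window 200–1000 ms after stimulus onset, and the count in a matched
background window 1000–200 ms before onset. On these paired counts the
package runs:

1. **Selectivity regression.** A 5-level multinomial logistic regression with
   the spike count as the sole predictor: each trial enters once labeled by
   its category (predictor = response count) and once labeled *background*
   (predictor = background count), with background as the reference level.
   For each category *c* with slope β<sub>c</sub>,

   log [ P(c) / P(background) ] = α<sub>c</sub> + β<sub>c</sub> · n<sub>spikes</sub>,

   and a two-sided Wald test of β<sub>c</sub> = 0 decides whether the
   neuron's firing predicts that category versus background firing.
2. **Changes-from-background test (CBT).** A resampling test of the combined
   null that firing is insensitive to category *and* equal to background,
   with statistic T = Σ<sub>c</sub> ( mean response count in c − grand mean
   background count )², and a pooled-resampling null distribution.
3. **Population statistics.** Per-area counts of selective neurons against
   the fraction expected by chance (exact upper-tail binomial test,
   Benjamini–Hochberg FDR across tests), per-neuron one-way ANOVA, Fisher's
   exact comparison of fractions between subject groups, and tuning-breadth
   histograms (how many neurons code 0–4 categories).
4. **Information to decode.** The plug-in mutual information I(count;
   category) in bits per neuron, and per area the number of neurons needed
   for the 2 bits that distinguish four equiprobable categories
   (2 / mean MI, assuming additivity across neurons).
5. **Spike detection** (optional front end): 300–3000 Hz zero-phase
   Butterworth bandpass, two-sided threshold at 2.8 channel standard
   deviations, 32-sample waveforms aligned at the 9th sample, plus a
   cross-session duplicate-cluster screen (<50% rate difference with the same
   waveform peak sign).

## Worked example

```python
import spikesel as ss

trials = ss.make_session(seed=1)                       # 720 trials, 120 faces
tuning = ss.NeuronTuning("amy_042", area="A",
                         baseline_rate_hz=5.0, gain={"Black": 3.0})
train = ss.simulate_spike_train(tuning, trials, seed=2)
counts = ss.count_trials(train, trials)

result = ss.fit_selectivity(counts, alpha=0.05)
print(result.table.round(4))
print("categories coded:", result.n_categories_coded)

cbt = ss.cbt_test(counts, n_resamples=10_000, seed=3)
print(f"CBT: T = {cbt.observed_T:.2f}, p = {cbt.p_value:.5f}")

mi = ss.mutual_information(counts)
print(f"mutual information: {mi.mi_bits:.3f} bits")
```

Output:

```text
                  coef      se     stat       p  significant
category
White           0.0175  0.0414   0.4239  0.6717        False
AmbiguousWhite  0.0203  0.0414   0.4902  0.6240        False
AmbiguousBlack -0.0087  0.0417  -0.2082  0.8350        False
Black           1.1414  0.0921  12.3935  0.0000         True
categories coded: 1
CBT: T = 70.36, p = 0.00010
mutual information: 0.644 bits
```

The simulated neuron triples its 5 Hz rate on Black-face trials. The
regression recovers exactly that structure: a strongly positive Black slope
(each extra spike in the window multiplies the odds of a Black trial versus
background by e^1.14 ≈ 3.1) with the other three categories at chance, so the
neuron codes one category. The CBT rejects the no-change null at its
resolution floor (p = 1/10001 with the add-one rule), and the neuron carries
0.64 bits of the 2 bits needed to identify the category outright — about
3 such neurons would suffice under additivity.

## Command line

```sh
spikesel simulate --seed 0 --n-neurons 10 --selective-fraction 0.2 --out-dir data/
spikesel run --seed 0 --in-dir data/ --out-dir results/
```

`run` executes counts → selectivity → CBT → population summaries → mutual
information and writes each table product as CSV plus a `manifest.json` with
SHA-256 hashes; identical config and seed reproduce byte-identical outputs.
Individual stages are available as `detect`, `counts`, `select`, `cbt`,
`info` and `report` subcommands.

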