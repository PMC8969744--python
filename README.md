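# oddball-eeg

Sensor-space analysis pipeline for two-state auditory odd-ball EEG
experiments, built for the study design in which a participant hears
series of five 50-ms sounds — the fifth either identical (*standard*,
AAAAA/BBBBB) or different (*deviant*, AAAAB/BBBBA) — in two conditions
(a baseline state, PRE, and a hypnotic-deafness state, HYP), while
high-density EEG is recorded at 250 Hz.

The package is aimed at EEG researchers who want a tested, reusable and
fully seeded implementation of this analysis chain:

* **paradigm** — deterministic synthesis of the three-tone stimuli and
  seeded generation of block schedules and event timelines
  (78 series/block, 67%/33% standard/deviant, 150-ms SOA,
  1.35–1.65-s inter-series intervals in 50-ms steps);
* **synth** — a synthetic-EEG generator with ground truth: evoked
  components (P1, MMN, P3a, P3b) with per-(state, stimulus) amplitudes,
  1/f and narrowband background noise with realistic spatial structure,
  planted artifacts, and lagged inter-sensor coupling — the stand-in
  for the unavailable subject recording that makes every stage
  verifiable;
* **preprocess** — zero-phase band-pass (0.5–10 Hz ERP / 0.5–45 Hz
  spectral, 50/100-Hz notches), epoching (−0.2..1.4 s re first sound),
  automated peak-to-peak / variance artifact rejection with the 70%/70%
  pass rule, average reference, realignment to the fifth sound and
  baselining;
* **erp_stats** — mass-univariate two-way type-II ANOVA
  (STATE × STIMULUS) with Benjamini–Hochberg FDR across time,
  component window amplitudes with Welch post hocs, Cohen's *d*,
  partial η², and JZS Bayes factors;
* **decoding** — timewise linear-SVM decoding (standardized features,
  inverse-frequency class weights, Platt calibration, stratified 7-fold
  CV), cross-condition transfer, temporal generalization (5-fold), and
  label-permutation significance with FDR;
* **state_markers** — pseudo-resting-state markers on the 800 ms before
  the fifth sound: normalized band power (δ/θ/α/β/γ) and weighted
  symbolic mutual information (wSMI), with per-sensor Welch contrasts,
  cluster-mass permutation tests on the montage adjacency, and
  Bayes-factor maps.

The core statistics of the chain, in the field's notation: the
component amplitude is the trial-wise window average of ROI voltage;
decoding performance is the AUC of held-out Platt probabilities with
permutation p-values p(t) = #{AUC*π* ≥ AUC}/(n_perm+1); and

wSMI(i,j) = 1/log k! · Σ_{s,s'} w(s,s') p(s,s') log[ p(s,s') / (p(s)p(s')) ]

over joint rank-order symbol probabilities (k = 3, band-specific τ),
with w zero for identical and sign-opposite symbol pairs.

See `docs/methods.md` for the full model description, defaults and
limitations.

## Worked example

```python
from oddball.paradigm import build_block, schedule_events

plan = build_block("a", n_series=78, deviant_fraction=0.33, rng_seed=7)
timeline = schedule_events(plan, rng_seed=8)
print(f"block a: {plan.n_series} series, {plan.deviant_count} deviant")
print(f"first series starts at {timeline.series_onset[0]:.3f} s, "
      f"fifth sound at {timeline.fifth_onset[0]:.3f} s")

from oddball.experiments import amplitude_recovery

rec = amplitude_recovery(seeds=[0, 1])
for (comp, state), r in sorted(rec.items()):
    print(f"{comp} {state}: recovered {r['recovered_uv']:+.2f} uV "
          f"({r['n_trials']} trials)")
```

prints

```
block a: 78 series, 26 deviant
first series starts at 1.000 s, fifth sound at 1.600 s
P3a HYP: recovered +2.19 uV (312 trials)
P3a PRE: recovered +0.02 uV (312 trials)
P3b HYP: recovered +0.01 uV (312 trials)
P3b PRE: recovered +1.34 uV (312 trials)
```

The block reproduces the design constants (78 series, 26 deviants; the
fifth sound 4 × 150 ms after the first), and the generator's injected
deviant-minus-standard amplitudes — a 1.36-µV P3b in PRE only and a
2.23-µV P3a in HYP only — are recovered by the window-averaged ERP
measurement to within sampling error, and measure ≈ 0 µV in the state
where nothing was injected.

A full experiment (simulation → preprocessing → ERP → decoding →
markers, with a manifest and JSON/TSV results) runs from the command
line:

```bash
oddball run --seed 1 --out results/run1          # reference configuration
oddball paradigm --block a --n-series 78 --seed 3 --out events.tsv
oddball simulate --seed 2 --out sim/             # recordings + ground truth
```

or from Python via `oddball.pipeline.run_experiment(RunConfig(), out,
seed)`.  Re-running with the same config and seed regenerates
byte-identical numeric outputs.

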