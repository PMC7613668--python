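# lfpdetect

Resource-constrained seizure-state classifiers for local field
potentials (LFP), built for the question closed-loop neuromodulation
keeps asking: can a neural network of only dozens of units compete with
the hand-tuned band-power detectors deployed in implantable pulse
generators?

The package implements and compares, on a common footing:

- **A band-power filter chain** — the classical detector: an 8–22 Hz
  4th-order Butterworth band-pass realized as Direct Form I biquads with
  16-bit coefficients and saturating 32-bit accumulators (bit-true to
  the embedded arithmetic, with a floating-point reference), an
  exponential-moving-average envelope `y[n] = y[n−1] + (|x[n]| −
  y[n−1])/32`, and a scalar threshold.
- **A compact MLP** — a 20-sample input window, 8 hidden ReLU units and
  a logistic output (177 parameters), trained by mini-batch gradient
  descent on binary cross entropy −[y log p + (1−y) log(1−p)], quantized
  post-training to 8-bit weights, and smoothed at inference by
  thresholding the mean of the last 3 window scores ("adjusted" output).
  An optional 1-D convolutional front end gives the CNN variant.
- **The study tooling** — a synthetic LFP generator (1 µVrms pink
  background, rare 10 µVrms epileptiform bursts with annotations),
  dataset windowing / 3:1 class balancing / stratified 70:30 split,
  hyperparameter grid search over window length × hidden units, and an
  evaluation battery: per-timestep ROC/AUROC, onset latency, per-event
  label overlap, and frequency × amplitude response maps probed with 1 s
  test tones.

It is aimed at researchers prototyping embedded biomarker classifiers
who need the fixed-point arithmetic, the training pipeline and the
evaluation protocol in one reproducible, pure-Python place.

## Worked example

The `run-all` command chains the whole study at desk scale — synthesize
training and held-out recordings (480 s, 12 events each), train and
quantize the 20×8 MLP, run both classifiers, and evaluate at a matched
5% per-timestep false-positive rate:

```sh
lfpdetect run-all --seed 0 --out demo/
```

```json
{
  "final_val_bce": 0.0930753674066545,
  "filter": {
    "auroc": 0.986230610854559,
    "threshold": 0.353370339838456,
    "mean_latency_s": 0.16145833333333334,
    "n_missed": 0,
    "mean_overlap_pct": 97.14370820756994
  },
  "mlp": {
    "auroc": 0.9873671715147003,
    "threshold": 0.06161656964059148,
    "mean_latency_s": 0.2138671875,
    "n_missed": 0,
    "mean_overlap_pct": 97.31470001021817
  }
}
```

Reading the numbers: the trained network's validation cross entropy
(0.093) indicates a clean fit; both detectors separate ictal from
background timesteps equally well (AUROC ≈ 0.99), miss none of the 20
held-out events, and cover ~97% of each event's clinician-style
annotation. The thresholds differ in units — envelope microvolts for the
filter, adjusted score for the MLP — because each was placed at the
score quantile giving 5% FPR on non-event timesteps. Mean onset latency
is ~0.16 s for the filter and ~0.21 s for the MLP on these sharp-onset
synthetic events; the MLP's output is quantized to 78.125 ms window
boundaries, see `docs/methods.md` for why this ordering differs on
clinical data.

The same pieces are available individually (`synth`, `train`,
`gridsearch`, `classify-filter`, `classify-mlp`, `evaluate`, `respmap`),
and everything is importable as a library:

```python
from lfpdetect import (SynthConfig, synthesize_recording,
                       FilterChainConfig, classify_filter)

rec = synthesize_recording(SynthConfig(duration_s=3600, seed=7))
trace = classify_filter(rec, FilterChainConfig(threshold_uV=2.0))
```

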