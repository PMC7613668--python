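# Methods

`lfpdetect` studies two resource-constrained detectors of seizure state in
single-channel local field potentials (LFP), together with the data,
training and evaluation machinery needed to compare them. Everything
operates at (or is resampled to) 256 Hz; amplitudes are microvolts; event
annotations are half-open intervals `[onset_s, offset_s)` in seconds.

## The band-power filter chain (baseline)

The classical detector estimates power in a fixed band and thresholds it:

1. **Band-pass**: an 8–22 Hz Butterworth filter of total order 4 (two
   biquad sections). "Order 4" is read as the order of the overall
   transfer function; a per-edge reading (8 poles) is available via
   `order_is_per_edge`. Discretization is the bilinear transform with
   pre-warped band edges (scipy), which places the −3 dB points on the
   band edges by construction.
2. **Rectify + smooth**: absolute value followed by an exponential moving
   average, `y[n] = y[n−1] + (|x[n]| − y[n−1])/32`, initial condition 0.
   The decay of 32 samples is read as smoothing factor α = 1/32 (a single
   right-shift in fixed point); an exponential-time-constant reading
   (α = 1 − e^(−1/32), numerically close) is selectable via `ema_mode`.
3. **Threshold**: `envelope ≥ threshold_uV`, ties positive. For an
   in-band sinusoid of peak amplitude A the steady-state envelope is
   2A/π, which fixes the scale of `threshold_uV`.

### Fixed-point realization

The embedded-faithful path mirrors a Direct Form I implementation with
16-bit coefficients and 32-bit accumulators:

- Coefficients are quantized to Q2.13 (2 integer bits cover the ±4 range
  of stable biquad coefficients; half-LSB error 2^−14). Stability is
  re-checked after rounding.
- The overall design gain is distributed by *cumulative peak scaling*:
  section gains are chosen so that after every section the partial
  cascade's peak magnitude response is 1, keeping the 16-bit
  inter-section signals from clipping. White noise at half scale
  (±16383) produces zero saturation events.
- Each section accumulates five 16×16-bit products with saturating
  32-bit adds, then renormalizes by an arithmetic right shift with
  round-half-away-from-zero. Saturation (rather than wraparound) is the
  overflow contract; events are counted and reported.
- The shift rounding injects ≤ 0.5 output-LSB per section per sample.
  Because the rounded output feeds the section's own recursion, the
  noise is shaped by 1/A_k(z) before passing through later sections, so
  the worst-case output error is 0.5·Σ_k ‖(1/A_k)·H_{k+1..n}‖₁
  (`fixed_point_error_bound`, ≈ 27 LSB for the default design; observed
  errors on random input are ~9 LSB). The reference for this bound is
  the float filter run with the *dequantized* coefficients; coefficient
  rounding itself is assessed separately by re-measuring the −3 dB
  points (they move by well under 3%).
- The integer EMA keeps the envelope in an accumulator scaled by the
  decay factor (`acc += |x| − round(acc/32)`), giving 5 fractional bits
  of envelope resolution without a divider.
- On the fixed path, input microvolts are quantized at
  `input_lsb_uV = 0.05` µV/LSB (full scale ±1638 µV), leaving ample
  headroom above the ~10 µVrms ictal signals while keeping the 1 µVrms
  background ~20 LSB deep.

## The compact MLP and its deployment form

The network maps a window of 20 consecutive samples through one hidden
layer of 8 rectified-linear units to a logistic output unit — 177
parameters. Choices the architecture leaves open were resolved as
follows: ReLU hidden units with a logistic output are the minimal pair
compatible with binary cross entropy; inputs are divided by a fixed
full-scale constant (50 µV, recorded in the model file) because an
implant cannot standardize windows online; windows do not overlap (hop =
window length), so inference cost is one forward pass per 78.125 ms.

The *adjusted* output averages the three most recent raw scores before
thresholding (shorter prefixes at the start), giving the temporal
coherence that recurrent state would otherwise provide. A strict
unanimous-vote mode exists behind `mode="vote"`; the two coincide for
unanimous votes. Averaging is a 3-tap low-pass on the score sequence: at
the 0.5 decision threshold it only removes label toggles, though an
adversarial threshold placed inside the score bulk can in principle make
a moving average ring — the smoothing claim is an operating-point
property, not an algebraic identity.

A 1-D convolutional front end (4 kernels of length 8, stride 2 — sizes
are our choice) can be prepended for the CNN comparison; it shares the
MLP head and training loop.

**Quantization** is post-training, symmetric, per-tensor: scale =
max|w|/127, integers in [−128, 127], an all-zero tensor gets scale 1.
Inference dequantizes and computes in float, matching interpreter-style
embedded runtimes; bit-exact integer kernels are out of scope. On the
synthetic validation set the AUROC cost of 8-bit weights is ~10⁻⁵.

## Training pipeline

- **Windowing**: consecutive non-overlapping windows; a window is
  positive iff more than half its samples lie inside an annotation (the
  mapping from interval labels to window labels is our choice).
- **Balancing**: all positives kept, negatives subsampled without
  replacement to exactly 3 per positive. Balancing precedes the split so
  both halves carry the 3:1 bias; the window (not sample) count defines
  the ratio.
- **Split**: stratified 70:30; per-class rounding means the global train
  count can differ from round(0.7·N) by one.
- **Optimizer**: plain mini-batch gradient descent (lr 0.01, batch 32,
  200 epochs) on binary cross entropy with probabilities clipped at
  1e−7. Deterministic given the seed; training aborts with a diagnostic
  on non-finite loss.
- **Grid search** re-windows the source recordings at each window
  length, trains a fresh seeded model per (window, hidden) cell and
  records final validation cross entropy; failed cells are marked NaN.
  The selected cell is the loss argmin, or the smallest network within
  10% of it under the `low_complexity` rule.

## Synthetic data

No patient recordings accompany this package, so the generator emulates
the relevant statistical structure: pink (1/f) Gaussian background at
1 µVrms — the standard first approximation of inter-ictal LFP — and
rare, seconds-long bursts at 10 µVrms, the amplitude decade separating
epileptiform discharges from background oscillations in chronically
sensed LFP. Default density is 1.25 events/h (30 per 24 h). Two burst
templates exist: `spike_wave` (harmonic series of a 4 Hz fundamental,
1/k amplitudes, harmonics through ~40 Hz — energy reaches the 8–22 Hz
detection band while the fundamental dominates) and `narrowband`
(band-passed white noise). Bursts get a 0.5 s raised-cosine taper at
each end; annotations cover exactly the tapered extent. Placement is
uniform with rejection sampling, ≥10 s between events; the event count
is the rounded expectation (`fixed`) or Poisson. All randomness derives
from a single seed per call.

What the generator does **not** model: morphological evolution of real
seizure onsets (low-amplitude fast activity developing into rhythmic
discharges over seconds), stimulation artifacts, nonstationary
background, multichannel structure. Tests passing on this data therefore
validate the machinery and its contracts, not clinical performance.

## Evaluation

- **ROC** at per-output-timestep granularity, truth sampled from the
  annotations at the trace's own timestamps; AUROC by trapezoid.
- **Onset latency**: first positive output inside
  `[onset, onset + 10 s]`; earlier positives are false positives, not
  negative latencies; events without a positive are missed and excluded
  from the mean.
- **Overlap**: percent of event duration covered by positive output,
  labels held piecewise-constant over the preceding hop interval.
- **Operating-point matching**: to compare detectors with incommensurate
  score scales, traces are re-thresholded to a common per-timestep FPR
  (default 0.05) computed from non-event timesteps.
- **Response map**: mean score for 1 s sinusoidal test tones over a
  frequency × amplitude grid, 10 repeats per cell with fresh phase and
  1 µVrms background. The filter chain's output is normalized to [0, 1]
  by the steady-state envelope of a full-scale in-band tone (2·A_max/π);
  the MLP reports its mean adjusted score directly.

### A note on latency ordering

On this synthetic data both detectors trigger early inside the 0.5 s
onset taper, and the comparison is then dominated by output granularity:
the filter chain emits one output per sample while the MLP's output is
quantized to 78.125 ms window ends and smoothed over three windows. At
matched FPR the filter is consistently a few tens of milliseconds
faster here. The latency advantage reported for compact networks on
clinical recordings rests on gradually developing onsets — in-band power
that builds over seconds while the waveform is already ictal — which the
fixed-template generator deliberately does not model. `scripts/
acceptance.py` reports both measured latencies rather than asserting an
ordering.

## Problem sizes and numerical choices

Study-scale runs use a 480 s training recording (12 events) and a 900 s
held-out recording (20 events); the 24 h × 30-event density is exercised
only through the generator's annotation count. Probability clipping
1e−7; envelope threshold ties classify positive; EDF export uses 1 s
records, 16-bit samples and a symmetric physical range (quantization
step max|x|/32767). EDF reading goes through mne; writing uses the
package's own minimal single-channel encoder because no installed
library exports EDF.

## Known limitations

- Synthetic events are stationary templates; no claim of morphological
  fidelity to any patient's seizures.
- The quantized model computes in dequantized float; integer-only
  inference may differ at the last bit.
- The CNN variant's topology is a reasonable default, not a tuned
  architecture; it supports qualitative comparison only.
- Single channel only; no artifact or stimulation modeling.
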