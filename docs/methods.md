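# Methods

## The soft-sensing problem

A fed-batch CHO production run lasts about 17 calendar days (seeding at
-3 dpi, induction at 0 dpi, harvest at 14 dpi). Five variables that drive
process decisions — product titer (mg/L), viable cell density (VCD,
cells/mL), lactate (mM), ammonia (mM) and cumulative glucose consumed
(cGC, mM) — are measured only on sampling days (-3, -2, -1, 0, 3, 5, 7,
10, 12, 14 dpi), and titer in particular is slow and laborious to assay.
The bioreactor's control system, by contrast, logs telemetry continuously:
pH, DO, temperature, cumulative base addition, and O2/CO2 sparge flows.
The soft sensor uses the current day's telemetry together with whatever
offline values are available to predict all five variables one day ahead,
every day of the run.

## Model

A recurrent network with a shared hidden state and five per-variable
decoder heads, all of width H = 256 with ReLU activations:

    h_t       = W_hidden · Φ(W_in · [h_{t-1}; O_t; X_t])
    X̂_{t+1}^i = W_out^i · Φ(W_h_in^i · h_t),   i ∈ {titer, VCD, lactate,
                                                    ammonia, cGC}

where O_t is the day-t online 7-vector, X_t the day-t offline 5-vector
(measured where available, otherwise the model's previous prediction) and
Φ = ReLU. Each MLP is a single affine → ReLU → affine block: the update
equations show exactly one activation per MLP, and no activation is
applied after W_hidden. h_0 = 0 (no information before seeding). Biases
are included in every affine map by default; `use_bias=False` gives the
strict bias-free form of the equations. All inputs and targets are
standardized per feature with training-set statistics.

Two rollout modes mirror the two use cases:

* **full_feedback** — on sampling days the measured values replace the
  model's predictions as the next input (teacher forcing); elsewhere the
  model runs on its own predictions.
* **cellcount_only** — true soft sensing: only VCD measurements are ever
  fed back (cell counts are cheap); titer and metabolites run on model
  predictions from day one onward.

## Training protocol

SGD with momentum 0.97, weight decay 0.125 (classic coupled L2; a
decoupled variant is available as a switch), learning rate 1.6e-4, 5000
epochs, H = 256. One epoch is one pass over the training sequences in an
order reshuffled by the seeded generator, with a parameter update after
each sequence (batch size = one sequence). Gradients are exact BPTT
through both the hidden-state recursion and the prediction-feedback path;
they are verified against central finite differences in the test suite.

The loss is the per-variable mean squared error over supervised days,
summed over the five variables, scaled by a constant `loss_scale`
(default 5, i.e. roughly a plain sum of squared errors over all
supervised points of a sequence). The scale matters because the weight
decay is coupled: it sets the equilibrium between data gradient and decay
pull. A unit scale leaves the model visibly under-fitted at these
hyperparameters, while very large scales over-fit the titer head;
the default sits between those regimes. Supervision uses sampling days
only (`loss_days="sampling_only"`); pre-induction titer measurements
(zeros) are included as targets. Training runs in float32 (the loop is
memory-bandwidth-bound; float64 is available via `TrainConfig.dtype` and
is used in the gradient-verification tests).

## Evaluation

Per batch and per variable, predictions are compared with the measured
values at the comparable days: sampling days after the first input day
(9 on the full grid), titer from 3 dpi onward because production only
begins at induction. RMSE and MAE are normalized by the within-batch
population SD (ddof = 0) of the measured values, so a batch-mean
predictor scores nRMSE exactly 1 and R² exactly 0; metrics are averaged
unweighted across batches, and across-batch SDs of RMSE/MAE are
reported. R² is the coefficient of determination 1 − SSres/SStot by
default; the squared-Pearson variant is available (`r2_mode="corr"`).

Because the evaluation reference is itself a noisy assay (Table of RSDs
below), R² has a hard ceiling below 1: on a typical synthetic held-out
set even a perfect predictor of the noise-free truth scores only ≈ 0.93
for titer (12 % assay RSD against a within-batch spread of roughly 4
assay SDs) and ≈ 0.96-0.99 for the other variables. Reported model R²
values must be read against that ceiling.

## Synthetic campaign generator

No production dataset ships with the package, so a simulator generates
campaigns with the same structure as the real process: 0.75-L
bioreactors seeded at 0.4e6 cells/mL, 37→32 °C shift 3 days after
seeding, pH setpoint shift 7.05±0.05 → 6.95±0.05 after 2 days, DO at
40 % with an air-cap/O2 cascade, bolus feeds of 5/5/5/7.5/5/5 % of the
initial volume at 0/3/5/7/10/12 dpi, glucose topped up to stay above
17 mM until the next sample, and the ten sampling days listed above.

The kinetics are deliberately minimal — Monod growth on glucose with a
temperature-shift growth reduction, a logistic density cap and mild
ammonia inhibition; growth-coupled plus maintenance glucose uptake;
lactate produced during growth and consumed after a metabolic switch
(with optional late re-production); ammonia accumulating during growth,
near-flat in a plateau window, then rising; titer proportional to the
viable-cell integral from induction. Three pool phenotypes set the
flags: "Delta" (highest density, largest lactate swings, micro-sparger),
"Beta" (secondary growth spurt after the shift, ammonia lag to 7 dpi,
macro-sparger) and "WuTL" (post-shift plateau, ammonia rise right after
induction, late lactate re-production, highest specific productivity,
macro-sparger). All magnitudes are package defaults chosen to look like
plausible CHO fed-batch runs; they are not measurements.

The control loops are what make the online channels informative: lactate
flux acidifies the broth, base is added only below the pH deadband and
CO2 sparged only above it, and O2 sparging tracks oxygen demand
(∝ VCD × metabolic activity) above the air-cap capacity, with
sparger-type-dependent transfer efficiency. Integration is explicit
Euler at 0.01-day steps; telemetry is emitted on a 15-minute grid and
pushed through the same preprocessing pipeline as real data
(Savitzky-Golay pH smoothing, daily averages, trapezoidal integrals).

Observation noise: offline values get multiplicative Gaussian noise,
truncated at ±3 SD, with relative SDs VCD 7 %, lactate 2 %, ammonia 3 %,
cGC 3 %, titer 12 %; the observed cGC is kept non-decreasing (running
max — increments between samples are large relative to 3 %, so the clip
is almost never active) and the recorded pre/post-feed glucose pair is
back-computed to stay ledger-consistent with the noisy cGC. Online
channels get small additive sensor noise (pH SD 0.005).

Per-batch kinetic parameters are drawn from pool-specific distributions
(multiplicative Gaussian jitter, SD 8-15 % depending on the parameter,
truncated at ±2.5 SD); passage number and MSX level are drawn as
metadata. The default campaign is 10 Delta / 6 Beta / 5 WuTL = 21
batches with a grouped within-pool 80/20 split (8/2, 5/1, 4/1) and one
WuTL test batch harvested early at 12 dpi to exercise variable-length
sequences.

What the generator does **not** emulate: assay drift and sensor faults,
osmolality and viability, amino-acid metabolism, volume loss from
sampling, scale-up hydrodynamics, and any quantitative CHO physiology.
Passing tests on this generator therefore demonstrate that the
implementation learns the stated process structure from data with
realistic noise and sparsity — not that it would reach the same numbers
on a particular industrial dataset.

## Specific glucose consumption rates

IVCC (cell·day/mL) is the trapezoidal integral of VCD over time. Daily
consumed glucose is the first difference of predicted cGC; dividing by
the IVCC increment gives qGluc per day. Ground rates divide the measured
interval consumption (post-feed minus next residual) by the interval's
IVCC increment and are attributed to the interval end day. qGluc is
carried internally in mM·mL/(cell·day); multiplying by 1e6 gives
pmol/(cell·day) (with VCD in cells/mL the two differ only by that
factor). Intervals with non-positive IVCC increments are flagged and
reported as NaN rather than extrapolated.

## Numerical choices and degenerate inputs

* Standardization refuses constant features by name rather than dividing
  by zero; normalized metrics refuse zero within-batch SD the same way.
* Day convention: day d covers [d, d+1); daily averages use all samples
  in that window, cumulative telemetry integrals are evaluated at day
  starts, and the base-volume counter uses the last reading of the day
  (it is a running total — averaging would distort it).
* Savitzky-Golay defaults (window 31 samples ≈ 7.75 h at 15-min cadence,
  polynomial order 2) are gentle and configurable; assembly skips the
  filter when a series is shorter than the window.
* Negative apparent interval glucose consumption (possible under assay
  noise) is kept by default with a warning; a clamp-to-zero switch
  exists.
* Variable-length batches simply stop the rollout at their last online
  day; metrics use whatever comparable days exist.
* The checkpoint is a single npz archive holding weights, scaler
  statistics and a format-version string; the loader validates shapes.

## Problem sizes

The test suite and the acceptance script both run the full default
campaign (21 simulated batches, 17 train / 4 test) with the complete
5000-epoch protocol; training takes a few minutes of a single CPU at
H = 256. Unit and property tests use smaller widths (H ≤ 32) and short
epoch counts, which are stated in each test.

## Known limitations

* The per-batch kinetic jitter plus the configured assay noise bound the
  achievable held-out R² (see the ceiling discussion above); titer, with
  its 12 % assay RSD and purely multiplicative batch-to-batch
  productivity differences, is the variable that sits closest to its
  ceiling.
* The optimizer is faithful to the published protocol (per-sequence SGD,
  momentum 0.97); its stationary behavior is a noise ball rather than a
  point, so end-of-training metrics retain some run-to-run spread even
  at fixed seeds across platforms.
* The simulator's pH/gassing loop is a caricature (single lumped acid
  balance); it produces the qualitative base/CO2 signatures the model
  exploits, not calibrated control-engineering behavior.
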