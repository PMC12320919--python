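# Methods

This note documents the model, the numerical choices, the synthetic task,
and the limits of what the tests show.  It states no result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Model structure

One spatial dimension spans −40° to +40°, covered by 40 neurons with
Gaussian tuning and receptive-field centres 2° apart.  Centres sit at
−40, −38, …, +38: with this staggering the sum of any two centres lands
on the same grid again, so the diagonal (craniotopic) readout of a 40×40
map and the remapping-feedback lookup are exact index operations with no
interpolation.  The published description of the grid is over-determined
by one neuron; this is the variant that keeps the algebra closed.

Two 40×40 gain-field maps share the drive law

    r(x, y) = f(x) · (C + g(y) · w_fb) + noise

with `C = 0.5`, `w_fb = 1`, additive Gaussian drive noise
σ = 0.02 (2% of the unit drive peak) per neuron and step, and rate
relaxation τ = 10 ms.  The eye-signal axis of `lip_cd` is the
head-centred CD signal; that of `lip_pc` the per-synapse-delayed PC
signal.

Projection set (the supplementary wiring table of the source model is not
public, so the graph is reconstructed from its block diagram and declared
per projection in the configuration):

* `Xr_eye → lip_cd, lip_pc` — the visual drive, to both maps.
* `CD_eye × PC → cd_head` — gain-field transform (outer product, diagonal
  readout) of the retinotopic CD with the current (undelayed) eye
  reference; yields the future eye position in head coordinates.  How the
  CD obtains its eye reference is not specified in the source; the
  undelayed PC drive is used because before the saccade — the only time
  the CD is active — the PC signal is constant and the choice is
  immaterial.
* `PC_head → lip_pc` — topographic, one synapse per map neuron, each with
  its own delay drawn per trial from φ (truncated normal, μ = 200 ms,
  σ = 100 ms, support [120, 250] ms).
* `lip_pc → xh_head` — diagonal readout; the PC map is the one whose
  (eye, retina) activity is craniotopically consistent throughout the
  trial, which also makes the whole graph feed-forward and hence
  unconditionally stable.
* `xh_head → lip_cd` — remapping feedback, gated multiplicatively by
  `cd_head`; places drive at the retinal position each craniotopic
  stimulus will occupy after the saccade.  `feedback_enabled = False` is
  the ablation path.  `cd_gain_enabled = False` additionally silences the
  CD pathway, giving the "late, sudden, non-predictive" comparison model.

The two readout weights (`cd_head_weight = 6.5`, `xh_weight = 4.0`)
compensate the attenuation of the diagonal *mean* readout so the gain
signals reaching the maps have O(1) peaks like the inputs; they were set
once from measured signal peaks in a pilot trial.  The mean normalisation
itself (required so a uniform map reads out uniformly) makes an
off-centre craniotopic bump land one 2° bin outward of the ideal
position, because the neighbouring, one-neuron-shorter diagonal wins
narrowly; all positional contracts are therefore stated to one RF
spacing.

## Numerics

Rates follow τ·dr/dt = −r + drive integrated with the exponential
(exact) update `r ← drive + (r − drive)·exp(−dt/τ)` at dt = 1 ms,
rectified at zero each step.  For piecewise-constant drive this is exact
at any dt, halving dt changes final rates by well under 1%, and a
constant drive reproduces the closed-form relaxation to 1e-6.  Drives are
checked for NaN (fault names the population) and rates against a ceiling
of 50 (instability names the step).

The saccade follows a minimum-jerk position profile rescaled to the
(amplitude, duration) pair — monotone, single-peaked bell velocity,
analytic — as a pluggable strategy; only the endpoint, duration and
monotonicity are load-bearing downstream.  Synaptic delays are sampled
with `scipy.stats.truncnorm`, which is equal in law to redrawing
out-of-bounds normal samples and puts no probability mass at the bounds
(clipping would let a decoder key on saturated synapses).  Delays are
rounded to the integration step.

## Task and synthetic data

The default protocol emulates a saccade-to-target experiment: a
persistent stimulus at +20° craniotopic appears at 200 ms; the 20°,
62 ms rightward saccade follows after a uniform latency of 100–300 ms
(the jitter decorrelates stimulus-locked from saccade-locked activity);
vision lags by 30 ms; the CD ramps up 50 ms before onset, peaks at
onset and decays with τ = 25 ms, clamped to zero beyond five decay
constants so its support is compact.  200 trials per run (160 train / 40
test, split by whole trials), recordings exported at 5 ms resolution
over −300…+500 ms around saccade onset; latencies are snapped to the
5 ms recording grid so all exported records share one time base.  A
master seed spawns independent per-trial streams (latency, delays,
noise), so adding trials never changes earlier ones.

What the generator does **not** emulate: spiking variability and
realistic firing-rate distributions, multiple saccade vectors or starting
positions, vertical/oblique saccades, visual transients other than the
single persistent target, and any fitted correspondence to real neurons.
Passing tests therefore show internal consistency of the mechanism, not
quantitative agreement with electrophysiology.

## Decoder

A single dense readout with bias and rectified-linear output decodes the
eye position at temporal offsets {+100, 0, −200} ms from all 3200 map
neurons (inputs standardised per neuron with training-split statistics; a
bias is needed because standardised inputs cannot express a nonzero
resting eye position; the rectifier is valid because all task eye
positions are ≥ 0, and can be disabled).  Training minimises the ridge
objective `mean((relu(Xw + b) − y)²) + α‖w‖²` with α = 1e-2: the weights
are initialised at the closed-form ridge solution of the linear part and
refined by 100 epochs of full-batch gradient descent through the
rectifier, step 1/L from a power-iteration curvature bound with
backtracking halving, so the loss curve is non-increasing and training is
deterministic.  (Plain small-step gradient descent from random weights
reaches the same optimum far too slowly for 3200 correlated inputs; the
initialisation changes the path, not the objective.)  α = 1e-2 (a 1%
relative ridge) was chosen from a coarse grid for stable generalisation —
at 1e-4 the readout overfits the ~1600 input channels that carry only
noise at any given epoch, which contaminates comparisons between input
subsets.

Evaluation pools the squared error over all held-out samples; the
"sluggish baseline" replaces the 62 ms saccade in each test trial with a
250 ms linear ramp from onset — the classical slow eye-position signal —
and any decoder claimed to track the eye must beat its RMSE.  Transition
span and midpoint are measured on the smoothed decoded trace between the
10%/90% and 50% crossings of the plateau-to-plateau excursion.

## Gain-field index

GFI(t) = (V_probe(t) − V_post) / (V_pre − V_post) on trial-averaged
PC-map rates.  Both steady windows sit *after* the saccade: pre =
[+110, +175] ms (after the CD transient and visual settling, before the
earliest PC arrival at 62 + 120 = 182 ms) and post = [+350, +500] ms
(after the latest arrival at 312 ms plus relaxation), so the steady-rate
difference is attributable to the PC update alone — the in-task analogue
of probing a neuron with a stimulus fixed in its receptive field.  With
the sweeping retinal stimulus of this task, a pre-saccadic steady window
would confound visual and PC changes, so the probe domain starts at the
pre-window.  Selection: |Δrate| > 20% of the pre-steady rate (absolute
floor 0.05) with a sign consistent in ≥ 90% of trials; degenerate
denominators exclude the neuron rather than fail.  Neurons come from the
PC map only; CD-map activity changes are CD/remapping-driven by
construction.  Windows, threshold and consistency are configurable.

## Known limitations

* The decoded *past* eye-position transition tracks the cumulative
  distribution of φ; with the [120, 250] ms support its 10–90% rise is
  ≈ 110 ms.  Any characterisation of the past decoder as "spread over
  more than the delay support" cannot hold — the delay distribution is
  the upper bound.
* Both maps receive the latency-delayed visual drive, so during the
  saccade much of the linearly accessible eye-position information is the
  visual sweep itself.  Removing the CD map therefore degrades
  peri-saccadic decoding moderately rather than catastrophically; the CD
  pathway's distinctive contributions are presaccadic anticipation and
  saccade-onset detection.
* The mixed-population variant (`mixed_population = True`, each neuron
  mixing both gain signals) is implemented but intentionally untested.
* Decoder weights are saccade-specific; decoding other vectors would
  require retraining, which is a property of the approach, not a bug.
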