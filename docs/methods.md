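# Methods

## The model family

`glifkit` implements a family of five generalized leaky integrate-and-fire
(GLIF) point-neuron models of increasing complexity. Between spikes the state
vector (membrane potential `V`, spike-dependent threshold component `Θ_s`,
two after-spike currents `I_1, I_2`, voltage-dependent threshold component
`Θ_v`) evolves linearly:

    C dV/dt   = I_e(t) + I_1 + I_2 − (V − E_L)/R
    dΘ_s/dt   = −b_s Θ_s
    dI_j/dt   = −k_j I_j                     (j = 1, 2)
    dΘ_v/dt   = a_v (V − E_L) − b_v Θ_v

A spike is emitted at the first sample where `V > Θ_∞ + Θ_s + Θ_v`. After a
refractory gap equal to the spike cut length `δt` (state frozen; the trace is
filled with the crossing value, since the action-potential shape is not part
of the model), the state is reset:

    V   ← E_L + f_v (V⁻ − E_L) − δV
    Θ_s ← Θ_s + δΘ_s
    I_j ← f_j I_j + δI_j                     (f_j fixed to 1)
    Θ_v ← Θ_v (unchanged)

Level 1 is the classic LIF with reset to rest (`f_v = 0, δV = 0`); level 2
adds the voltage/threshold reset rules; level 3 instead adds the two
after-spike currents (ASCs, with `R` then refit jointly with them, flagged
`R_is_R_ASC`); level 4 combines both; level 5 adds the voltage-dependent
threshold. Mechanisms absent at a level are held at zero, which makes the
nesting structure exact: zeroing a mechanism's parameters collapses a higher
level onto a lower one sample-for-sample (tested).

### Integration

Forward Euler at the stimulus sampling interval for the coupled pair
(`V`, `Θ_v`); exact exponential factors `e^{−b_s h}`, `e^{−k_j h}` for the
autonomous decays. The equations are linear and the scheme is stable at the
5–100 kHz rates used here. Spike times are reported at the left edge of the
crossing sample under strict inequality (no ties). A refractory period
shorter than one sample is rounded up to one sample with a warning. The
constant-current inter-spike interval agrees with the closed-form LIF
solution `δt + RC ln(IR/(IR − (Θ_∞ − E_L)))` to better than 1 % at 100 kHz.
Under grid refinement the first spike time and every inter-spike interval
change by less than one coarse step; absolute spike times far into a train
drift by the accumulated per-interval bias, as with any fixed-step scheme.
Everything is strict SI internally; file I/O may declare mV/pA.

## The synthetic protocol and its measurement model

The synthetic-data module generates ground-truth cells and the full stimulus
protocol, so every pipeline stage is testable without external recordings:

* **Pink noise** — 3 s epochs, 1/f power restricted to 1–100 Hz, coefficient
  of variation 0.2, at 75/100/125 % of the cell's long-pulse rheobase
  `(Θ_∞ − E_L)/R`, two repeats each; one seed for training ("noise1"), a
  second for hold-out testing ("noise2"). Each sweep carries a 0.5 s rest
  prefix used for the resting-potential fit. The noise is synthesized in the
  frequency domain (Gaussian coefficients shaped by 1/√f inside the band,
  zero outside) and affinely rescaled so the epoch mean and CV are exact.
* **Short squares** — a 9-step ladder of 3 ms pulses from 0.8× to 1.6× the
  amplitude that just reaches threshold in 3 ms.
* **Long square** — 1 s at 0.9× rheobase for the intrinsic-noise estimate.
* **Triple short squares** — three 3 ms pulses at 1.5× the short-square
  threshold amplitude, at inter-pulse intervals of 10, 20 and 40 ms.
* **Current steps** (optional) — 1 s steps at −10…−90 pA and a depolarizing
  ladder, for feature extraction.

If the supra-threshold noise epoch evokes no spikes (strongly adapting
cells), its amplitude is raised in 25 % steps with a warning.

Noise and step sweeps are sampled at 10 kHz; the pulse protocols (short and
triple short squares) at 100 kHz, because a threshold crossing during fast
pulse charging is quantized by roughly (slope × sample period) — up to
~1.5 mV at 10 kHz — which would dominate the millivolt-scale threshold
elevations those protocols exist to measure. Experimental threshold-probing
protocols are acquired at comparable rates.

Two noise sources are modeled. *Intrinsic membrane noise* is injected into
the integration as an AR(1)-consistent per-step voltage kick whose
stationary standard deviation is the requested `noise_sd` (default 0.2 mV);
this is what makes repeated sweeps jitter their spike times, gives the
data-to-data explained variance a value below 1, and is what the long-square
noise estimator recovers. *Recording noise* (default `noise_sd/8`,
band-limited to ~kHz, emulating the acquisition filter chain) is added to
the stored trace; it is what makes the pre/post-spike reset regression
stochastic. Purely additive noise alone would leave repeats bit-identical;
purely intrinsic noise alone would make the reset relation exactly
deterministic — both layers are needed for the fits to face realistic
residuals. Real neurons have richer noise (channel state, electrode drift);
passing recovery tests here demonstrates correctness of the estimators under
the stated model, not robustness to every artifact of real recordings.

A stereotyped spike waveform is pasted over each spike-cut window: a ~0.1 ms
rise to ~40 mV above the crossing voltage, a ~0.4 ms fall to a trough below
the reset voltage, then linear relaxation to the model's reset value at the
window end. Peak and trough carry seeded per-spike jitter (sd 3 mV). The
jitter matters: a purely affine template would make every sample inside the
window an exact linear function of the onset voltage, leaving the spike cut
length unidentifiable; real spike shapes vary nonlinearly from spike to
spike, and that variability is what pins the regression minimum at the true
cut length.

Default archetypes: four profiles (fast-spiking-like, adapting
excitatory-like, bursting-like with a depolarizing fast ASC, delayed-like)
whose means differ by well over two pooled standard deviations in several
parameters, as a planted-partition fixture requires.

## Stage-1 fitting

* **Spike detection** — candidate upstrokes are runs of dV/dt above a 20 V/s
  floor; an event qualifies as a spike only if its maximum dV/dt reaches
  100 V/s and the voltage climbs ≥ 10 mV (passive charging under strong
  pulses exceeds 20 V/s, so the floor alone is not diagnostic). The onset is
  found by walking back from the peak to where dV/dt last dropped below 5 %
  of the event maximum; the threshold estimate subtracts half a pre-spike
  slope step to undo the expected sampling overshoot, while the raw sampled
  onset voltage is kept for the reset regression (the simulator's reset map
  acts on the sampled value).
* **E_L** — mean of the rest segments before the training noise.
* **δt, f_v, δV** — for every candidate post-spike offset on a one-sample
  grid up to 10 ms, the voltage at (onset + offset) is regressed on the
  onset voltage over all pooled spikes; the offset minimizing the summed
  squared residuals (over the set of spikes valid at every offset; ties
  toward shorter) is δt, and the slope/intercept give `f_v` and
  `δV = E_L(1 − f_v) − intercept`. The residual standard error is reported
  as a spike-reproducibility measure. Spikes whose onset is degenerate in
  variance (fixed-threshold models) fall back to an intercept-only fit.
* **R, C** — least squares on the sub-threshold noise epoch, solved with
  dV/dt as the regression *response* (`dV/dt = I_e/C − (V − E_L)/(RC)`).
  Putting the noisy derivative on the response side keeps the estimates
  unbiased; using it as a regressor attenuates C severely. Spike
  neighborhoods, including a 150 ms post-spike stretch (slow ASCs outlast
  the cut window), are masked.
* **δI_j, k_j, R_ASC** — for every unordered pair from the discrete rate
  library {1000, 333, 100, 33.3, 10} s⁻¹, dV/dt is regressed on the injected
  current, unit exponential regressors driven at each spike's reset sample,
  and −(V − E_L), over spike-cut-removed inter-spike samples; the pair with
  minimal residual sum of squares wins. The current coefficient is 1/C, so
  capacitance and resistance are refit jointly with the currents and the
  amplitudes stay internally consistent. Columns are scaled to unit norm
  before solving — raw SI columns span ten orders of magnitude and defeat
  rank tolerance checks otherwise. Total charges `Q_j = δI_j/k_j` are
  exposed for clustering.
* **b_s, δΘ_s** — threshold elevations of subsequent spikes in the triple
  short squares, relative to the first spike, fit by the accumulated
  exponential `δΘ_s Σ_l e^{−b_s Δ_l}` (amplitude linear given the rate; the
  rate from a bounded 1-D search; decay time excludes refractory gaps, where
  the state is frozen). An amplitude below 0.2 mV flags the rate
  unidentifiable.
* **a_v, b_v** — observed spike-onset thresholds in the supra-threshold
  noise are modeled as `Θ_∞ + Θ_s(t) + a_v g_{b_v}(t)` where `g` integrates
  the voltage equation along the *recorded* voltage (frozen inside cut
  windows); `a_v` is solved in closed form per candidate `b_v`. At level 5
  the two threshold fits alternate twice, subtracting the voltage-component
  contribution from the triple-short-square elevations — pulse-driven
  depolarization raises the threshold through that mechanism too, and
  ignoring it biases `b_s` by tens of percent.
* **Θ_∞ (initial)** — onset threshold of the lowest-amplitude spiking short
  square (ties averaged, compared relatively — the amplitudes are ~nA).

On noiseless synthetic cells the full stage-1 chain recovers C, R, E_L
essentially exactly and every mechanism parameter to within the grid
resolution; at 0.2 mV noise the mechanism parameters recover within 10 %.

## Stage-2 optimization (MLIN)

The intrinsic noise scale σ is the standard deviation of the linearly
detrended steady-state voltage during the sub-threshold long square (last
50 % of the pulse). A noiseless trace yields a floor of 10 µV, flagged
degenerate.

The model is then integrated with its resets imposed at the data spike times
(its own crossings do not reset). At each data spike the gap
`V_model − (Θ_∞ + Θ_s + Θ_v)` is recorded, plus the maximum gap per
inter-spike interval. The objective is

    Σ_spikes gap_i² / (2σ²)  −  Σ_intervals log Φ(−max_gap_j / σ),

a Gaussian log-density demanding threshold be reached exactly at each data
spike plus a survival penalty demanding the voltage stay below threshold in
between. The exact likelihood used originally is not published in the main
text; this is the simplest form with the stated structure and is isolated
behind `mlin_objective` so a different form can be slotted in. Because the
forced-spike voltage trace does not depend on Θ_∞, a threshold change shifts
all gaps by the opposite amount; the forced simulation runs once per sweep
and Nelder–Mead (absolute tolerance 10⁻⁴ V on Θ_∞, relative 10⁻⁶ on the
objective, ≤ 200 iterations) works on the shifted-gap objective exactly.
Only Θ_∞ is optimized; on synthetic ground truth it is recovered to within
0.5 mV, and it rescues the pulse-protocol bias of the stage-1 initializer
(which can start several mV high on strongly adapting cells).

## Evaluation

Spike trains are binned into counts over half-open `Δt` windows (10 ms by
default). For two binned trains, the pairwise explained variance is
`2 cov(a, b)/(var a + var b)` with population moments — equal to 1 exactly
for identical non-constant vectors, symmetric, undefined (flagged) for
constant vectors. The reported metric is the mean model-vs-repeat pwEV
divided by the mean over repeat pairs. Sub-threshold accuracy is the RMSE
outside all spike-cut windows. Models are excluded when the training
(noise 1) EV ratio falls below 20 % or a parameter leaves the plausibility
box (C ∈ (1, 1000) pF, R ∈ (10, 3000) MΩ, Θ_∞ − E_L ∈ (1, 60) mV;
configurable).

## Features

Fourteen intrinsic electrophysiology features are computed from one-second
steps and the short squares: τ_m (anchored single-exponential fits over the
10 %-to-complete deflection window of hyperpolarizing steps; steps
deflecting < 3 mV are skipped as noise-dominated), R_i (deflection-vs-
amplitude slope), V_rest, sag, I_thresh, V_thresh, V_peak, V_fasttrough,
V_trough, upstroke:downstroke ratios for long and short squares, f–I slope,
first-spike latency, and maximum burst index. Burst detection classifies
each inter-spike interval as "direct" (membrane rising through the first
quarter after the cut window) or "delay" (hyperpolarizing first); the index
is `(f_in − f_out)/(f_in + f_out)` over maximal instantaneous rates, zero on
regular trains. The single-sweep τ_m estimator is noise-limited: at 0.05 mV
recording noise it tracks RC within 5 %, at 0.2 mV errors of 10–25 % occur
because the noise is correlated at exactly the membrane time constant.

## Clustering

Per-level parameter sets enter clustering (level 1: R, C, E_L, Θ_∞, δt;
level 2 adds f_v, δV; level 3 replaces the reset terms with the ASC charges
Q_1, Q_2 and uses R_ASC; level 4 has both). Charges rather than rates are
used because only two of five discrete library rates are chosen per cell.
Strictly positive scale parameters are log-transformed, every column
z-scored (with a relative-tolerance guard so constant columns standardize to
zero), and transforms recorded for exact inversion.

Iterative binary splitting cuts each node in two with Ward linkage and
accepts the split only if a linear SVM, trained on a random half over 100
rounds, classifies the held-out half with *minimum* accuracy ≥ 0.90 and both
children hold ≥ 5 cells. The threshold was calibrated on planted data:
genuinely separated nodes score ~1.00 while spurious bisections of a single
Gaussian reach ~0.80 (a hyperplane split of a blob is always learnable), so
the conventional-looking 0.80 over-splits. Affinity propagation is exposed
as an alternative backend behind the same partition contract.

Partitions are compared with the adjusted Rand index (chance-corrected pair
agreement) and the adjusted variation of information: `VI = H(p) + H(q) −
2I(p, q)` in nats, baselined by the mean VI against label-shuffled copies
(1000 shuffles, seeded), so 0 is chance and the attainable ceiling is
`ln(n)` — 6.47 for 645 cells. A composition table reports the fraction of
each label falling into each cluster (columns sum to 1).

On the default four-archetype population (50 cells each, fit end-to-end at
level 3), binary splitting recovers the archetypes exactly (ARI 1.0,
AVOI ≈ 2.7 against a ceiling of ln 200 ≈ 5.3).

## Problem sizes and determinism

The test suite runs the full pipeline at the sizes the analyses need and no
larger: per-level recovery uses one ground-truth cell per level (noiseless
and at 0.2 mV), the population property 20 cells, and the clustering
recovery 4 × 50 cells; the whole suite completes in under two minutes on one
core. All randomness flows through explicit seeds (population, noise,
shuffles, SVM rounds), and identical seeds reproduce reports bit-for-bit.

## Known limitations

* The MLIN functional form and the burst-detection operator are documented
  stand-ins behind stable interfaces.
* The synthesizer's spike waveform is a jittered triangle, not a
  biophysical action potential; spike-shape features are meaningful only
  relative to that template.
* Threshold measurements inherit sampling quantization of fast crossings;
  the pulse protocols are synthesized at 100 kHz and the crossing estimate
  is slope-corrected, but a residual positive bias of order 0.1 mV remains
  and is absorbed by the stage-2 optimization.
* Exclusion bounds and the split-acceptance threshold are configuration,
  not science; both are echoed in every report.
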