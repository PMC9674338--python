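# Methods

`sacglu` implements a three-stage computational chain for studying how the
kinetics of glutamatergic bipolar-cell (BC) input shape direction
selectivity in starburst amacrine cell (SAC) dendrites: (1) kinetics
metrics on iGluSnFR ΔF/F traces, (2) vesicle release-rate inference by
quantal deconvolution, and (3) a compartmental SAC model driven by the
inferred release profiles. A seeded synthetic-data generator provides
inputs with the statistical structure the analysis assumes, so the whole
chain is testable without imaging data.

## Trace kinetics

ΔF/F is `(F − F0)/F0` with `F0` the mean raw fluorescence in a 1-s window
before stimulus onset. ROI selection uses

    SNR = peak ΔF/F in the stimulus window / s.d. of baseline ΔF/F,

with the baseline s.d. taken over the same 1-s pre-stimulus window; only
ROIs with SNR strictly greater than 4 pass. Response kinetics are
summarized by the sustained/transient index

    STi = mean ΔF/F over the plateau window / peak ΔF/F,

where the peak is taken over the whole stimulus window and the plateau
window defaults to the last 1 s of a 2-s stimulus (both configurable for
other stimulus durations). STi = 0 is a purely transient response,
STi = 1 purely sustained. Negative plateau means are reported as-is; the
`STi ∈ [0, 1]` guarantee holds when ΔF/F is nonnegative and the plateau
window lies inside the peak window. Rise time is the 20%→80% interval on
the rising phase and latency the time from stimulus onset to 20% of
peak, both linearly interpolated between samples; the 20% latency
fraction is a convention choice (field-standard, configurable).

Reverse-correlation kernels are response-weighted averages of a
0.5-neutral contrast stimulus, `0.5 + Σ r(t)(s(t−ℓ)−0.5)/Σ r(t)`. Their
biphasic indices use clamped excursions about neutral contrast:
`peak index = Trough/(Peak+Trough)` with `Peak = clip(max c − 0.5, 0, 1)`
and `Trough = clip(0.5 − min c, 0, 1)`, and
`area index = −negative/(positive − negative)` with `positive` and
`negative` the sums of `clip(c − 0.5, 0, 1)` and `clip(c − 0.5, −1, 0)`.
Both are 0 for purely positive kernels and 1 for purely negative ones.
This is a 1-D temporal reverse correlation; no spatial stimulus
structure is modelled.

## Release-rate inference

The inference model treats a trace as a linear superposition of quantal
events: `response = rate ∗ quantum`. The quantum is a peak-normalized
double exponential with default time constants 2 ms (rise) and 30 ms
(decay); an alpha-function variant is available (with τ_rise ≪ τ_decay
the two are numerically close). The time constants are fitted by least
squares to the average of peak-aligned spontaneous-event snippets.

The quantal **amplitude** comes from fluctuation analysis of the
steady-state response, `QSE = 2σ²/µ` (variance and mean over the last 1 s
of the stimulus — the same window as the STi plateau; the window is an
analysis choice). By Campbell's theorem this identity is exact for
Poisson shot noise with a single-exponential quantum; for the 2/30-ms
double exponential it carries a shape factor of ≈1.14, which we accept
as a known small bias rather than altering the classical formula. Two
practical refinements:

* the baseline ΔF/F variance (measurement noise) is subtracted from the
  steady-state variance before the ratio, standard background correction
  in quantal analysis;
* the pipeline pools the ratio across the ROIs of a scan-field group
  (`2·Σσ²/Σµ`). At steady-state rates of a few vesicles per second a
  single ROI's 1-s plateau contains only ~3–6 quanta and the per-ROI
  ratio is ill-conditioned (its mean can even be non-positive); the
  pooled ratio is the fluctuation estimate for the field, consistent
  with computing prototypical release rates from field-averaged
  responses. Per-ROI QSE values are still reported.

Deconvolution divides the ΔF/F spectrum by the quantum's spectrum. The
division is stabilized (the operation is otherwise noise-amplifying and
ill-posed) by Wiener-style regularization `Q*/(|Q|² + ε·max|Q|²)` with
ε = 1e-3 and a Gaussian low-pass with half-amplitude at 20 Hz,
approximately the quantum's own bandwidth. Traces are padded to the next
power of two with their baseline mean before the FFT. The quantum kernel
is sampled **frame-averaged** (mean of the continuous waveform over each
frame): at imaging frame rates (58.25 Hz against a 30-ms decay),
pointwise sampling under-counts the quantum's area by tens of percent and
would bias all rates. At DC the division enforces conservation — the
integral of the recovered rate equals (response integral)/(quantum
integral) to ≈0.1%.

The raw rate estimate can go negative where noise dominates; release is
nonnegative, so the rate is rectified to ≥ 0 (the raw estimate is kept
alongside). Steady-state summaries average the **raw** rate over the
window and floor the average at zero: averaging the pointwise-rectified
rate would add the rectified noise to the estimate and measurably
inflates small rates (the ~1 vesicle/s distal group by several tens of
percent). The rectified rate is what the Poisson discretizer consumes.

Discretization draws independent Poisson counts in 1-ms bins with mean
`rate·bin`, event times at bin centers; counts over any window then have
Fano factor 1. Reconvolution (superposing quantal waveforms on the event
train, or convolving the continuous rate) closes the loop: on noiseless
input, deconvolve-then-reconvolve reproduces the trace to r ≥ 0.95,
limited only by the regularization bandwidth.

## Synthetic data generator

Traces are built exactly the way the inference model reads them, plus
noise: an inhomogeneous Poisson train on a fine grid (~1-ms bins tiling
the imaging frames), superposed quantal waveforms, frame integration to
58.25 Hz, and additive frame-level Gaussian noise. The release profile is

    rate(t) = baseline + plateau + (peak − plateau)·e^(−(t−t_on)/τ)

during the 2-s stimulus and `baseline` outside it, so the steady-state
rate *above baseline* — what a baseline-referenced ΔF/F measurement
reports — equals `plateau`. Defaults anchor to deconvolution-derived BC
estimates: onset peak 8 vesicles/s (within the 5–10 range), plateau 3
(sustained, proximal-like) or 1 (transient, distal-like) vesicles/s,
spontaneous baseline 0.2 vesicles/s, stimulus onset at 4 s. The onset
decay τ = 0.15 s is a generator tuning chosen so synthetic STi values
fall in the experimentally observed range; it is not a measured value.

Free parameters the source experiments do not constrain, chosen once:
quantal amplitude 1.0 ΔF/F (order of published iGluSnFR quantal events in
small ROIs), Gaussian noise s.d. 0.02 ΔF/F per frame (puts synthetic ROI
SNR in the comfortably-selected range, ~15–50), spontaneous recordings at
1 kHz ("high-speed" imaging must resolve the 2-ms rise). What the
generator does **not** emulate: spatial image structure, motion,
bleaching, sensor saturation and nonlinearity, correlated noise across
ROIs, glutamate spillover. Passing tests therefore demonstrate estimator
correctness under the model's own assumptions (linear superposition,
Poisson release, additive Gaussian noise), not robustness to those
physical effects.

## Compartmental SAC model

A ball-and-stick cell: one somatic compartment (8-µm equivalent
cylinder) plus three passive dendritic sections — initial 0–40 µm ×
0.9 µm, middle 40–110 µm × 0.4 µm, terminal 110–150 µm × 0.3 µm —
discretized at 2 µm. Passive stand-ins (the source model's exact values
are not published in text): C_m = 1 µF/cm², R_m = 20 kΩ·cm²,
R_a = 100 Ω·cm, leak reversal −60 mV. All exposed in `SACModel`.

Synapses: 6 proximal and 12 distal positions drawn per trial from
truncated-Gaussian stand-in densities (proximal 25 ± 10 µm on [5, 45];
distal 75 ± 20 µm on [45, 145]; replaceable by user-supplied tables).
Each vesicle triggers an AMPA-like double-exponential conductance
(0.14 ms rise, 0.54 ms decay, 0 mV reversal, linear summation — no
saturation or desensitization), with peak conductance scaled linearly
from 172.2 pS at 5 µm to 68.6 pS at 145 µm (the synapse-bearing extent).

A 400-µm bar moving at 0.1–2 mm/s along the dendrite axis (soma at 0;
centrifugal = soma→tip) activates each synapse while it overlaps the
synapse's 60-µm receptive field, i.e. for `(400+60)/v` seconds. During
that window the synapse replays its canonical release profile: onset
transient first, plateau held until the bar leaves the field. Trains are
drawn from the windowed rate in 1-ms Poisson bins. Because the bar's
transit over a receptive field is direction-independent, each synapse's
train is drawn once per presentation and reused for both directions
(common random numbers): the direction comparison then isolates relative
timing rather than train sampling noise. Within a repeat, several
presentations (default 5) are simulated per direction and the peak Ca
responses averaged — the usual trial-averaging step.

The cable equation is integrated by backward Euler (Thomas algorithm on
the tridiagonal system) at 0.025 ms, resolving the 0.54-ms conductance
decay; synaptic gating variables decay analytically between vesicle
impulses. Halving the time or space step changes peak somatic voltage by
<1%, and the steady state matches the sealed-end finite-cable solution
`V(x) = I·R∞·cosh((L−x)/λ)/sinh(L/λ)` to <1%.

Terminal Ca²⁺ is read out (no feedback onto voltage) through a
Boltzmann-activated conductance on the distal-most compartment
(half-activation −30 mV, slope 6 mV, instantaneous activation, reversal
+45 mV) feeding a pool `dCa/dt = k·I_Ca − Ca/τ` with τ = 50 ms; Ca is in
arbitrary units since only peaks are compared. DSi defaults to the
literal subtraction `peakCa(CF) − peakCa(CP)`; the bounded
`(CF−CP)/(CF+CP)` index is reported alongside.

Experiments: velocity sweeps under four input arrangements (native
sustained-proximal/transient-distal, swapped, all-sustained,
all-transient), incremental conversion of sustained inputs to transient
(furthest proximal site first) at 0.15 mm/s, and an OLS regression of
per-roster |DSi| on the proximal–distal centroid distance.
`run_direction_pair(..., deterministic=True)` scales rates up 64-fold and
conductances down accordingly — the infinite-vesicle limit — for
studying the model's expected (noise-free) timing structure.

### Behavior and known limitations

With these stand-in parameters the model reproduces the qualitative
structure of the source study: positive DSi for the native arrangement at
slow velocities in every sampled roster (deterministic limit), sign
reversal when kinetics are swapped, intermediate DSi for homogenized
kinetics, DSi declining toward zero by 2 mm/s, and DSi falling roughly
linearly as sustained inputs are converted to transient. Quantitatively
the directional modulation is small (normalized DSi ~0.01–0.02): at
realistic release rates the plateau-coincidence signal is sub-millivolt
against Poisson shot noise from large, sparse quantal conductances, so
single-presentation DSi is noisy and sign consistency is a property of
means over repeats/presentations, not of single trials. Two quantitative
mismatches are documented rather than hidden: (1) the stochastic
peak-Ca statistic acquires a small positive bias at high velocities that
masks the deterministic velocity tuning, so the tuning invariant is
asserted in the deterministic limit; (2) the variance in DSi across
rosters explained by centroid distance is only ~5–9% here, below the
≈21% reported for the original model — the geometry dependence evidently
hinges on the unpublished channel parameters and the connectomic
position densities, for which ours are stand-ins.

## Problem sizes

Default test/acceptance scales, chosen for precision at desk scale: 120
synthetic ROIs per group for release-rate recovery (the group-mean
steady-state estimator has ~7–10% sampling s.d. there; 50 ROIs, the
experimental n, leaves the ratio estimate with ~13% s.d.); 24 rosters ×
5 presentations for the direction-sign experiments; 100 rosters for the
distance regression; 600–1000 seeds for Poisson statistics checks.
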