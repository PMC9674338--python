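# sacglu

Glutamate input kinetics along starburst amacrine cell dendrites:
trace metrics, vesicle release-rate inference, and a compartmental
direction-selectivity model.

Starburst amacrine cells (SACs) compute motion direction in the retina.
The *space-time wiring* account holds that bipolar cells with **sustained**
release kinetics contact **proximal** SAC dendrites while **transient**
bipolar cells contact **distal** dendrites, so that excitation sums
optimally for motion from soma to tip (centrifugal). `sacglu` implements
the computational chain used to test this idea with the glutamate sensor
iGluSnFR, for retinal physiologists and modellers:

1. **Kinetics** of ΔF/F responses per region of interest (ROI):
   signal-to-noise ratio `SNR = peak ΔF/F ÷ s.d.(baseline)` with the
   strict `SNR > 4` selection rule, the sustained/transient index
   `STi = ⟨ΔF/F⟩_plateau ÷ peak ΔF/F` (0 = purely transient, 1 = purely
   sustained; plateau = last 1 s of the stimulus), 20–80% rise times,
   latencies, and reverse-correlation kernels with biphasic indices.
2. **Release-rate inference** by quantal deconvolution:
   `RR = IFFT[FFT(response)/FFT(quantum)]` with Wiener regularization,
   where the quantum is a 2 ms-rise / 30 ms-decay unitary event fitted to
   spontaneous activity and scaled by the quantal size estimate
   `QSE = 2σ²/µ` from steady-state fluctuations (Campbell's theorem).
   Rates are discretized into vesicle trains by a 1-ms Poisson process
   and validated by reconvolution.
3. **A ball-and-stick SAC model** (backward-Euler cable solver, numba):
   6 proximal + 12 distal bipolar synapses per trial, AMPA-like
   0.14/0.54 ms miniature conductances (172.2→68.6 pS along the
   dendrite), a 400-µm bar moving at 0.1–2 mm/s over 60-µm receptive
   fields, terminal Ca²⁺ readout, and the direction-selectivity index
   `DSi = peakCa(centrifugal) − peakCa(centripetal)` with velocity
   sweeps, kinetics-swap, homogenized-input, incremental-conversion and
   DSi-vs-geometry experiments.
4. **A seeded synthetic-data generator** (Poisson vesicle trains →
   quantal waveforms → frame-rate sampling → Gaussian noise) so every
   stage is testable without imaging data.

See `docs/methods.md` for the model details, parameter defaults and
known limitations.

## Worked example

```bash
python examples/simulate_direction_selectivity.py
```

prints (expectation limit, 4 synapse rosters per condition):

```
normalized DSi of peak terminal Ca (mean over 4 rosters, deterministic limit)

   condition   0.15 mm/s    0.5 mm/s    2.0 mm/s
      native     +0.0167     +0.0141     +0.0042
     swapped     -0.0257     -0.0132     -0.0007
```

With the native arrangement (sustained proximal, transient distal) the
model prefers centrifugal motion (DSi > 0) at slow bar speeds, the
preference collapses toward zero at 2 mm/s, and swapping which dendritic
zone receives sustained vs transient input reverses the preferred
direction — the space-time wiring signatures.

```bash
python examples/infer_release_rates.py
```

```
fitted quantum: rise 2.00 ms, decay 30.1 ms (truth: 2.00 / 30.0)
recovered steady-state rates (vesicles/s): {'distal': 0.93, 'proximal': 2.75}
proximal/distal ratio: 2.96 (truth: 3.0)
reconvolution check on p000: Pearson r = 0.986 against the noisy trace
```

The deconvolution pipeline recovers the generator's sustained ≈3 and
transient ≈1 vesicles/s steady-state release rates and their ≈3-fold
proximal/distal ratio from noisy synthetic fluorescence, and
reconvolving the estimated rate reproduces the measured trace.

The other examples (`analyze_kinetics.py`, `fit_quantal_waveform.py`)
demonstrate the STi gradient between proximal and distal input and the
quantal-waveform fit. A thin command line (`sacglu generate`,
`analyze-kinetics`, `infer-release`, `simulate-ds`) wraps the same
functions for shell pipelines.

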