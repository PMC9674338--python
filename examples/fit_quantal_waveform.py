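"""Fit the unitary iGluSnFR event from spontaneous quantal activity.

Simulates a high-speed (1 kHz) recording of sparse spontaneous quantal
events, cuts snippets around the true event times, and fits a
peak-normalized double exponential to the snippet average.  The fitted
time constants should recover the generator's 2 ms rise and 30 ms decay;
this waveform is the deconvolution kernel for release-rate inference.
"""

from sacglu import release, synth

trace, times = synth.synthesize_spontaneous(
    event_rate_vps=1.0, duration_s=120.0, seed=0, frame_rate_hz=1000.0
)
print(f"simulated {times.size} spontaneous events over 120 s at 1 kHz")

snips = release.extract_snippets(trace, times, pre_s=0.01, post_s=0.15)
fit = release.fit_quantum(snips, dt_s=trace.dt_s)

print(f"fitted rise  τ = {fit.tau_rise_s * 1e3:.2f} ms   (truth 2.00 ms)")
print(f"fitted decay τ = {fit.tau_decay_s * 1e3:.2f} ms  (truth 30.00 ms)")
print(f"fitted amplitude = {fit.amplitude:.3f} ΔF/F (truth 1.000)")
print(f"r.m.s. fit residual = {fit.fit_residual:.4f} ΔF/F")
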