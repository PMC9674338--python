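"""Synthetic iGluSnFR data with the statistical structure the analysis assumes.

Traces are built exactly the way the inference model reads them: an
inhomogeneous Poisson vesicle train drawn from a release-rate profile,
superposed quantal waveforms (2 ms rise / 30 ms decay by default),
frame-integration down to the imaging frame rate (58.25 Hz default) and
additive frame-level Gaussian noise.  Sustained (plateau-rich, ~3
vesicles/s steady state) and transient (onset-dominated, ~1 vesicle/s)
profiles emulate proximal and distal bipolar-cell inputs respectively.

Everything is seeded; identical seeds give bit-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .release import QuantalWaveform, ReleaseRate, VesicleTrain
from .trace_io import RecordingSet, ROITrace

__all__ = [
    "ReleaseProfileSpec",
    "NoiseSpec",
    "make_release_profile",
    "synthesize_trace",
    "synthesize_fov",
    "synthesize_spontaneous",
]


@dataclass
class ReleaseProfileSpec:
    """Parametric vesicle release-rate profile.

    The rate is ``baseline + plateau + (onset_peak − plateau)·exp(−(t −
    t_on)/τ)`` during the stimulus and the spontaneous *baseline_vps*
    outside it, so the steady-state rate **above baseline** — what a
    baseline-referenced ΔF/F measurement reports — equals *plateau_vps*.
    Defaults
    follow the deconvolution-based estimates for retinal bipolar cells:
    onset peaks of 5–10 vesicles/s and steady states of ~3 (sustained,
    proximal-like) or ~1 (transient, distal-like) vesicles/s.
    """

    kind: str = "sustained"
    onset_peak_vps: float = 8.0
    transient_tau_s: float = 0.15
    plateau_vps: float = 3.0
    baseline_vps: float = 0.2
    stim_onset_s: float = 4.0
    stim_duration_s: float = 2.0
    # during the stimulus the total rate is baseline + plateau + transient;
    # a baseline-referenced ΔF/F measurement therefore sees the plateau value.

    def __post_init__(self) -> None:
        for name in ("onset_peak_vps", "plateau_vps", "baseline_vps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.plateau_vps > self.onset_peak_vps:
            raise ValueError("plateau must not exceed the onset peak")

    @classmethod
    def sustained(cls, **kw) -> "ReleaseProfileSpec":
        return cls(kind="sustained", plateau_vps=kw.pop("plateau_vps", 3.0), **kw)

    @classmethod
    def transient(cls, **kw) -> "ReleaseProfileSpec":
        return cls(kind="transient", plateau_vps=kw.pop("plateau_vps", 1.0), **kw)

    @property
    def stim_offset_s(self) -> float:
        return self.stim_onset_s + self.stim_duration_s

    def rate_at(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the rate (vesicles/s) at times *t*."""
        t = np.asarray(t, float)
        rel = t - self.stim_onset_s
        evoked = (
            self.baseline_vps
            + self.plateau_vps
            + (self.onset_peak_vps - self.plateau_vps)
            * np.exp(-np.clip(rel, 0.0, None) / self.transient_tau_s)
        )
        in_stim = (rel >= 0) & (rel < self.stim_duration_s)
        return np.where(in_stim, evoked, self.baseline_vps)

    def evoked_rate_at(self, t_local: np.ndarray) -> np.ndarray:
        """Evoked rate only, on a stimulus-locked clock (t = 0 at onset).

        The onset transient plays first and the plateau is held for as
        long as asked — the form used to stretch a profile to an
        arbitrary stimulus duration (e.g. a moving bar's dwell time).
        """
        t_local = np.asarray(t_local, float)
        return (
            self.baseline_vps
            + self.plateau_vps
            + (self.onset_peak_vps - self.plateau_vps)
            * np.exp(-np.clip(t_local, 0.0, None) / self.transient_tau_s)
        )


@dataclass
class NoiseSpec:
    """Frame-level additive Gaussian noise and acquisition rate."""

    gaussian_sd: float = 0.02
    frame_rate_hz: float = 58.25

    def __post_init__(self) -> None:
        if self.gaussian_sd < 0:
            raise ValueError("noise sd must be nonnegative")


def make_release_profile(
    spec: ReleaseProfileSpec, duration_s: float = 8.0, bin_s: float = 0.001
) -> ReleaseRate:
    """Sample the parametric profile onto a regular (default 1-ms) clock."""
    t = np.arange(0.0, duration_s, bin_s)
    return ReleaseRate(time_s=t, rate_vps=spec.rate_at(t), meta={"kind": spec.kind})


def _fine_grid(noise: NoiseSpec, duration_s: float) -> tuple[float, int, int]:
    dt_frame = 1.0 / noise.frame_rate_hz
    oversample = max(1, int(np.ceil(dt_frame / 0.001)))
    n_frames = int(round(duration_s * noise.frame_rate_hz))
    return dt_frame, oversample, n_frames


def synthesize_trace(
    profile: ReleaseProfileSpec,
    quantum: QuantalWaveform | None = None,
    noise: NoiseSpec | None = None,
    seed: int | None = 0,
    duration_s: float = 8.0,
    roi_id: str = "synth0",
    f0: float = 100.0,
    group: str = "unassigned",
    radial_distance_um: float | None = None,
) -> tuple[ROITrace, dict]:
    """Poisson train → superposed quanta → frame resampling → noise.

    The Poisson process is sampled on a fine grid of ≈1-ms bins that tiles
    the imaging frames exactly; fluorescence is integrated (averaged) over
    each frame, emulating frame-rate acquisition.  Raw fluorescence is
    ``f0·(1 + signal + noise)``; ΔF/F is left for the analysis pipeline to
    compute.  Returns the trace and a ground-truth dict holding the drawn
    :class:`~sacglu.release.VesicleTrain`, the fine-grid rate profile and
    the noiseless frame-rate signal.
    """
    quantum = quantum or QuantalWaveform()
    noise = noise or NoiseSpec()
    dt_frame, over, n_frames = _fine_grid(noise, duration_s)
    dt_fine = dt_frame / over
    n_fine = n_frames * over
    t_fine = np.arange(n_fine) * dt_fine
    rate = profile.rate_at(t_fine)

    rng = np.random.default_rng(seed)
    counts = rng.poisson(rate * dt_fine)
    kernel_len = min(n_fine, int(round(8 * quantum.tau_decay_s / dt_fine)))
    kernel = quantum.sample(dt_fine, kernel_len, frame_average=False)
    signal_fine = np.convolve(counts.astype(float), kernel)[:n_fine]
    signal = signal_fine.reshape(n_frames, over).mean(axis=1)
    dff_noisy = signal + rng.normal(0.0, noise.gaussian_sd, n_frames)

    trace = ROITrace(
        roi_id=roi_id,
        time_s=np.arange(n_frames) * dt_frame,
        f_raw=f0 * (1.0 + dff_noisy),
        stim_onset_s=profile.stim_onset_s,
        stim_offset_s=min(profile.stim_offset_s, (n_frames - 1) * dt_frame),
        group=group,
        radial_distance_um=radial_distance_um,
    )
    truth = {
        "train": VesicleTrain((t_fine + dt_fine / 2)[counts > 0].repeat(counts[counts > 0]), seed=seed),
        "profile": profile,
        "rate_fine": ReleaseRate(time_s=t_fine, rate_vps=rate),
        "clean_dff": signal,
    }
    return trace, truth


def synthesize_fov(
    n_proximal_rois: int,
    n_distal_rois: int,
    sustained_spec: ReleaseProfileSpec | None = None,
    transient_spec: ReleaseProfileSpec | None = None,
    quantum: QuantalWaveform | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    duration_s: float = 8.0,
    fov_id: str = "fov0",
) -> tuple[RecordingSet, dict]:
    """A labeled field of view mixing sustained- and transient-profile ROIs.

    Proximal ROIs carry the sustained profile (radial distances drawn in
    5–45 µm), distal ROIs the transient one (45–145 µm).  Returns the
    recording plus ``{roi_id: truth}`` ground-truth metadata.
    """
    sustained_spec = sustained_spec or ReleaseProfileSpec.sustained()
    transient_spec = transient_spec or ReleaseProfileSpec.transient()
    rng = np.random.default_rng(seed)
    traces, truths = [], {}
    plan = [("proximal", sustained_spec, n_proximal_rois), ("distal", transient_spec, n_distal_rois)]
    i = 0
    for group, spec, count in plan:
        lo, hi = (5.0, 45.0) if group == "proximal" else (45.0, 145.0)
        for _ in range(count):
            roi_id = f"{group[0]}{i:03d}"
            trace, truth = synthesize_trace(
                spec,
                quantum,
                noise,
                seed=int(rng.integers(0, 2**31 - 1)),
                duration_s=duration_s,
                roi_id=roi_id,
                group=group,
                radial_distance_um=float(rng.uniform(lo, hi)),
            )
            trace.fov_id = fov_id
            traces.append(trace)
            truths[roi_id] = truth
            i += 1
    provenance = {
        "generator": "sacglu.synth.synthesize_fov",
        "seed": seed,
        "ground_truth": {
            rid: {"kind": tr["profile"].kind, "plateau_vps": tr["profile"].plateau_vps}
            for rid, tr in truths.items()
        },
    }
    noise = noise or NoiseSpec()
    return RecordingSet(traces, frame_rate_hz=noise.frame_rate_hz, provenance=provenance), truths


def synthesize_spontaneous(
    event_rate_vps: float = 1.0,
    duration_s: float = 60.0,
    quantum: QuantalWaveform | None = None,
    noise: NoiseSpec | None = None,
    seed: int | None = 0,
    frame_rate_hz: float = 1000.0,
) -> tuple[ROITrace, np.ndarray]:
    """Sparse spontaneous quantal events on a noisy baseline.

    Imaged at high speed (default 1 kHz, resolving the 2-ms rise) so the
    events are usable for quantal-waveform fitting; returns the trace and
    the ground-truth event times.  Warns when ``rate·τ_decay > 0.2``
    (events begin to overlap).
    """
    quantum = quantum or QuantalWaveform()
    noise = noise or NoiseSpec(frame_rate_hz=frame_rate_hz)
    if event_rate_vps * quantum.tau_decay_s > 0.2:
        warnings.warn("event rate high enough for substantial event overlap")
    dt = 1.0 / noise.frame_rate_hz
    n = int(round(duration_s / dt))
    t = np.arange(n) * dt
    rng = np.random.default_rng(seed)
    counts = rng.poisson(event_rate_vps * dt, n)
    kernel_len = min(n, int(round(8 * quantum.tau_decay_s / dt)))
    kernel = quantum.sample(dt, kernel_len, frame_average=False)
    dff = np.convolve(counts.astype(float), kernel)[:n]
    dff += rng.normal(0.0, noise.gaussian_sd, n)
    trace = ROITrace(
        roi_id="spont0", time_s=t, f_raw=100.0 * (1.0 + dff), dff=dff
    )
    return trace, t[counts > 0].repeat(counts[counts > 0])
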