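"""Trace-kinetics metrics for iGluSnFR responses.

The central quantities are the signal-to-noise ratio used to select ROIs,

    SNR = peak ΔF/F in the response window / s.d. of ΔF/F in a 1-s
          pre-stimulus baseline window,

and the sustained/transient index,

    STi = mean ΔF/F over the plateau window / peak ΔF/F,

where the plateau window defaults to the last 1 s of the light response.
STi = 0 marks a purely transient response (no plateau), STi = 1 a purely
sustained one (plateau equals peak).  Rise time (20→80% of peak on the
rising phase) and latency (stimulus onset to 20% of peak) characterize
response onset.  Reverse-correlation (stimulus-weighted average) temporal
kernels and their biphasic peak/area indices quantify responses to
white-noise stimulation on a 0.5-centered contrast scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trace_io import RecordingSet, ROITrace

__all__ = [
    "KineticsResult",
    "TemporalKernel",
    "compute_snr",
    "filter_rois",
    "compute_sti",
    "compute_rise_time",
    "compute_latency",
    "compute_sta_kernel",
    "biphasic_peak_index",
    "biphasic_area_index",
    "analyze_recording",
    "cumulative_sti",
]

SNR_THRESHOLD_DEFAULT = 4.0


@dataclass
class KineticsResult:
    """Per-ROI kinetics summary."""

    roi_id: str
    peak_dff: float
    plateau_dff: float
    sti: float
    snr: float
    rise_time_s: float | None
    latency_s: float | None
    passed_filter: bool
    group: str = "unassigned"
    radial_distance_um: float | None = None


@dataclass
class TemporalKernel:
    """A reverse-correlation kernel on the 0.5-centered contrast scale."""

    lag_s: np.ndarray
    contrast: np.ndarray

    @property
    def peak(self) -> float:
        """Positive excursion above neutral contrast, clamped to [0, 1]."""
        return float(np.clip(np.max(self.contrast) - 0.5, 0.0, 1.0))

    @property
    def trough(self) -> float:
        """Negative excursion below neutral contrast, clamped to [0, 1]."""
        return float(np.clip(0.5 - np.min(self.contrast), 0.0, 1.0))

    @property
    def positive_area(self) -> float:
        return float(np.sum(np.clip(self.contrast - 0.5, 0.0, 1.0)))

    @property
    def negative_area(self) -> float:
        """Signed (≤ 0) sum of the sub-neutral excursion."""
        return float(np.sum(np.clip(self.contrast - 0.5, -1.0, 0.0)))


def _stim_window(trace: ROITrace) -> tuple[float, float]:
    if trace.stim_onset_s is None or trace.stim_offset_s is None:
        raise ValueError(f"roi {trace.roi_id}: stimulus window not set")
    return trace.stim_onset_s, trace.stim_offset_s


def compute_snr(trace: ROITrace, baseline_window_s: tuple[float, float] | None = None) -> float:
    """Peak ΔF/F in the stimulus window over baseline ΔF/F s.d.

    The baseline window defaults to the 1 s before stimulus onset.
    """
    dff = trace.require_dff()
    on, off = _stim_window(trace)
    if baseline_window_s is None:
        baseline_window_s = (on - 1.0, on)
    base = dff[trace.window_mask(*baseline_window_s)]
    if base.size < 2:
        raise ValueError("baseline window too short for an s.d.")
    sd = float(np.std(base, ddof=1))
    if sd == 0:
        raise ValueError(f"roi {trace.roi_id}: degenerate baseline (zero s.d.)")
    peak = float(np.max(dff[trace.window_mask(on, off)]))
    return peak / sd


def filter_rois(
    rec: RecordingSet,
    snr_threshold: float = SNR_THRESHOLD_DEFAULT,
    baseline_window_s: tuple[float, float] | None = None,
) -> RecordingSet:
    """Retain exactly the ROIs with SNR strictly greater than *snr_threshold*."""
    keep = [
        t.roi_id
        for t in rec
        if compute_snr(t, baseline_window_s) > snr_threshold
    ]
    return rec.subset(keep)


def compute_sti(
    trace: ROITrace, plateau_window_s: tuple[float, float] | None = None
) -> float:
    """Sustained/transient index: plateau-mean ΔF/F over peak ΔF/F.

    The peak is taken over the full stimulus window; the plateau window
    defaults to the last 1 s of the stimulus.  Negative plateau means are
    reported as-is (no clipping).
    """
    dff = trace.require_dff()
    on, off = _stim_window(trace)
    if plateau_window_s is None:
        plateau_window_s = (off - 1.0, off)
    peak = float(np.max(dff[trace.window_mask(on, off)]))
    if peak <= 0:
        raise ValueError(f"roi {trace.roi_id}: no response (non-positive peak)")
    plateau_mask = trace.window_mask(*plateau_window_s)
    if not plateau_mask.any():
        raise ValueError("plateau window contains no samples")
    return float(np.mean(dff[plateau_mask])) / peak


def _first_crossing(time_s: np.ndarray, y: np.ndarray, level: float) -> float:
    """Time of the first upward crossing of *level*, linearly interpolated."""
    above = y >= level
    if above[0]:
        return float(time_s[0])
    idx = np.flatnonzero(~above[:-1] & above[1:])
    if idx.size == 0:
        raise ValueError(f"signal never crosses level {level:g}")
    i = idx[0]
    frac = (level - y[i]) / (y[i + 1] - y[i])
    return float(time_s[i] + frac * (time_s[i + 1] - time_s[i]))


def compute_rise_time(
    trace: ROITrace, lo_frac: float = 0.2, hi_frac: float = 0.8
) -> float:
    """20→80% rise time of the response within the stimulus window.

    Measured between the first upward crossings of ``lo_frac·peak`` and
    ``hi_frac·peak``, with linear interpolation between samples.
    """
    dff = trace.require_dff()
    on, off = _stim_window(trace)
    mask = trace.window_mask(on, off)
    t, y = trace.time_s[mask], dff[mask]
    peak = float(np.max(y))
    if peak <= 0:
        raise ValueError(f"roi {trace.roi_id}: no response (non-positive peak)")
    t_lo = _first_crossing(t, y, lo_frac * peak)
    t_hi = _first_crossing(t, y, hi_frac * peak)
    return t_hi - t_lo


def compute_latency(trace: ROITrace, frac: float = 0.2) -> float:
    """Time from stimulus onset to the first crossing of ``frac·peak``."""
    dff = trace.require_dff()
    on, off = _stim_window(trace)
    mask = trace.window_mask(on, off)
    t, y = trace.time_s[mask], dff[mask]
    peak = float(np.max(y))
    if peak <= 0:
        raise ValueError(f"roi {trace.roi_id}: no response (non-positive peak)")
    return _first_crossing(t, y, frac * peak) - on


def compute_sta_kernel(
    stimulus: np.ndarray,
    response: ROITrace | np.ndarray,
    max_lag_s: float,
    dt_s: float | None = None,
) -> TemporalKernel:
    """Response-weighted average of the stimulus at each lag.

    *stimulus* holds contrast values on the 0.5-neutral scale sampled on
    the same clock as the response.  For each lag ℓ the kernel value is
    ``0.5 + Σ_t r(t)·(s(t−ℓ)−0.5) / Σ_t r(t)``, i.e. the average stimulus
    contrast preceding the response, weighted by the response itself.
    """
    if isinstance(response, ROITrace):
        resp = response.require_dff()
        dt = response.dt_s
    else:
        resp = np.asarray(response, float)
        if dt_s is None:
            raise ValueError("dt_s required when response is a bare array")
        dt = dt_s
    stim = np.asarray(stimulus, float)
    if stim.shape != resp.shape:
        raise ValueError("stimulus and response must share a clock")
    n_lag = int(round(max_lag_s / dt)) + 1
    if n_lag > stim.size:
        raise ValueError("max_lag exceeds record length")
    w = resp[n_lag - 1 :]
    total = float(np.sum(w))
    if total <= 0:
        raise ValueError("non-positive total response weight")
    centered = stim - 0.5
    lags = np.arange(n_lag)
    kernel = np.array(
        [np.dot(w, centered[n_lag - 1 - k : stim.size - k]) / total for k in lags]
    )
    return TemporalKernel(lag_s=lags * dt, contrast=0.5 + kernel)


def biphasic_peak_index(kernel: TemporalKernel) -> float:
    """Trough / (Peak + Trough) of a 0.5-centered kernel, in [0, 1].

    0 for kernels that never dip below neutral contrast, 1 for kernels
    that never rise above it.
    """
    peak, trough = kernel.peak, kernel.trough
    if peak + trough == 0:
        raise ValueError("flat kernel: peak and trough both zero")
    return trough / (peak + trough)


def biphasic_area_index(kernel: TemporalKernel) -> float:
    """−negative / (positive − negative) with clamped lobe sums, in [0, 1]."""
    pos, neg = kernel.positive_area, kernel.negative_area
    if pos - neg == 0:
        raise ValueError("flat kernel: zero total area")
    return -neg / (pos - neg)


def analyze_recording(
    rec: RecordingSet,
    snr_threshold: float = SNR_THRESHOLD_DEFAULT,
    plateau_window_s: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Per-ROI kinetics table for a recording whose ΔF/F is computed.

    Rise time and latency are reported as NaN where no threshold crossing
    exists; STi and SNR are always computed (a non-positive peak raises).
    """
    rows = []
    for t in rec:
        snr = compute_snr(t)
        res = KineticsResult(
            roi_id=t.roi_id,
            peak_dff=float(np.max(t.require_dff()[t.window_mask(*_stim_window(t))])),
            plateau_dff=compute_sti(t, plateau_window_s)
            * float(np.max(t.require_dff()[t.window_mask(*_stim_window(t))])),
            sti=compute_sti(t, plateau_window_s),
            snr=snr,
            rise_time_s=_try(compute_rise_time, t),
            latency_s=_try(compute_latency, t),
            passed_filter=snr > snr_threshold,
            group=t.group,
            radial_distance_um=t.radial_distance_um,
        )
        rows.append(res.__dict__)
    return pd.DataFrame(rows)


def _try(fn, trace):
    try:
        return fn(trace)
    except ValueError:
        return float("nan")


def cumulative_sti(table: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Cumulative STi distribution per group (for Fig.-style summaries).

    Returns ``{group: (sorted_sti, cumulative_fraction)}`` over ROIs that
    passed the SNR filter.
    """
    out = {}
    passed = table[table["passed_filter"]]
    for group, sub in passed.groupby("group"):
        x = np.sort(sub["sti"].to_numpy())
        out[str(group)] = (x, np.arange(1, x.size + 1) / x.size)
    return out
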