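"""Read, write, and preprocess ROI fluorescence time series.

Traces are stored as :class:`ROITrace` objects grouped in a
:class:`RecordingSet`.  Two on-disk formats are supported:

* ``table`` — a comma-separated file with a ``time_s`` column plus one
  column per ROI, and an optional JSON sidecar (``<path>.meta.json``)
  holding per-ROI metadata (stimulus window, dendritic position, group).
* ``container`` — an HDF5 file with one dataset per ROI and metadata
  stored as attributes; lossless for all fields.

ROIs can also be extracted from a multi-frame TIFF stack over a regular
grid with :func:`extract_rois`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "ROITrace",
    "RecordingSet",
    "read_traces",
    "write_traces",
    "compute_dff",
    "extract_rois",
]


@dataclass
class ROITrace:
    """One region of interest's fluorescence time series.

    Parameters
    ----------
    roi_id, fov_id
        Identifiers of the ROI and the field of view it came from.
    time_s
        Strictly increasing sample times in seconds.
    f_raw
        Raw fluorescence in arbitrary units.
    dff
        ΔF/F, present only after :func:`compute_dff` (or when the trace was
        synthesized directly in ΔF/F units).
    stim_onset_s, stim_offset_s
        Stimulus window in seconds; must lie within the trace extent.
    radial_distance_um
        Distance of the ROI center from the soma, if known.
    group
        ``"proximal"``, ``"distal"`` or ``"unassigned"``.
    """

    roi_id: str
    time_s: np.ndarray
    f_raw: np.ndarray
    fov_id: str = "fov0"
    dff: np.ndarray | None = None
    stim_onset_s: float | None = None
    stim_offset_s: float | None = None
    radial_distance_um: float | None = None
    group: str = "unassigned"

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.f_raw = np.asarray(self.f_raw, dtype=float)
        if self.time_s.ndim != 1 or self.time_s.shape != self.f_raw.shape:
            raise ValueError(f"roi {self.roi_id}: time and fluorescence shapes differ")
        if self.time_s.size >= 2 and not np.all(np.diff(self.time_s) > 0):
            raise ValueError(f"roi {self.roi_id}: non-monotonic time")
        if np.all(np.isnan(self.f_raw)):
            raise ValueError(f"roi {self.roi_id}: NaN-only trace")
        if self.dff is not None:
            self.dff = np.asarray(self.dff, dtype=float)
        if self.stim_onset_s is not None and self.stim_offset_s is not None:
            if not (
                self.time_s[0] <= self.stim_onset_s
                < self.stim_offset_s <= self.time_s[-1]
            ):
                raise ValueError(f"roi {self.roi_id}: stimulus window outside trace")

    @property
    def dt_s(self) -> float:
        return float(np.median(np.diff(self.time_s)))

    def window_mask(self, t0: float, t1: float) -> np.ndarray:
        """Boolean mask for samples with ``t0 <= t < t1``."""
        return (self.time_s >= t0) & (self.time_s < t1)

    def require_dff(self) -> np.ndarray:
        if self.dff is None:
            raise ValueError(f"roi {self.roi_id}: ΔF/F not computed")
        return self.dff


@dataclass
class RecordingSet:
    """A collection of :class:`ROITrace` sharing a common acquisition."""

    traces: list[ROITrace]
    frame_rate_hz: float | None = None
    provenance: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.traces)

    def __len__(self) -> int:
        return len(self.traces)

    def __getitem__(self, i: int) -> ROITrace:
        return self.traces[i]

    def roi_ids(self) -> list[str]:
        return [t.roi_id for t in self.traces]

    def subset(self, roi_ids: Sequence[str]) -> "RecordingSet":
        keep = set(roi_ids)
        return RecordingSet(
            [t for t in self.traces if t.roi_id in keep],
            frame_rate_hz=self.frame_rate_hz,
            provenance=dict(self.provenance),
        )


_META_FIELDS = (
    "fov_id",
    "stim_onset_s",
    "stim_offset_s",
    "radial_distance_um",
    "group",
)


def _meta_of(trace: ROITrace) -> dict:
    return {k: getattr(trace, k) for k in _META_FIELDS}


def read_traces(path: str | Path, format: Literal["table", "container"] = "table") -> RecordingSet:
    """Read a :class:`RecordingSet` from disk.

    ``table`` expects a CSV with a ``time_s`` column; each remaining column
    becomes one ROI.  ``container`` reads the HDF5 layout written by
    :func:`write_traces`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "table":
        return _read_csv(path)
    if format == "container":
        return _read_h5(path)
    raise ValueError(f"unknown format {format!r}")


def write_traces(
    rec: RecordingSet, path: str | Path, format: Literal["table", "container"] = "table"
) -> Path:
    """Write a :class:`RecordingSet`; inverse of :func:`read_traces`."""
    if len(rec) == 0:
        raise ValueError("cannot write an empty RecordingSet")
    path = Path(path)
    if format == "table":
        _write_csv(rec, path)
    elif format == "container":
        _write_h5(rec, path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def _read_csv(path: Path) -> RecordingSet:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing time column 'time_s'")
    time_s = df["time_s"].to_numpy(float)
    if time_s.size >= 2 and not np.all(np.diff(time_s) > 0):
        raise ValueError(f"{path}: non-monotonic time")
    meta_path = path.with_name(path.name + ".meta.json")
    meta = {}
    frame_rate = None
    provenance: dict = {}
    if meta_path.exists():
        sidecar = json.loads(meta_path.read_text())
        meta = sidecar.get("rois", {})
        frame_rate = sidecar.get("frame_rate_hz")
        provenance = sidecar.get("provenance", {})
    traces = []
    for col in df.columns:
        if col == "time_s":
            continue
        traces.append(
            ROITrace(roi_id=col, time_s=time_s, f_raw=df[col].to_numpy(float), **meta.get(col, {}))
        )
    if frame_rate is None and time_s.size >= 2:
        frame_rate = 1.0 / float(np.median(np.diff(time_s)))
    return RecordingSet(traces, frame_rate_hz=frame_rate, provenance=provenance)


def _write_csv(rec: RecordingSet, path: Path) -> None:
    cols = {"time_s": rec.traces[0].time_s}
    for t in rec.traces:
        if t.time_s.shape != rec.traces[0].time_s.shape or not np.allclose(
            t.time_s, rec.traces[0].time_s
        ):
            raise ValueError("table format requires a common time base across ROIs")
        cols[t.roi_id] = t.f_raw
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.10g")
    sidecar = {
        "frame_rate_hz": rec.frame_rate_hz,
        "provenance": rec.provenance,
        "rois": {t.roi_id: _meta_of(t) for t in rec.traces},
    }
    path.with_name(path.name + ".meta.json").write_text(json.dumps(sidecar, indent=1))


def _write_h5(rec: RecordingSet, path: Path) -> None:
    with h5py.File(path, "w") as h5:
        if rec.frame_rate_hz is not None:
            h5.attrs["frame_rate_hz"] = rec.frame_rate_hz
        h5.attrs["provenance"] = json.dumps(rec.provenance)
        h5.attrs["roi_order"] = json.dumps([t.roi_id for t in rec.traces])
        for t in rec.traces:
            g = h5.create_group(t.roi_id)
            g.create_dataset("time_s", data=t.time_s)
            g.create_dataset("f_raw", data=t.f_raw)
            if t.dff is not None:
                g.create_dataset("dff", data=t.dff)
            for k, v in _meta_of(t).items():
                if v is not None:
                    g.attrs[k] = v


def _read_h5(path: Path) -> RecordingSet:
    traces = []
    with h5py.File(path, "r") as h5:
        order = json.loads(h5.attrs.get("roi_order", "null")) or sorted(h5.keys())
        for roi_id in order:
            g = h5[roi_id]
            meta = {k: g.attrs[k] for k in _META_FIELDS if k in g.attrs}
            if "group" in meta:
                meta["group"] = str(meta["group"])
            if "fov_id" in meta:
                meta["fov_id"] = str(meta["fov_id"])
            traces.append(
                ROITrace(
                    roi_id=str(roi_id),
                    time_s=g["time_s"][...],
                    f_raw=g["f_raw"][...],
                    dff=g["dff"][...] if "dff" in g else None,
                    **meta,
                )
            )
        frame_rate = h5.attrs.get("frame_rate_hz")
        provenance = json.loads(h5.attrs.get("provenance", "{}"))
    return RecordingSet(traces, frame_rate_hz=frame_rate, provenance=provenance)


def compute_dff(trace: ROITrace, baseline_window_s: tuple[float, float] | None = None) -> ROITrace:
    """Return a copy of *trace* with ``dff = (f_raw − F0)/F0``.

    ``F0`` is the mean raw fluorescence over *baseline_window_s*, which
    defaults to the 1 s immediately preceding stimulus onset.  Requires
    ``F0 > 0``.
    """
    if baseline_window_s is None:
        if trace.stim_onset_s is None:
            raise ValueError("no baseline window given and no stimulus onset set")
        baseline_window_s = (trace.stim_onset_s - 1.0, trace.stim_onset_s)
    t0, t1 = baseline_window_s
    if trace.stim_onset_s is not None and t1 > trace.stim_onset_s:
        raise ValueError("baseline window must precede stimulus onset")
    mask = trace.window_mask(t0, t1)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    f0 = float(np.mean(trace.f_raw[mask]))
    if f0 <= 0:
        raise ValueError(f"roi {trace.roi_id}: non-positive baseline")
    return replace(trace, dff=(trace.f_raw - f0) / f0)


def extract_rois(
    stack: np.ndarray,
    grid_um: float,
    pixel_size_um: float,
    frame_rate_hz: float = 58.25,
    fov_id: str = "fov0",
) -> RecordingSet:
    """Tile a (frames, y, x) stack into square ROIs and average pixels.

    ROIs are non-overlapping ``grid_um``-edge squares in row-major order
    with 0-based ``r{row}c{col}`` identifiers; partial edge tiles are
    dropped.  *stack* may be an array or a TIFF file path.
    """
    if isinstance(stack, (str, Path)):
        import tifffile

        stack = tifffile.imread(str(stack))
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("stack must be (frames, y, x) with at least 2 frames")
    if grid_um <= 0 or pixel_size_um <= 0:
        raise ValueError("grid and pixel size must be positive")
    px = int(round(grid_um / pixel_size_um))
    n_frames, ny, nx = stack.shape
    if px > ny or px > nx:
        raise ValueError("ROI grid larger than the imaging field")
    time_s = np.arange(n_frames) / frame_rate_hz
    traces = []
    for r in range(ny // px):
        for c in range(nx // px):
            tile = stack[:, r * px : (r + 1) * px, c * px : (c + 1) * px]
            traces.append(
                ROITrace(
                    roi_id=f"r{r}c{c}",
                    fov_id=fov_id,
                    time_s=time_s,
                    f_raw=tile.mean(axis=(1, 2)),
                )
            )
    return RecordingSet(traces, frame_rate_hz=frame_rate_hz)
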