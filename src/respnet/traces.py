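"""Fluorescence trace containers, ΔF/F₀ normalization and Ca²⁺ event detection.

The central object is :class:`TraceSet`, a cells × frames matrix of mean ROI
intensities with a fixed frame interval.  Normalization follows the sliding
local-baseline convention used for slice-culture imaging: for every sample
F₁(t) the baseline F₀(t) is the average intensity within ±30 s around t, and
ΔF/F₀ = (F₁ − F₀)/F₀.  Events are local maxima of the normalized trace rising
at least a fixed fraction (default 20%) above a running baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal


@dataclass
class TraceSet:
    """Raw fluorescence intensities, one row per ROI.

    Parameters
    ----------
    values : (n_cells, n_frames) array
        Mean intensity of each ROI at each frame.
    frame_interval : float
        Seconds between consecutive frames (typically 0.1–2 s).
    roi_ids : list of str
        One label per ROI.
    roi_centroids : (n_cells, 2) array, optional
        Pixel coordinates (row, col) of each ROI centroid.
    """

    values: np.ndarray
    frame_interval: float
    roi_ids: list[str] = field(default_factory=list)
    roi_centroids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (n_cells, n_frames) array")
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 frames")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")
        if not self.roi_ids:
            self.roi_ids = [f"roi_{i:03d}" for i in range(self.n_cells)]
        if len(self.roi_ids) != self.n_cells:
            raise ValueError("roi_ids length does not match number of cells")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Time of frame i is i · frame_interval (frame 0 at t = 0)."""
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_interval

    def to_csv(self, path) -> None:
        """Write as a table with a leading ``time_s`` column, one column per ROI."""
        df = pd.DataFrame(self.values.T, columns=self.roi_ids)
        df.insert(0, "time_s", self.times)
        df.to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path) -> "TraceSet":
        df = pd.read_csv(path)
        if df.columns[0] != "time_s":
            raise ValueError("first column of a trace table must be 'time_s'")
        t = df["time_s"].to_numpy(float)
        if len(t) < 2:
            raise ValueError("trace table needs at least 2 frames")
        dt = float(np.median(np.diff(t)))
        return cls(values=df.iloc[:, 1:].to_numpy(float).T,
                   frame_interval=dt,
                   roi_ids=list(df.columns[1:]))


@dataclass
class NormalizedTraceSet:
    """ΔF/F₀ traces; same shape as the source TraceSet.

    ``invalid`` flags cells whose sliding baseline F₀ was ≤ 0 somewhere; their
    rows are NaN and they are excluded from correlation analysis.
    """

    values: np.ndarray
    frame_interval: float
    roi_ids: list[str]
    roi_centroids: np.ndarray | None = None
    invalid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.invalid is None:
            self.invalid = np.zeros(self.values.shape[0], dtype=bool)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.values.T, columns=self.roi_ids)
        df.insert(0, "time_s", self.times)
        df.to_csv(path, index=False, float_format="%.10g")


@dataclass
class EventSeries:
    """Per-cell Ca²⁺ transient times in seconds; a cell is active iff it has ≥ 1 event."""

    times: list[np.ndarray]
    roi_ids: list[str]

    @property
    def n_cells(self) -> int:
        return len(self.times)

    @property
    def active(self) -> np.ndarray:
        return np.array([len(t) > 0 for t in self.times], dtype=bool)

    @property
    def n_active(self) -> int:
        return int(self.active.sum())

    def to_csv(self, path) -> None:
        rows = [(self.roi_ids[i], t) for i in range(self.n_cells) for t in self.times[i]]
        pd.DataFrame(rows, columns=["cell_id", "event_time_s"]).to_csv(
            path, index=False, float_format="%.10g")


def _sliding_mean(x: np.ndarray, half: int) -> np.ndarray:
    """Centered moving average with window truncated at the edges.

    Window for sample i is [max(0, i-half), min(n-1, i+half)], inclusive of i.
    """
    n = x.shape[-1]
    c = np.concatenate([np.zeros(x.shape[:-1] + (1,)), np.cumsum(x, axis=-1)], axis=-1)
    i = np.arange(n)
    lo = np.maximum(i - half, 0)
    hi = np.minimum(i + half, n - 1)
    return (c[..., hi + 1] - c[..., lo]) / (hi - lo + 1)


def normalize_dff(traces: TraceSet, window_half_width: float = 30.0) -> NormalizedTraceSet:
    """ΔF/F₀ with a centered sliding baseline.

    F₀(t) is the mean intensity within ±``window_half_width`` seconds of t
    (window truncated at the recording edges), and
    ΔF/F₀(t) = (F(t) − F₀(t)) / F₀(t).

    Cells with F₀ ≤ 0 at any frame are flagged invalid (NaN rows) and a
    warning is issued; they are skipped by the correlation stage.
    """
    if not window_half_width > 0:
        raise ValueError("window_half_width must be positive")
    half = int(round(window_half_width / traces.frame_interval))
    f0 = _sliding_mean(traces.values, half)
    bad = np.any(f0 <= 0, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        dff = (traces.values - f0) / f0
    if bad.any():
        names = [traces.roi_ids[i] for i in np.flatnonzero(bad)]
        warnings.warn(f"non-positive baseline F0 for cells {names}; excluded from correlation")
        dff[bad] = np.nan
    return NormalizedTraceSet(values=dff, frame_interval=traces.frame_interval,
                              roi_ids=list(traces.roi_ids),
                              roi_centroids=traces.roi_centroids, invalid=bad)


def detect_events(norm: NormalizedTraceSet, threshold_frac: float = 0.20,
                  min_separation: float = 2.0,
                  baseline_window: float = 60.0,
                  baseline_percentile: float = 10.0) -> EventSeries:
    """Detect Ca²⁺ transients as peaks rising ≥ ``threshold_frac`` above baseline.

    The baseline is a running percentile (default 10th over 60 s) of the
    normalized trace; peaks are local maxima of ΔF/F₀ whose height above this
    baseline is at least ``threshold_frac`` (the 20% criterion).  Maxima closer
    than ``min_separation`` seconds are merged keeping the larger one.
    """
    dt = norm.frame_interval
    size = max(3, int(round(baseline_window / dt)) | 1)
    distance = max(1, int(round(min_separation / dt)))
    out: list[np.ndarray] = []
    for i in range(norm.n_cells):
        x = norm.values[i]
        if norm.invalid is not None and norm.invalid[i]:
            out.append(np.array([]))
            continue
        base = ndimage.percentile_filter(x, baseline_percentile, size=size,
                                         mode="nearest")
        peaks, _ = signal.find_peaks(x - base, height=threshold_frac,
                                     distance=distance)
        out.append(peaks * dt)
    return EventSeries(times=out, roi_ids=list(norm.roi_ids))


def rectify_smooth(trace: np.ndarray, frame_interval: float,
                   cutoff_hz: float = 0.06, smooth_window: float = 1.0,
                   mode: str = "lowpass") -> np.ndarray:
    """Filter, rectify and smooth a population/nerve trace.

    A 4th-order Butterworth filter at ``cutoff_hz`` (``mode`` selects
    low-pass, the printed convention, or high-pass) is applied forward and
    backward, the result is full-wave rectified, and a centered moving
    average of ``smooth_window`` seconds is applied.
    """
    x = np.asarray(trace, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D signal")
    if smooth_window < frame_interval:
        raise ValueError("smooth_window shorter than the frame interval")
    if mode not in ("lowpass", "highpass"):
        raise ValueError("mode must be 'lowpass' or 'highpass'")
    nyq = 0.5 / frame_interval
    if cutoff_hz >= nyq:
        raise ValueError("cutoff at or above the Nyquist frequency")
    sos = signal.butter(4, cutoff_hz / nyq, btype=mode, output="sos")
    padlen = min(x.size - 1, 3 * 8)
    y = signal.sosfiltfilt(sos, x, padlen=padlen)
    y = np.abs(y)
    win = max(1, int(round(smooth_window / frame_interval)))
    return ndimage.uniform_filter1d(y, size=win, mode="nearest")


def extract_rois_and_traces(stack: np.ndarray, min_area: int = 4,
                            max_area: int = 10_000,
                            smooth_sigma: float = 1.0) -> TraceSet:
    """Segment active cells from a time-lapse stack and extract their traces.

    ROIs are found on the per-pixel standard deviation of intensity over time:
    the SD image is Gaussian-smoothed, thresholded automatically (Otsu), and
    connected components with area in [min_area, max_area] become ROIs.  Each
    trace is the mean intensity inside its ROI per frame.

    Returns an empty TraceSet (with a warning) when no ROI is found.
    ``frame_interval`` is set to 1.0; callers that know the true interval
    should pass the stack's timing separately via :func:`set_frame_interval`
    or rebuild the TraceSet.
    """
    from skimage import filters, measure

    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("stack must be (n_frames, H, W) with at least 2 frames")
    sd = stack.std(axis=0)
    if smooth_sigma > 0:
        sd = filters.gaussian(sd, sigma=smooth_sigma, preserve_range=True)
    if np.ptp(sd) == 0:
        warnings.warn("no dynamic pixels in stack; returning empty TraceSet")
        return TraceSet(values=np.empty((0, stack.shape[0])),
                        frame_interval=1.0, roi_ids=[])
    mask = sd > filters.threshold_otsu(sd)
    labels = measure.label(mask)
    regions = [r for r in measure.regionprops(labels)
               if min_area <= r.area <= max_area]
    if not regions:
        warnings.warn("no ROI within the area bounds; returning empty TraceSet")
        return TraceSet(values=np.empty((0, stack.shape[0])),
                        frame_interval=1.0, roi_ids=[])
    flat = stack.reshape(stack.shape[0], -1)
    values = np.empty((len(regions), stack.shape[0]))
    centroids = np.empty((len(regions), 2))
    for i, r in enumerate(regions):
        lin = np.ravel_multi_index(tuple(r.coords.T), stack.shape[1:])
        values[i] = flat[:, lin].mean(axis=1)
        centroids[i] = r.centroid
    return TraceSet(values=values, frame_interval=1.0,
                    roi_ids=[f"roi_{i:03d}" for i in range(len(regions))],
                    roi_centroids=centroids)


def extract_traces_from_labels(stack: np.ndarray, label_image: np.ndarray) -> TraceSet:
    """Extract traces for externally curated ROIs given as a label image."""
    from skimage import measure

    stack = np.asarray(stack, dtype=float)
    labels = np.asarray(label_image)
    if labels.shape != stack.shape[1:]:
        raise ValueError("label image shape must match the frame shape")
    regions = measure.regionprops(labels)
    flat = stack.reshape(stack.shape[0], -1)
    values = np.empty((len(regions), stack.shape[0]))
    centroids = np.empty((len(regions), 2))
    ids = []
    for i, r in enumerate(regions):
        lin = np.ravel_multi_index(tuple(r.coords.T), stack.shape[1:])
        values[i] = flat[:, lin].mean(axis=1)
        centroids[i] = r.centroid
        ids.append(f"roi_{r.label:03d}")
    return TraceSet(values=values, frame_interval=1.0, roi_ids=ids,
                    roi_centroids=centroids)
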