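"""Per-cell frequency/regularity statistics, burst detection, epoch comparison.

Frequencies are reported in mHz.  A cell's frequency within an epoch is
(n_events − 1)/(t_last − t_first) — the inverse mean inter-event interval —
which avoids the edge bias of n/duration; regularity is the coefficient of
variation (CV, %) of inter-event intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .traces import EventSeries


@dataclass
class FrequencyReport:
    roi_ids: list[str]
    freq_mhz: np.ndarray            # 0 when a cell has < 2 events
    cv_pct: np.ndarray              # NaN when < 3 events (needs ≥ 2 intervals)
    population_mean_mhz: float
    regular_cells: list[str]
    regularity_cv_max: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cell_id": self.roi_ids,
                             "freq_mHz": self.freq_mhz,
                             "cv_pct": self.cv_pct})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")


@dataclass
class BurstReport:
    burst_times: np.ndarray
    rate_bpm: float
    cv_pct: float


@dataclass
class EpochComparison:
    epochs: list[tuple[float, float, str]]
    table: pd.DataFrame = field(repr=False)
    population_mean_mhz: dict[str, float] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.10g")


def _freq_cv(times: np.ndarray) -> tuple[float, float]:
    if len(times) < 2:
        return 0.0, float("nan")
    span = times[-1] - times[0]
    freq = (len(times) - 1) / span * 1000.0 if span > 0 else 0.0
    iei = np.diff(times)
    cv = float("nan")
    if len(iei) >= 2 and iei.mean() > 0:
        cv = 100.0 * iei.std(ddof=1) / iei.mean()
    return freq, cv


def frequency_and_cv(events: EventSeries, epoch: tuple[float, float] | None = None,
                     regularity_cv_max: float = 50.0) -> FrequencyReport:
    """Mean event frequency (mHz) and interval CV (%) per cell.

    ``epoch`` restricts events to [start, end).  The population mean is
    taken over cells with a defined (non-zero) frequency.  Cells with CV at
    or below ``regularity_cv_max`` are reported as regularly spiking.
    """
    freqs = np.zeros(events.n_cells)
    cvs = np.full(events.n_cells, np.nan)
    for i, t in enumerate(events.times):
        t = np.asarray(t)
        if epoch is not None:
            t = t[(t >= epoch[0]) & (t < epoch[1])]
        freqs[i], cvs[i] = _freq_cv(t)
    rhythmic = freqs > 0
    pop = float(freqs[rhythmic].mean()) if rhythmic.any() else 0.0
    regular = [events.roi_ids[i] for i in range(events.n_cells)
               if np.isfinite(cvs[i]) and cvs[i] <= regularity_cv_max]
    return FrequencyReport(roi_ids=list(events.roi_ids), freq_mhz=freqs,
                           cv_pct=cvs, population_mean_mhz=pop,
                           regular_cells=regular,
                           regularity_cv_max=regularity_cv_max)


def detect_bursts(processed: np.ndarray, frame_interval: float,
                  threshold: float = 0.5, min_burst_gap: float = 2.0) -> BurstReport:
    """Group threshold crossings of a rectified–smoothed trace into bursts.

    The threshold is ``threshold`` × the signal maximum.  Supra-threshold
    runs separated by less than ``min_burst_gap`` seconds are merged; each
    burst is timed at its peak.  Rate is bursts per minute; CV is over
    inter-burst intervals.
    """
    x = np.asarray(processed, dtype=float)
    duration = x.size * frame_interval
    if x.size == 0 or np.nanmax(x) <= 0:
        return BurstReport(np.array([]), 0.0, float("nan"))
    thr = threshold * np.nanmax(x)
    above = x >= thr
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(x.size)
    runs = list(zip(starts, ends))
    gap = min_burst_gap / frame_interval
    merged = []
    for s, e in runs:
        if merged and s - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    peaks = np.array([s + int(np.argmax(x[s:e])) for s, e in merged])
    times = peaks * frame_interval
    rate = len(times) / duration * 60.0
    cv = float("nan")
    if len(times) >= 3:
        iei = np.diff(times)
        if iei.mean() > 0:
            cv = 100.0 * iei.std(ddof=1) / iei.mean()
    return BurstReport(times, rate, cv)


def compare_epochs(events: EventSeries,
                   epochs: list[tuple[float, float, str]]) -> EpochComparison:
    """Paired per-cell frequency changes between labelled epochs.

    Epochs must be non-overlapping with positive duration.  The table holds
    one row per cell with the frequency in each epoch and the delta of every
    epoch relative to the first; population means are per-epoch means over
    rhythmic cells.  Descriptive only — no hypothesis testing.
    """
    if len(epochs) < 2:
        raise ValueError("need at least 2 epochs")
    for start, end, _ in epochs:
        if not end > start:
            raise ValueError("epoch with non-positive duration")
    spans = sorted((s, e) for s, e, _ in epochs)
    for (s1, e1), (s2, _) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError("epochs overlap")
    reports = {label: frequency_and_cv(events, epoch=(s, e))
               for s, e, label in epochs}
    table = pd.DataFrame({"cell_id": events.roi_ids})
    ref = epochs[0][2]
    for _, _, label in epochs:
        table[f"freq_mHz_{label}"] = reports[label].freq_mhz
    for _, _, label in epochs[1:]:
        table[f"delta_mHz_{label}_vs_{ref}"] = (reports[label].freq_mhz
                                               - reports[ref].freq_mhz)
    pop = {label: reports[label].population_mean_mhz for _, _, label in epochs}
    return EpochComparison(epochs=epochs, table=table, population_mean_mhz=pop)
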