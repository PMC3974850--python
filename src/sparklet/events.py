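"""Sparklet classification from per-ROI F/F0 traces.

An event is a maximal run of consecutive frames at or above
``baseline_mean + sd_multiplier * baseline_sd``.  A run is kept as a sparklet
iff it lasts at least ``min_duration_frames`` frames AND its peak excess over
the baseline mean reaches ``min_peak`` ΔF/F0 (defaults: 3 frames, 2.5 SD,
0.05 ΔF/F0).  Runs truncated by the recording edge are kept if they meet the
criteria within the observed span.

Events that occur simultaneously (or near simultaneously, onset difference
within ``simultaneity_window`` frames) in separate ROIs are excluded: a signal
detected in more than one ROI is too large to be a sparklet (whole-cell
transient or wave).  Exclusion is transitive across the co-occurrence graph,
so every member of a chain of overlapping multi-ROI events is flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .detect import Trace
from .movie import AcquisitionParams

__all__ = [
    "SparkletCriteria",
    "SparkletEvent",
    "DurationFit",
    "detect_events",
    "exclude_simultaneous",
    "fit_duration_distribution",
    "events_to_frame",
    "save_event_csv",
    "load_event_csv",
]


@dataclass(frozen=True)
class SparkletCriteria:
    """The three sparklet criteria plus the simultaneity tolerance."""

    min_duration_frames: int = 3
    sd_multiplier: float = 2.5
    min_peak: float = 0.05
    simultaneity_window: int = 2

    def __post_init__(self) -> None:
        if self.min_duration_frames < 1:
            raise ValueError("min_duration_frames must be >= 1")
        if self.sd_multiplier <= 0 or self.min_peak <= 0:
            raise ValueError("sd_multiplier and min_peak must be positive")
        if self.simultaneity_window < 0:
            raise ValueError("simultaneity_window must be >= 0")


@dataclass
class SparkletEvent:
    """One classified transient.

    ``onset_frame``/``offset_frame`` are inclusive 0-based frame indices;
    ``peak_amplitude`` is the maximal excess over the trace baseline mean in
    ΔF/F0; ``peak_area`` integrates that excess over the event span in
    ΔF/F0 * s.
    """

    roi_id: int
    cell_id: int
    onset_frame: int
    offset_frame: int
    duration_s: float
    peak_amplitude: float
    peak_area: float
    excluded: bool = False
    exclusion_reason: str = "none"


def detect_events(
    trace: Trace,
    crit: SparkletCriteria | None = None,
    acq: AcquisitionParams | None = None,
    cell_id: int = 0,
) -> list[SparkletEvent]:
    """Classify the supra-threshold runs of one trace as sparklet events."""
    crit = crit or SparkletCriteria()
    acq = acq or AcquisitionParams()
    v = np.asarray(trace.values, dtype=float)
    thr = trace.baseline_mean + crit.sd_multiplier * trace.baseline_sd
    above = v >= thr
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    stops = list(np.nonzero(edges == -1)[0])
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(len(v) - 1)
    events = []
    for on, off in zip(starts, stops):
        n = off - on + 1
        excess = v[on:off + 1] - trace.baseline_mean
        peak = float(excess.max())
        if n < crit.min_duration_frames or peak < crit.min_peak:
            continue
        events.append(
            SparkletEvent(
                roi_id=trace.roi_id,
                cell_id=cell_id,
                onset_frame=int(on),
                offset_frame=int(off),
                duration_s=n / acq.frame_rate,
                peak_amplitude=peak,
                peak_area=float(excess.sum() / acq.frame_rate),
            )
        )
    return events


def exclude_simultaneous(
    events: list[SparkletEvent], crit: SparkletCriteria | None = None
) -> list[SparkletEvent]:
    """Flag multi-ROI simultaneous events; returns the same list, flags set.

    Two events in distinct ROIs co-occur when their frame spans overlap or
    their onsets differ by at most ``simultaneity_window`` frames.  Flagging
    is transitive: connected components of the co-occurrence graph are
    excluded wholesale, so if A causes B's exclusion, A is excluded too.
    """
    crit = crit or SparkletCriteria()
    n = len(events)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    conflict = [False] * n
    for i in range(n):
        for j in range(i + 1, n):
            a, b = events[i], events[j]
            if a.roi_id == b.roi_id:
                continue
            overlap = a.onset_frame <= b.offset_frame and b.onset_frame <= a.offset_frame
            near = abs(a.onset_frame - b.onset_frame) <= crit.simultaneity_window
            if overlap or near:
                union(i, j)
                conflict[i] = conflict[j] = True
    roots = {find(i) for i in range(n) if conflict[i]}
    for i in range(n):
        if find(i) in roots:
            events[i].excluded = True
            events[i].exclusion_reason = "simultaneous"
    return events


@dataclass(frozen=True)
class DurationFit:
    """Truncated-exponential fit of event durations."""

    mean_s: float
    truncation_s: float
    n: int
    ks_statistic: float
    ks_p_value: float
    degenerate: bool = False


def fit_duration_distribution(
    durations, truncation_s: float = 0.0
) -> DurationFit:
    """Maximum-likelihood exponential mean for left-truncated durations.

    For an exponential law observed only above ``truncation_s``, the MLE of
    the scale is the sample mean minus the truncation point (memorylessness).
    Goodness of fit is a one-sample Kolmogorov-Smirnov statistic against the
    fitted truncated exponential; its p-value is approximate because the
    scale was estimated from the same data.  Fits are most meaningful from
    ~10 durations upward.  All-equal samples yield a valid MLE but a
    ``degenerate`` goodness flag.
    """
    d = np.asarray(list(durations), dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 durations")
    if np.any(d < truncation_s):
        raise ValueError("durations below the truncation point")
    mean = float(d.mean() - truncation_s)
    if np.ptp(d) == 0.0:
        # zero-variance sample: the MLE is still the shifted sample mean but
        # no distributional fit is possible
        return DurationFit(mean_s=mean, truncation_s=truncation_s,
                           n=int(d.size), ks_statistic=float("nan"),
                           ks_p_value=float("nan"), degenerate=True)
    if mean <= 0:
        raise ValueError("non-positive fitted mean (degenerate fit)")

    def cdf(x):
        return 1.0 - np.exp(-np.clip(x - truncation_s, 0, None) / mean)

    ks = sps.kstest(d, cdf)
    return DurationFit(mean_s=mean, truncation_s=truncation_s, n=int(d.size),
                       ks_statistic=float(ks.statistic),
                       ks_p_value=float(ks.pvalue))


# ---------------------------------------------------------------------------
# CSV interface

EVENT_COLUMNS = [
    "roi_id", "cell_id", "onset_frame", "offset_frame", "duration_s",
    "peak_amplitude_ff0", "peak_area_ff0s", "excluded", "exclusion_reason",
]


def events_to_frame(events: list[SparkletEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "roi_id": e.roi_id,
                "cell_id": e.cell_id,
                "onset_frame": e.onset_frame,
                "offset_frame": e.offset_frame,
                "duration_s": e.duration_s,
                "peak_amplitude_ff0": e.peak_amplitude,
                "peak_area_ff0s": e.peak_area,
                "excluded": e.excluded,
                "exclusion_reason": e.exclusion_reason,
            }
            for e in events
        ],
        columns=EVENT_COLUMNS,
    )


def save_event_csv(events: list[SparkletEvent], path: str | Path,
                   header_lines: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        events_to_frame(events).to_csv(fh, index=False)


def load_event_csv(path: str | Path) -> list[SparkletEvent]:
    df = pd.read_csv(path, comment="#")
    return [
        SparkletEvent(
            roi_id=int(r.roi_id), cell_id=int(r.cell_id),
            onset_frame=int(r.onset_frame), offset_frame=int(r.offset_frame),
            duration_s=float(r.duration_s),
            peak_amplitude=float(r.peak_amplitude_ff0),
            peak_area=float(r.peak_area_ff0s), excluded=bool(r.excluded),
            exclusion_reason=str(r.exclusion_reason),
        )
        for r in df.itertuples()
    ]
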