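"""High-level modelling interface: ``SparkletAnalysis`` and ``SparkletResults``.

Wraps the pipeline stages in the fit/results idiom: the analysis object holds
the data (movie + cell mask) and the settings; :meth:`SparkletAnalysis.fit`
runs ROI detection, trace extraction, sparklet classification, simultaneity
exclusion and per-cell quantification, and returns a results object carrying
the ROI/event/cell tables, per-cell frequency estimates with Poisson standard
errors, and a text ``summary()``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .detect import DetectionParams, Roi, Trace, detect_rois, extract_trace, \
    rois_to_frame
from .events import SparkletCriteria, SparkletEvent, events_to_frame
from .movie import AcquisitionParams, CellMask, Movie
from .quantify import CellRecord, records_to_frame, summarize_cells

__all__ = ["SparkletAnalysis", "SparkletResults"]


class SparkletAnalysis:
    """Sparklet detection model for one recording.

    Parameters
    ----------
    movie, mask
        The fluorescence stack and its cell label image (same pixel grid).
    detection, criteria
        Detector constants and sparklet classification criteria.
    condition
        Label attached to the per-cell records (e.g. a drug name).
    """

    def __init__(
        self,
        movie: Movie,
        mask: CellMask,
        detection: DetectionParams | None = None,
        criteria: SparkletCriteria | None = None,
        condition: str = "control",
    ) -> None:
        if mask.labels.shape != movie.frame_shape:
            raise ValueError("movie and mask frame shapes differ")
        self.movie = movie
        self.mask = mask
        self.detection = detection or DetectionParams()
        self.criteria = criteria or SparkletCriteria()
        self.condition = condition

    @classmethod
    def from_files(
        cls,
        movie_path: str | Path,
        mask_path: str | Path,
        frame_rate: float = 150.0,
        pixel_size: float = 0.4,
        **kwargs,
    ) -> "SparkletAnalysis":
        movie = Movie.load(movie_path, frame_rate=frame_rate, pixel_size=pixel_size)
        mask = CellMask.load(mask_path, pixel_size=pixel_size)
        return cls(movie, mask, **kwargs)

    def fit(self) -> "SparkletResults":
        """Run the full detection pipeline and return the results."""
        from .events import detect_events, exclude_simultaneous

        rois = detect_rois(self.movie, self.mask, self.detection)
        traces: list[Trace] = []
        events: list[SparkletEvent] = []
        for roi in rois:
            tr = extract_trace(self.movie, roi)
            traces.append(tr)
            events.extend(
                detect_events(tr, self.criteria, self.movie.acq, cell_id=roi.cell_id)
            )
        exclude_simultaneous(events, self.criteria)
        # pipeline invariant: every kept event satisfies all three criteria
        min_dur = self.criteria.min_duration_frames / self.movie.acq.frame_rate
        for e in events:
            if not e.excluded:
                assert e.peak_amplitude >= self.criteria.min_peak
                assert e.duration_s >= min_dur - 1e-12
        records = summarize_cells(events, self.mask, self.movie.acq, self.condition)
        return SparkletResults(model=self, rois=rois, traces=traces,
                               events=events, records=records)


@dataclass
class SparkletResults:
    """Fitted results: detected ROIs, classified events, per-cell summaries."""

    model: SparkletAnalysis
    rois: list[Roi]
    traces: list[Trace]
    events: list[SparkletEvent]
    records: list[CellRecord]

    @property
    def roi_table(self) -> pd.DataFrame:
        return rois_to_frame(self.rois)

    @property
    def event_table(self) -> pd.DataFrame:
        return events_to_frame(self.events)

    @property
    def cell_table(self) -> pd.DataFrame:
        """Per-cell summary with a Poisson SE on each frequency estimate."""
        df = records_to_frame(self.records)
        with np.errstate(divide="ignore", invalid="ignore"):
            df["frequency_se_hz_per_mm2"] = np.sqrt(df.n_events) / (
                df.recording_duration_s * df.membrane_area_mm2
            )
        return df

    @property
    def n_events(self) -> int:
        return sum(1 for e in self.events if not e.excluded)

    @property
    def n_excluded(self) -> int:
        return sum(1 for e in self.events if e.excluded)

    def summary(self) -> str:
        """Human-readable run summary."""
        acq = self.model.movie.acq
        df = self.cell_table
        amps = [e.peak_amplitude for e in self.events if not e.excluded]
        lines = [
            "Sparklet analysis summary",
            "=" * 60,
            f"condition:            {self.model.condition}",
            f"recording:            {acq.n_frames} frames @ {acq.frame_rate:g} Hz "
            f"({acq.duration_s:.1f} s), {acq.pixel_size:g} um/px",
            f"cells in mask:        {len(self.records)}",
            f"ROIs detected:        {len(self.rois)} "
            f"(diameter {self.model.detection.roi_diameter}px)",
            f"sparklets kept:       {self.n_events}",
            f"excluded (multi-ROI): {self.n_excluded}",
        ]
        if amps:
            lines.append(
                f"amplitude [dF/F0]:    mean {np.mean(amps):.3f}, "
                f"range [{min(amps):.3f}, {max(amps):.3f}]"
            )
        lines.append("-" * 60)
        lines.append(f"{'cell':>4} {'events':>7} {'area mm2':>10} "
                     f"{'freq Hz/mm2':>12} {'+/- SE':>8}")
        for r in df.itertuples():
            lines.append(
                f"{r.cell_id:>4} {r.n_events:>7} {r.membrane_area_mm2:>10.5f} "
                f"{r.frequency_hz_per_mm2:>12.3f} {r.frequency_se_hz_per_mm2:>8.3f}"
            )
        return "\n".join(lines)

    def plot_overlay(self, ax=None):
        """Static overlay: time-max projection, cell outlines, ROI circles."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib.patches import Circle

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 6))
        proj = self.model.movie.data.max(axis=0)
        ax.imshow(proj, cmap="gray", interpolation="nearest")
        ax.contour(self.model.mask.labels > 0, levels=[0.5], colors="cyan",
                   linewidths=0.8)
        for roi in self.rois:
            ax.add_patch(Circle((roi.center[1], roi.center[0]),
                                roi.diameter / 2, fill=False, color="yellow",
                                linewidth=1.0))
        ax.set_title(f"{self.model.condition}: {len(self.rois)} ROIs, "
                     f"{self.n_events} sparklets")
        ax.set_axis_off()
        return ax.figure

    def save(self, outdir: str | Path, header_lines: list[str] | None = None) -> None:
        """Write ROI, trace, event and cell-summary CSVs plus an overlay PNG."""
        from .detect import save_roi_csv, save_trace_csv
        from .events import save_event_csv
        from .quantify import save_cell_csv

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        save_roi_csv(self.rois, outdir / "rois.csv", header_lines)
        save_trace_csv(self.traces, outdir / "traces.csv", header_lines)
        save_event_csv(self.events, outdir / "events.csv", header_lines)
        save_cell_csv(self.records, outdir / "cells.csv", header_lines)
        fig = self.plot_overlay()
        fig.savefig(outdir / "overlay.png", dpi=120)
        import matplotlib.pyplot as plt

        plt.close(fig)
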