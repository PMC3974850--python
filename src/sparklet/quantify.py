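"""Per-cell frequency and amplitude summaries corrected for membrane area.

Sparklet counts are normalized by recording duration and by each cell's
membrane footprint visible in the TIRF zone (the full masked area), because
that footprint varies substantially from cell to cell:

    frequency [Hz/mm^2] = n_events / duration_s / membrane_area_mm2

Excluded (multi-ROI simultaneous) events are never counted.  Cells present in
the mask with zero events still appear, with frequency 0 and an undefined
(NaN) mean amplitude; the amplitude table drops them, mirroring the removal
of zero-sparklet cells from amplitude comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .events import SparkletEvent
from .movie import AcquisitionParams, CellMask

__all__ = ["CellRecord", "summarize_cells", "amplitude_table",
           "records_to_frame", "save_cell_csv", "load_cell_csv"]


@dataclass(frozen=True)
class CellRecord:
    """Per-cell, per-condition event summary."""

    cell_id: int
    condition: str
    n_events: int
    membrane_area_mm2: float
    recording_duration_s: float
    frequency_hz_per_mm2: float
    mean_amplitude_ff0: float  # NaN when n_events == 0


def summarize_cells(
    events: list[SparkletEvent],
    mask: CellMask,
    acq: AcquisitionParams | None = None,
    condition: str = "control",
) -> list[CellRecord]:
    """Aggregate non-excluded events into per-cell records.

    Every cell label in the mask yields a record; an event referencing a cell
    absent from the mask raises a consistency error.
    """
    acq = acq or AcquisitionParams()
    areas = mask.areas_mm2()
    duration = acq.duration_s
    counts: dict[int, int] = {k: 0 for k in areas}
    amps: dict[int, list[float]] = {k: [] for k in areas}
    for e in events:
        if e.cell_id not in areas:
            raise ValueError(f"event references cell {e.cell_id} absent from mask")
        if e.excluded:
            continue
        counts[e.cell_id] += 1
        amps[e.cell_id].append(e.peak_amplitude)
    records = []
    for cell in sorted(areas):
        n = counts[cell]
        area = areas[cell]
        records.append(
            CellRecord(
                cell_id=cell,
                condition=condition,
                n_events=n,
                membrane_area_mm2=area,
                recording_duration_s=duration,
                frequency_hz_per_mm2=n / duration / area,
                mean_amplitude_ff0=float(np.mean(amps[cell])) if n else math.nan,
            )
        )
    return records


def amplitude_table(
    records: list[CellRecord], events: list[SparkletEvent] | None = None
) -> pd.DataFrame:
    """Per-cell mean amplitudes with zero-event cells removed.

    Cells with no sparklets (and therefore an amplitude of zero) are dropped
    rather than entering the comparison as zeros.  When ``events`` is given,
    the means are recomputed from the non-excluded events as a consistency
    cross-check.
    """
    rows = [
        {"cell_id": r.cell_id, "condition": r.condition,
         "mean_amplitude_ff0": r.mean_amplitude_ff0}
        for r in records
        if r.n_events >= 1
    ]
    df = pd.DataFrame(rows, columns=["cell_id", "condition", "mean_amplitude_ff0"])
    if events is not None and len(df):
        by_cell = {}
        for e in events:
            if not e.excluded:
                by_cell.setdefault(e.cell_id, []).append(e.peak_amplitude)
        recomputed = df.cell_id.map(lambda c: float(np.mean(by_cell.get(c, [np.nan]))))
        if not np.allclose(recomputed, df.mean_amplitude_ff0, equal_nan=True):
            raise ValueError("records inconsistent with event table")
    return df


# ---------------------------------------------------------------------------
# CSV interface

CELL_COLUMNS = [
    "cell_id", "condition", "n_events", "membrane_area_mm2",
    "recording_duration_s", "frequency_hz_per_mm2", "mean_amplitude_ff0",
]


def records_to_frame(records: list[CellRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_id": r.cell_id,
                "condition": r.condition,
                "n_events": r.n_events,
                "membrane_area_mm2": r.membrane_area_mm2,
                "recording_duration_s": r.recording_duration_s,
                "frequency_hz_per_mm2": r.frequency_hz_per_mm2,
                "mean_amplitude_ff0": r.mean_amplitude_ff0,
            }
            for r in records
        ],
        columns=CELL_COLUMNS,
    )


def save_cell_csv(records: list[CellRecord], path: str | Path,
                  header_lines: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        records_to_frame(records).to_csv(fh, index=False)


def load_cell_csv(path: str | Path) -> list[CellRecord]:
    df = pd.read_csv(path, comment="#")
    return [
        CellRecord(
            cell_id=int(r.cell_id), condition=str(r.condition),
            n_events=int(r.n_events),
            membrane_area_mm2=float(r.membrane_area_mm2),
            recording_duration_s=float(r.recording_duration_s),
            frequency_hz_per_mm2=float(r.frequency_hz_per_mm2),
            mean_amplitude_ff0=float(r.mean_amplitude_ff0),
        )
        for r in df.itertuples()
    ]
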