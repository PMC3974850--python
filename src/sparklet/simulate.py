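"""Synthetic TIRF movie generator with ground truth.

Emulates the statistical structure the sparklet analysis assumes: fixed active
sites firing repetitively with exponentially distributed durations (left
truncated at the detectable floor of ``duration_floor_frames`` frames),
amplitudes inside a configured ΔF/F0 band, a spatial Gaussian footprint sized
so the ~2σ disc covers 50-60 µm² of membrane, occasional whole-cell "global"
transients that span every site of a cell, additive Gaussian noise in ΔF/F0
units and an optional slow mono-exponential photobleach.

The pixel model is::

    F(t, x) = B(x) * ( bleach(t) * (1 + sum_events kernel(t, x)) + eps(t, x) )

with ``B`` the per-pixel resting intensity, ``eps ~ N(0, noise_sd)`` i.i.d.
Each non-global event contributes ``amp * exp(-r^2 / 2 sigma^2)`` spatially
(clipped to its own cell's footprint) and, temporally, an instantaneous rise
followed by a single-exponential decay whose supra-half-maximum span equals
the drawn duration.  Global events are spatially uniform over one whole cell.

Also provides :func:`generate_paired_rates`, drawing per-cell paired
(control, treatment) frequencies from gamma marginals coupled through a
Gaussian copula so the population Spearman rank correlation equals the
requested value exactly (0 for the independent model).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .movie import AcquisitionParams, CellMask, Movie

__all__ = [
    "SynthConfig",
    "GroundTruthEvent",
    "PairedRateScenario",
    "generate_movie",
    "generate_paired_rates",
    "truth_to_frame",
    "save_truth_csv",
    "load_truth_csv",
]

TRUTH_COLUMNS = [
    "cell_id",
    "site_row",
    "site_col",
    "onset_frame",
    "duration_s",
    "amplitude_ff0",
    "is_global",
]

#: pixel contributions below this ΔF/F0 level are treated as zero
_KERNEL_FLOOR = 1e-5


@dataclass(frozen=True)
class SynthConfig:
    """Generative settings for one synthetic recording.

    Rates are per second; amplitudes and noise are in ΔF/F0 units; spatial
    scales in micrometres.  ``duration_mean`` is the scale of the exponential
    duration law *before* left truncation at the detectable floor.
    """

    n_cells: int = 4
    sites_per_cell: int = 5
    site_rate: float = 0.1
    amplitude_band: tuple[float, float] = (0.05, 0.27)
    duration_mean: float = 0.10
    duration_floor_frames: int = 3
    footprint_sigma: float = 2.1
    noise_sd: float = 0.01
    bleach_rate: float = 0.0
    global_event_rate: float = 0.0375
    global_amplitude: float = 0.3
    global_duration_mean: float = 0.3
    baseline_cell: float = 1000.0
    baseline_background: float = 100.0
    poisson_noise: bool = False
    cell_margin_px: int = 4
    site_margin_px: int = 6
    min_site_separation_px: float = 16.0
    rng_seed: int = 0
    structure_seed: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.amplitude_band
        if not lo < hi:
            raise ValueError("amplitude_band must satisfy low < high")
        for name in ("site_rate", "global_event_rate", "bleach_rate", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.duration_mean <= 0 or self.global_duration_mean <= 0:
            raise ValueError("duration means must be positive")
        if self.n_cells < 1 or self.sites_per_cell < 0:
            raise ValueError("need at least one cell and non-negative site count")


@dataclass(frozen=True)
class GroundTruthEvent:
    """One injected transient, for validating the detection pipeline."""

    cell_id: int
    site_row: int
    site_col: int
    onset_frame: int
    duration_s: float
    amplitude_ff0: float
    is_global: bool = False


class SizingError(ValueError):
    """Frame too small to hold the requested cells/sites."""


# ---------------------------------------------------------------------------
# geometry


def _cell_layout(cfg: SynthConfig, acq: AcquisitionParams) -> np.ndarray:
    """Tile ``n_cells`` rectangular cells on a near-square grid."""
    rows, cols = acq.frame_shape
    ncol = int(math.ceil(math.sqrt(cfg.n_cells)))
    nrow = int(math.ceil(cfg.n_cells / ncol))
    th, tw = rows // nrow, cols // ncol
    m = cfg.cell_margin_px
    if th - 2 * m < 4 or tw - 2 * m < 4:
        raise SizingError(
            f"frame {acq.frame_shape} too small for {cfg.n_cells} cells "
            f"with margin {m}px"
        )
    labels = np.zeros((rows, cols), dtype=np.int32)
    k = 0
    for i in range(nrow):
        for j in range(ncol):
            if k >= cfg.n_cells:
                break
            k += 1
            labels[i * th + m:(i + 1) * th - m, j * tw + m:(j + 1) * tw - m] = k
    return labels


def _place_sites(
    labels: np.ndarray, cfg: SynthConfig, rng: np.random.Generator
) -> dict[int, np.ndarray]:
    """Uniform random sites per cell, pairwise ``min_site_separation_px`` apart."""
    from scipy.ndimage import binary_erosion

    sites: dict[int, np.ndarray] = {}
    m = cfg.site_margin_px
    struct = np.ones((2 * m + 1, 2 * m + 1), bool)
    for cell in range(1, int(labels.max()) + 1):
        interior = binary_erosion(labels == cell, structure=struct)
        cand = np.argwhere(interior)
        if len(cand) < cfg.sites_per_cell:
            raise SizingError(f"cell {cell} interior too small for site placement")
        chosen: list[np.ndarray] = []
        for _ in range(2000):
            if len(chosen) == cfg.sites_per_cell:
                break
            p = cand[rng.integers(len(cand))]
            if all(np.hypot(*(p - q)) >= cfg.min_site_separation_px for q in chosen):
                chosen.append(p)
        if len(chosen) < cfg.sites_per_cell:
            raise SizingError(
                f"could not place {cfg.sites_per_cell} sites with "
                f"{cfg.min_site_separation_px}px separation in cell {cell}"
            )
        sites[cell] = np.array(chosen, dtype=int)
    return sites


# ---------------------------------------------------------------------------
# event drawing


def _draw_durations(
    n: int, mean_s: float, floor_s: float, rng: np.random.Generator
) -> np.ndarray:
    """Left-truncated exponential: floor + Exp(mean) by memorylessness."""
    return floor_s + rng.exponential(mean_s, size=n)


def draw_events(
    cfg: SynthConfig,
    acq: AcquisitionParams,
    sites: dict[int, np.ndarray],
    rng: np.random.Generator,
) -> list[GroundTruthEvent]:
    """Draw the full truth table (site sparklets then global transients)."""
    floor_s = cfg.duration_floor_frames / acq.frame_rate
    lo, hi = cfg.amplitude_band
    events: list[GroundTruthEvent] = []
    for cell in sorted(sites):
        for row, col in sites[cell]:
            n = rng.poisson(cfg.site_rate * acq.duration_s)
            onsets = rng.integers(0, acq.n_frames, size=n)
            durs = _draw_durations(n, cfg.duration_mean, floor_s, rng)
            amps = rng.uniform(lo, hi, size=n)
            events.extend(
                GroundTruthEvent(int(cell), int(row), int(col), int(t0),
                                 float(d), float(a))
                for t0, d, a in zip(onsets, durs, amps)
            )
    n_glob = rng.poisson(cfg.global_event_rate * acq.duration_s)
    cells = sorted(sites) or [1]
    for _ in range(n_glob):
        cell = int(cells[rng.integers(len(cells))])
        t0 = int(rng.integers(0, acq.n_frames))
        d = float(_draw_durations(1, cfg.global_duration_mean, floor_s, rng)[0])
        events.append(GroundTruthEvent(cell, -1, -1, t0, d, cfg.global_amplitude,
                                       is_global=True))
    events.sort(key=lambda e: (e.onset_frame, e.cell_id, e.site_row, e.site_col))
    return events


# ---------------------------------------------------------------------------
# rendering


def _event_envelope(ev: GroundTruthEvent, acq: AcquisitionParams) -> tuple[int, np.ndarray]:
    """Frames and ΔF/F0 temporal envelope of one event (instant rise, exp decay)."""
    tau_frames = ev.duration_s / math.log(2.0) * acq.frame_rate
    # render until amp * exp(-dt/tau) falls below the kernel floor
    n = int(math.ceil(tau_frames * math.log(max(ev.amplitude_ff0, _KERNEL_FLOOR * 2)
                                            / _KERNEL_FLOOR))) + 1
    t1 = min(ev.onset_frame + n, acq.n_frames)
    dt = np.arange(ev.onset_frame, t1) - ev.onset_frame
    return t1, ev.amplitude_ff0 * np.exp(-dt / tau_frames)


def generate_movie(
    cfg: SynthConfig,
    acq: AcquisitionParams | None = None,
    events: list[GroundTruthEvent] | None = None,
) -> tuple[Movie, CellMask, list[GroundTruthEvent]]:
    """Render a ground-truthed synthetic recording.

    Parameters
    ----------
    cfg, acq
        Generative settings and acquisition geometry.
    events
        Optional explicit truth table; when given, the random event draw is
        skipped and exactly these events are injected (sites need not coincide
        with the randomly placed ones).  Used for oracle tests.

    Returns
    -------
    (Movie, CellMask, truth)
        Float32 movie, the label mask, and the truth table listing every
        injected event.
    """
    acq = acq or AcquisitionParams()
    rng_struct = np.random.default_rng(
        cfg.structure_seed if cfg.structure_seed is not None else cfg.rng_seed
    )
    labels = _cell_layout(cfg, acq)
    sites = _place_sites(labels, cfg, rng_struct)
    rng = np.random.default_rng(cfg.rng_seed)
    if events is None:
        events = draw_events(cfg, acq, sites, rng)

    rows, cols = acq.frame_shape
    sigma_px = cfg.footprint_sigma / acq.pixel_size
    w = int(math.ceil(5 * sigma_px))

    baseline = np.where(labels > 0, cfg.baseline_cell,
                        cfg.baseline_background).astype(np.float32)

    # per-event spatial patches (clipped to the owning cell's footprint)
    patches: list[tuple[slice, slice, np.ndarray]] = []
    cell_boxes: dict[int, tuple[slice, slice, np.ndarray]] = {}
    for ev in events:
        if ev.is_global:
            if ev.cell_id not in cell_boxes:
                rr, cc = np.where(labels == ev.cell_id)
                sl = (slice(rr.min(), rr.max() + 1), slice(cc.min(), cc.max() + 1))
                cell_boxes[ev.cell_id] = (
                    sl[0], sl[1],
                    (labels[sl] == ev.cell_id).astype(np.float32),
                )
            patches.append(cell_boxes[ev.cell_id])
        else:
            r0, r1 = max(ev.site_row - w, 0), min(ev.site_row + w + 1, rows)
            c0, c1 = max(ev.site_col - w, 0), min(ev.site_col + w + 1, cols)
            yy, xx = np.mgrid[r0:r1, c0:c1]
            g = np.exp(-((yy - ev.site_row) ** 2 + (xx - ev.site_col) ** 2)
                       / (2 * sigma_px**2)).astype(np.float32)
            g[labels[r0:r1, c0:c1] != ev.cell_id] = 0.0  # footprint containment
            patches.append((slice(r0, r1), slice(c0, c1), g))

    envelopes = [_event_envelope(ev, acq) for ev in events]

    data = np.empty((acq.n_frames, rows, cols), dtype=np.float32)
    chunk = 256
    t_all = np.arange(acq.n_frames, dtype=np.float32)
    bleach_all = np.exp(-cfg.bleach_rate * t_all / acq.frame_rate)
    for a in range(0, acq.n_frames, chunk):
        b = min(a + chunk, acq.n_frames)
        signal = np.zeros((b - a, rows, cols), dtype=np.float32)
        for ev, (t1, env), (sr, sc, g) in zip(events, envelopes, patches):
            lo, hi2 = max(ev.onset_frame, a), min(t1, b)
            if lo >= hi2:
                continue
            seg = env[lo - ev.onset_frame:hi2 - ev.onset_frame]
            signal[lo - a:hi2 - a, sr, sc] += seg[:, None, None] * g[None]
        signal += 1.0
        signal *= bleach_all[a:b, None, None]
        if cfg.noise_sd > 0:
            signal += rng.standard_normal(signal.shape, dtype=np.float32) * cfg.noise_sd
        signal *= baseline[None]
        if cfg.poisson_noise:
            signal = rng.poisson(np.clip(signal, 0, None)).astype(np.float32)
        data[a:b] = signal

    movie = Movie(data=data, acq=acq)
    mask = CellMask(labels=labels, pixel_size=acq.pixel_size)
    return movie, mask, events


def site_table(cfg: SynthConfig, acq: AcquisitionParams | None = None) -> pd.DataFrame:
    """The deterministic site layout for a config (cell_id, site_row, site_col)."""
    acq = acq or AcquisitionParams()
    rng_struct = np.random.default_rng(
        cfg.structure_seed if cfg.structure_seed is not None else cfg.rng_seed
    )
    labels = _cell_layout(cfg, acq)
    sites = _place_sites(labels, cfg, rng_struct)
    recs = [
        {"cell_id": cell, "site_row": int(r), "site_col": int(c)}
        for cell in sorted(sites)
        for r, c in sites[cell]
    ]
    return pd.DataFrame(recs, columns=["cell_id", "site_row", "site_col"])


# ---------------------------------------------------------------------------
# truth table I/O


def truth_to_frame(events: list[GroundTruthEvent]) -> pd.DataFrame:
    rows = [
        {
            "cell_id": e.cell_id,
            "site_row": e.site_row,
            "site_col": e.site_col,
            "onset_frame": e.onset_frame,
            "duration_s": e.duration_s,
            "amplitude_ff0": e.amplitude_ff0,
            "is_global": e.is_global,
        }
        for e in events
    ]
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def save_truth_csv(events: list[GroundTruthEvent], path: str | Path,
                   header_lines: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        truth_to_frame(events).to_csv(fh, index=False)


def load_truth_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# paired-rate scenarios


@dataclass(frozen=True)
class PairedRateScenario:
    """Per-cell paired (control, treatment) sparklet frequencies.

    ``rate_control`` / ``rate_treatment`` are the marginal mean frequencies in
    Hz/mm²; cell-to-cell heterogeneity follows a gamma law with shape
    ``dispersion_shape``.  ``dependence_model`` is ``"independent"`` (ranks of
    the two columns unrelated) or ``"proportional-with-noise"`` (Gaussian
    copula tuned so the population Spearman correlation equals
    ``generative_rank_correlation``; 1 means an exact monotone relation).
    """

    n_cells: int = 25
    rate_control: float = 0.23
    rate_treatment: float = 0.23
    dependence_model: str = "independent"
    generative_rank_correlation: float = 0.0
    dispersion_shape: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 4:
            raise ValueError("n_cells must be >= 4 for rank tests to be meaningful")
        if self.rate_control < 0 or self.rate_treatment < 0:
            raise ValueError("rates must be >= 0")
        if self.dependence_model not in ("independent", "proportional-with-noise"):
            raise ValueError(f"unknown dependence_model {self.dependence_model!r}")
        if self.dependence_model == "independent" and self.generative_rank_correlation != 0:
            raise ValueError("independent model requires generative_rank_correlation = 0")
        if not -1 <= self.generative_rank_correlation <= 1:
            raise ValueError("generative_rank_correlation must lie in [-1, 1]")


def generate_paired_rates(sc: PairedRateScenario) -> pd.DataFrame:
    """Draw one paired frequency table (cell_id, freq_control, freq_treatment).

    Uses a Gaussian copula with Pearson correlation ``2 sin(pi * rho_s / 6)``,
    which yields population Spearman correlation exactly ``rho_s`` for the
    continuous gamma marginals.
    """
    rng = np.random.default_rng(sc.rng_seed)
    rho_s = sc.generative_rank_correlation
    rho = 2.0 * math.sin(math.pi * rho_s / 6.0)
    z1 = rng.standard_normal(sc.n_cells)
    z2 = rho * z1 + math.sqrt(max(1.0 - rho**2, 0.0)) * rng.standard_normal(sc.n_cells)
    u1, u2 = sps.norm.cdf(z1), sps.norm.cdf(z2)
    k = sc.dispersion_shape
    ctrl = sps.gamma.ppf(u1, a=k, scale=sc.rate_control / k)
    trt = sps.gamma.ppf(u2, a=k, scale=sc.rate_treatment / k)
    return pd.DataFrame(
        {
            "cell_id": np.arange(1, sc.n_cells + 1),
            "freq_control": ctrl,
            "freq_treatment": trt,
        }
    )
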