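"""Network-activity quantification from calcium-imaging recordings.

The analysis follows the standard field-of-view (FOV) workflow for organoid
GCaMP recordings: a maximum-intensity projection guides the placement of a
handful of disk-shaped regions of interest (ROIs, 50 um diameter by
default), per-frame mean intensities give raw ROI traces, traces are
converted to dF/F0 against a percentile baseline, transients are detected
as thresholded local maxima, and synchronous network events are detected on
the ROI-averaged dF/F0 trace.  One FOV is summarised by three numbers:

* ``frequency_per_min`` — total detected peaks across all ROIs per minute,
* ``amplitude_mean_dff`` — mean dF/F0 of all detected peaks,
* ``sync_rate_per_min`` — detected synchronous spikes per minute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from . import groupstats

__all__ = [
    "RoiTraceSet",
    "DffTraceSet",
    "PeakSet",
    "SyncEventSet",
    "FovSummary",
    "PeakParams",
    "frame_interval",
    "compute_mip",
    "select_rois",
    "extract_roi_traces",
    "compute_dff",
    "detect_peaks",
    "detect_synchrony",
    "summarize_fov",
    "analyze_fov",
    "stimulation_analysis",
]

CONDITIONS = ("baseline", "glycine_30", "glycine_60", "apv", "picrotoxin", "cnqx_apv")


@dataclass
class RoiTraceSet:
    """Raw ROI fluorescence traces for one field of view.

    ``traces`` is an (n_rois, n_frames) array in arbitrary fluorescence
    units; ``frame_interval_s`` is the sampling interval in seconds.
    """

    traces: np.ndarray
    frame_interval_s: float
    fov_id: str = "fov0"
    organoid_id: str = ""
    genotype: str = ""
    condition: str = "baseline"

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.ndim != 2:
            raise ValueError("traces must be a 2-D (roi x frame) array")
        if self.traces.shape[0] < 1 or self.traces.shape[1] < 2:
            raise ValueError("need at least 1 ROI and 2 frames")
        if not np.all(np.isfinite(self.traces)):
            raise ValueError("traces contain non-finite values")
        if not (self.frame_interval_s > 0):
            raise ValueError("frame_interval_s must be positive")

    @property
    def n_rois(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]

    @property
    def duration_min(self) -> float:
        return self.n_frames * self.frame_interval_s / 60.0


@dataclass
class DffTraceSet:
    """dF/F0 traces plus the per-ROI baseline F0 they were computed from."""

    dff: np.ndarray
    f0: np.ndarray
    frame_interval_s: float
    fov_id: str = "fov0"

    @property
    def n_rois(self) -> int:
        return self.dff.shape[0]


@dataclass
class PeakSet:
    """Detected transient peaks per ROI (frame indices and dF/F0 amplitudes)."""

    frames: list[np.ndarray]
    amplitudes: list[np.ndarray]

    @property
    def total_count(self) -> int:
        return int(sum(len(f) for f in self.frames))


@dataclass
class SyncEventSet:
    """Synchronous spikes detected on the FOV-averaged dF/F0 trace."""

    frames: np.ndarray
    amplitudes: np.ndarray

    @property
    def count(self) -> int:
        return len(self.frames)


@dataclass
class FovSummary:
    """The three per-FOV network statistics plus provenance."""

    frequency_per_min: float
    amplitude_mean_dff: float
    sync_rate_per_min: float
    n_rois: int
    duration_min: float
    n_peaks: int = 0
    amplitude_defined: bool = True
    fov_id: str = "fov0"
    organoid_id: str = ""
    genotype: str = ""
    condition: str = "baseline"


@dataclass
class PeakParams:
    """Detection settings for dF/F0 transient peaks.

    ``baseline_percentile`` sets F0 (percentile of each raw ROI trace);
    the peak threshold is ``max(floor_dff, mad_k * MAD)`` per trace, and
    peaks must be at least ``min_separation`` frames apart.
    """

    baseline_percentile: float = 10.0
    floor_dff: float = 0.05
    mad_k: float = 3.0
    min_separation: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.baseline_percentile <= 50):
            raise ValueError("baseline_percentile must lie in (0, 50]")
        if self.floor_dff < 0 or self.mad_k < 0:
            raise ValueError("floor_dff and mad_k must be non-negative")
        if self.min_separation < 1:
            raise ValueError("min_separation must be >= 1")


def frame_interval(duration_s: float, n_frames: int) -> float:
    """Sampling interval in seconds per frame: recording duration / frames.

    A 300 s recording of 109 frames gives 2.75 s/frame.
    """
    if n_frames is None or int(n_frames) < 1:
        raise ValueError("n_frames must be a positive integer")
    if not (duration_s > 0):
        raise ValueError("duration_s must be positive")
    return float(duration_s) / int(n_frames)


def compute_mip(stack: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection: per-pixel maximum across frames."""
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("stack must be a non-empty (frame, y, x) array")
    return stack.max(axis=0)


def _disk_mask(radius_px: float) -> np.ndarray:
    r = int(np.floor(radius_px))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy**2 + xx**2) <= radius_px**2


def select_rois(
    stack: np.ndarray,
    n: int,
    diameter_um: float = 50.0,
    pixel_size_um: float = 1.0,
) -> tuple[list[tuple[int, int]], float, list[str]]:
    """Place ``n`` non-overlapping disk ROIs on the most active regions.

    Activity is scored per candidate centre as the temporal standard
    deviation of the disk-mean trace; disks are placed greedily from the
    highest score down, rejecting centres closer than one diameter to an
    accepted centre or with the disk extending outside the image.  Ties are
    broken by raster (row, column) order.  Returns (centres, radius_px,
    warnings); fewer than ``n`` centres are returned with a warning record
    when the field cannot hold them.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("stack must be a non-empty (frame, y, x) array")
    if n < 1:
        raise ValueError("n must be >= 1")
    radius_px = diameter_um / 2.0 / pixel_size_um
    mask = _disk_mask(radius_px)
    area = mask.sum()
    # Disk-mean trace per candidate centre, then its temporal std.
    means = np.empty_like(stack)
    for i in range(stack.shape[0]):
        means[i] = ndimage.convolve(stack[i], mask / area, mode="constant")
    score = means.std(axis=0)

    h, w = score.shape
    r = int(np.floor(radius_px))
    valid = np.zeros_like(score, dtype=bool)
    if h > 2 * r and w > 2 * r:
        valid[r : h - r, r : w - r] = True

    centers: list[tuple[int, int]] = []
    notes: list[str] = []
    masked = np.where(valid, score, -np.inf)
    min_sep2 = (2 * radius_px) ** 2
    order = np.argsort(-masked, axis=None, kind="stable")  # raster order on ties
    for flat in order:
        if len(centers) == n:
            break
        if masked.flat[flat] == -np.inf:
            break
        cy, cx = divmod(int(flat), w)
        if all((cy - y) ** 2 + (cx - x) ** 2 >= min_sep2 for y, x in centers):
            centers.append((cy, cx))
    if len(centers) < n:
        notes.append(
            f"requested {n} ROIs but only {len(centers)} non-overlapping "
            f"disks of radius {radius_px:.1f}px fit the field"
        )
        warnings.warn(notes[-1], stacklevel=2)
    return centers, radius_px, notes


def extract_roi_traces(
    stack: np.ndarray,
    centers: list[tuple[int, int]],
    radius_px: float,
    frame_interval_s: float,
    **meta: str,
) -> RoiTraceSet:
    """Per-frame mean intensity within each disk ROI."""
    stack = np.asarray(stack, dtype=float)
    h, w = stack.shape[1:]
    traces = np.empty((len(centers), stack.shape[0]))
    for i, (cy, cx) in enumerate(centers):
        r = int(np.floor(radius_px))
        if cy - r < 0 or cx - r < 0 or cy + r >= h or cx + r >= w:
            raise ValueError(f"ROI {i} at ({cy},{cx}) extends outside the image")
        mask = _disk_mask(radius_px)
        sub = stack[:, cy - r : cy + r + 1, cx - r : cx + r + 1]
        traces[i] = sub[:, mask].mean(axis=1)
    return RoiTraceSet(traces, frame_interval_s, **meta)


def compute_dff(traces: RoiTraceSet, params: PeakParams | None = None) -> DffTraceSet:
    """dF/F0 per ROI with F0 = the configured percentile of the raw trace."""
    params = params or PeakParams()
    f0 = np.percentile(traces.traces, params.baseline_percentile, axis=1)
    for i, v in enumerate(f0):
        if not (v > 0):
            raise ValueError(f"ROI {i}: baseline F0={v!r} is not positive")
    dff = (traces.traces - f0[:, None]) / f0[:, None]
    return DffTraceSet(dff, f0, traces.frame_interval_s, fov_id=traces.fov_id)


def _detect_peaks_1d(trace: np.ndarray, params: PeakParams) -> tuple[np.ndarray, np.ndarray]:
    mad = np.median(np.abs(trace - np.median(trace)))
    threshold = max(params.floor_dff, params.mad_k * mad)
    # prominence at the same level rejects noise excursions riding on slow drift
    idx, _ = signal.find_peaks(
        trace, height=threshold, prominence=threshold, distance=params.min_separation
    )
    return idx, trace[idx]


def detect_peaks(dff: DffTraceSet, params: PeakParams | None = None) -> PeakSet:
    """Thresholded local maxima per ROI.

    The per-trace threshold is ``max(floor_dff, mad_k x MAD)``; peaks closer
    than ``min_separation`` frames collapse to the larger one.
    """
    params = params or PeakParams()
    frames, amps = [], []
    for trace in dff.dff:
        idx, a = _detect_peaks_1d(trace, params)
        frames.append(idx)
        amps.append(a)
    return PeakSet(frames, amps)


def detect_synchrony(dff: DffTraceSet, params: PeakParams | None = None) -> SyncEventSet:
    """Peak detection on the unweighted mean dF/F0 trace across ROIs.

    A peak of the ROI-averaged trace is a synchronous spike: independent
    single-ROI transients are diluted by the averaging while events shared
    across ROIs survive it.
    """
    params = params or PeakParams()
    mean_trace = dff.dff.mean(axis=0)
    idx, amps = _detect_peaks_1d(mean_trace, params)
    return SyncEventSet(idx, amps)


def summarize_fov(
    peaks: PeakSet,
    sync: SyncEventSet,
    traces: RoiTraceSet,
    per_roi_mean: bool = False,
) -> FovSummary:
    """Reduce one FOV to frequency, mean amplitude, and synchronous rate.

    ``frequency_per_min`` is by default the summed peak count over all ROIs
    divided by the recording length in minutes; ``per_roi_mean=True``
    instead averages the per-ROI rates (the two readings of a per-FOV
    "total ... across all traces" frequency).
    """
    duration_min = traces.duration_min
    if not (duration_min > 0):
        raise ValueError("recording duration must be positive")
    total = peaks.total_count
    if per_roi_mean:
        freq = float(np.mean([len(f) for f in peaks.frames])) / duration_min
    else:
        freq = total / duration_min
    all_amps = np.concatenate(peaks.amplitudes) if total else np.array([])
    amplitude_defined = total > 0
    amp = float(all_amps.mean()) if amplitude_defined else 0.0
    return FovSummary(
        frequency_per_min=freq,
        amplitude_mean_dff=amp,
        sync_rate_per_min=sync.count / duration_min,
        n_rois=traces.n_rois,
        duration_min=duration_min,
        n_peaks=total,
        amplitude_defined=amplitude_defined,
        fov_id=traces.fov_id,
        organoid_id=traces.organoid_id,
        genotype=traces.genotype,
        condition=traces.condition,
    )


def analyze_fov(
    traces: RoiTraceSet,
    params: PeakParams | None = None,
    per_roi_mean: bool = False,
) -> FovSummary:
    """Convenience: dF/F0 -> peaks -> synchrony -> summary for one FOV."""
    params = params or PeakParams()
    dff = compute_dff(traces, params)
    peaks = detect_peaks(dff, params)
    sync = detect_synchrony(dff, params)
    return summarize_fov(peaks, sync, traces, per_roi_mean=per_roi_mean)


def summaries_to_frame(summaries: list[FovSummary]) -> pd.DataFrame:
    cols = [
        "fov_id",
        "organoid_id",
        "genotype",
        "condition",
        "frequency_per_min",
        "amplitude_mean_dff",
        "sync_rate_per_min",
        "n_rois",
        "duration_min",
        "n_peaks",
        "amplitude_defined",
    ]
    return pd.DataFrame([{c: getattr(s, c) for c in cols} for s in summaries])


@dataclass
class StimulationResult:
    """Descriptives plus ANOVA/Tukey over genotype x condition cells."""

    descriptives: pd.DataFrame
    anova: groupstats.ComparisonResult | None
    note: str = ""


def stimulation_analysis(
    summaries: pd.DataFrame | list[FovSummary],
    metric: str = "sync_rate_per_min",
) -> StimulationResult:
    """Compare a per-FOV metric across genotype x condition groups.

    Each (genotype, condition) cell contributes its FOV values; cells are
    compared with a one-way ANOVA followed by Tukey HSD pairwise tests.
    If any cell has fewer than 2 FOVs the ANOVA is refused and only
    descriptives (mean, SEM, n) are reported.
    """
    if not isinstance(summaries, pd.DataFrame):
        summaries = summaries_to_frame(summaries)
    grouped = summaries.groupby(["genotype", "condition"], sort=True)[metric]
    desc = grouped.agg(
        n="count", mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v))
    ).reset_index()
    if desc["genotype"].nunique() >= 1 and desc.groupby("genotype")["condition"].count().min() < 2:
        raise ValueError("need >= 2 conditions per genotype for a stimulation comparison")
    cells = {f"{g}|{c}": v.to_numpy() for (g, c), v in grouped}
    if any(len(v) < 2 for v in cells.values()):
        return StimulationResult(desc, None, note="cell with n<2: ANOVA refused, descriptives only")
    result = groupstats.anova_tukey(cells)
    return StimulationResult(desc, result)
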