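"""Synthetic calcium-indicator recordings with known event ground truth.

Each ROI carries its own Poisson train of transients; a network-wide
Poisson process adds shared ("synchronous") events that recruit a fixed
fraction of the ROIs at a common time.  Transients follow a
peak-normalised difference-of-exponentials indicator kernel
(1 - e^(-t/tau_r)) * e^(-t/tau_d); the default tau_r = 0.05 s,
tau_d = 0.6 s pair approximates fast GCaMP6 kinetics.  The continuous
signal is rendered on a fine internal time grid and averaged within each
output frame — frames integrate the signal the way a camera exposure
does, which keeps sub-frame transients visible at coarse frame intervals.

Raw fluorescence per frame:

    F(t) = baseline_f * (1 + drift + sum of transients) + Gaussian noise
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..calcium import RoiTraceSet, PeakParams, analyze_fov, FovSummary

__all__ = [
    "CalciumSimConfig",
    "CalciumTruth",
    "simulate_roi_traces",
    "simulate_fov_summaries",
    "simulate_synthetic_stack",
]


@dataclass
class CalciumSimConfig:
    """Acquisition geometry, event rates and noise of one simulated FOV.

    Defaults mirror the experimental acquisition: 300 s recordings of 109
    frames (2.75 s/frame) with 5 disk ROIs per field of view.
    """

    n_rois: int = 5
    duration_s: float = 300.0
    n_frames: int = 109
    roi_event_rate: float = 3.0  # spontaneous events/min per ROI
    sync_event_rate: float = 2.0  # network events/min
    sync_participation: float = 0.8  # fraction of ROIs recruited per network event
    amplitude_dff: float = 0.75  # dF/F0 of a unit transient at its peak
    tau_rise_s: float = 0.05
    tau_decay_s: float = 0.6
    baseline_f: float = 100.0
    noise_sd: float = 1.0  # fluorescence units per frame (~1% of baseline)
    drift_per_min: float = 0.002  # fractional baseline drift (slow bleaching)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2 or self.n_rois < 1:
            raise ValueError("need n_frames >= 2 and n_rois >= 1")
        for name in ("roi_event_rate", "sync_event_rate", "noise_sd"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")
        if not (0 <= self.sync_participation <= 1):
            raise ValueError("sync_participation must lie in [0, 1]")
        if not (self.tau_decay_s > self.tau_rise_s > 0):
            raise ValueError("need tau_decay_s > tau_rise_s > 0")
        if not (self.duration_s > 0 and self.baseline_f > 0):
            raise ValueError("duration_s and baseline_f must be positive")

    @property
    def frame_interval_s(self) -> float:
        return self.duration_s / self.n_frames


@dataclass
class CalciumTruth:
    """Injected events: per-ROI times/amplitudes and network-event times.

    Network events are included in the event list of every recruited ROI.
    """

    roi_event_times: list[np.ndarray]
    roi_event_amplitudes: list[np.ndarray]
    sync_event_times: np.ndarray

    @property
    def roi_event_counts(self) -> np.ndarray:
        return np.array([len(t) for t in self.roi_event_times])


def _kernel(config: CalciumSimConfig, dt: float) -> np.ndarray:
    """Peak-normalised indicator kernel sampled at ``dt``."""
    tr, td = config.tau_rise_s, config.tau_decay_s
    t_peak = tr * np.log(1 + td / tr)
    peak = (1 - np.exp(-t_peak / tr)) * np.exp(-t_peak / td)
    t = np.arange(0.0, 8 * td, dt)
    return (1 - np.exp(-t / tr)) * np.exp(-t / td) / peak


def simulate_roi_traces(config: CalciumSimConfig) -> tuple[RoiTraceSet, CalciumTruth]:
    """Simulate one FOV; identical config + seed gives identical output."""
    rng = np.random.default_rng(config.seed)
    dur, n_frames = config.duration_s, config.n_frames
    frame_dt = config.frame_interval_s
    # internal rendering grid: <= 25 ms, an integer number per frame
    n_sub = max(1, int(np.ceil(frame_dt / 0.025)))
    fine_dt = frame_dt / n_sub
    n_fine = n_frames * n_sub
    kernel = _kernel(config, fine_dt)

    # network events and their recruited ROI subsets
    n_sync = rng.poisson(config.sync_event_rate / 60.0 * dur)
    sync_times = np.sort(rng.uniform(0, dur, n_sync))
    n_recruit = int(np.ceil(config.sync_participation * config.n_rois))
    recruits = [rng.choice(config.n_rois, size=n_recruit, replace=False) for _ in sync_times]

    roi_times: list[np.ndarray] = []
    roi_amps: list[np.ndarray] = []
    dff = np.zeros((config.n_rois, n_fine))
    for r in range(config.n_rois):
        n_own = rng.poisson(config.roi_event_rate / 60.0 * dur)
        own = rng.uniform(0, dur, n_own)
        shared = np.array([t for t, sub in zip(sync_times, recruits) if r in sub])
        times = np.sort(np.concatenate([own, shared]))
        amps = np.full(len(times), config.amplitude_dff)
        roi_times.append(times)
        roi_amps.append(amps)
        for te, a in zip(times, amps):
            i0 = int(np.floor(te / fine_dt))
            seg = min(len(kernel), n_fine - i0)
            if seg > 0:
                dff[r, i0 : i0 + seg] += a * kernel[:seg]

    frame_dff = dff.reshape(config.n_rois, n_frames, n_sub).mean(axis=2)
    t_frame = (np.arange(n_frames) + 0.5) * frame_dt
    drift = config.drift_per_min * t_frame / 60.0
    raw = config.baseline_f * (1.0 + drift[None, :] + frame_dff)
    raw = raw + rng.normal(0.0, config.noise_sd, size=raw.shape)
    traces = RoiTraceSet(raw, frame_dt)
    return traces, CalciumTruth(roi_times, roi_amps, sync_times)


def simulate_fov_summaries(
    config: CalciumSimConfig,
    n_fovs: int,
    genotype: str = "",
    condition: str = "baseline",
    params: PeakParams | None = None,
    seed: int | None = None,
) -> list[FovSummary]:
    """Simulate and analyse ``n_fovs`` independent FOVs under one config."""
    from dataclasses import replace

    base_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(base_seed)
    out = []
    for i in range(n_fovs):
        cfg = replace(config, seed=int(rng.integers(0, 2**31 - 1)))
        traces, _ = simulate_roi_traces(cfg)
        traces.fov_id = f"{genotype or 'fov'}_{condition}_{i}"
        traces.genotype = genotype
        traces.condition = condition
        out.append(analyze_fov(traces, params))
    return out


def simulate_synthetic_stack(
    config: CalciumSimConfig,
    shape: tuple[int, int] = (96, 96),
    roi_radius_px: float = 8.0,
    seed: int | None = None,
) -> tuple[np.ndarray, list[tuple[int, int]], CalciumTruth]:
    """Render a time-lapse image stack with disk-shaped active sources.

    ROI signals from :func:`simulate_roi_traces` are painted onto disks at
    well-separated positions over a dim background; returns (stack,
    centres, truth).  Intended for exercising MIP / ROI selection / trace
    extraction on images, not for spatial realism.
    """
    traces, truth = simulate_roi_traces(config)
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    h, w = shape
    r = roi_radius_px
    margin = int(np.ceil(3 * r))
    centers: list[tuple[int, int]] = []
    while len(centers) < config.n_rois:
        cy = int(rng.integers(margin, h - margin))
        cx = int(rng.integers(margin, w - margin))
        if all((cy - y) ** 2 + (cx - x) ** 2 >= (3 * r) ** 2 for y, x in centers):
            centers.append((cy, cx))
    yy, xx = np.mgrid[0:h, 0:w]
    stack = np.full((config.n_frames, h, w), 10.0)
    for (cy, cx), trace in zip(centers, traces.traces):
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        stack[:, disk] = trace[:, None]
    stack += rng.normal(0, 0.5, size=stack.shape)
    return stack, centers, truth
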