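"""File I/O for the pipeline's standard text and image formats."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calcium import RoiTraceSet, PeakSet, SyncEventSet
from .synthdata import CalciumTruth

__all__ = [
    "write_traces_csv",
    "read_traces_csv",
    "write_tiff_stack",
    "read_tiff_stack",
    "write_truth_json",
    "write_peaks_json",
]


def write_traces_csv(path, trace_sets: list[RoiTraceSet]) -> None:
    """Long-format trace table: fov_id, roi_id, frame, value (+ metadata)."""
    rows = []
    for ts in trace_sets:
        for roi in range(ts.n_rois):
            rows.append(
                pd.DataFrame(
                    {
                        "fov_id": ts.fov_id,
                        "roi_id": roi,
                        "frame": np.arange(ts.n_frames),
                        "value": ts.traces[roi],
                        "frame_interval_s": ts.frame_interval_s,
                        "organoid_id": ts.organoid_id,
                        "genotype": ts.genotype,
                        "condition": ts.condition,
                    }
                )
            )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_traces_csv(path) -> list[RoiTraceSet]:
    df = pd.read_csv(path, keep_default_na=False)
    out = []
    for fov_id, g in df.groupby("fov_id", sort=False):
        mat = g.pivot_table(index="roi_id", columns="frame", values="value", sort=True)
        first = g.iloc[0]
        out.append(
            RoiTraceSet(
                mat.to_numpy(),
                float(first["frame_interval_s"]),
                fov_id=str(fov_id),
                organoid_id=str(first.get("organoid_id", "")),
                genotype=str(first.get("genotype", "")),
                condition=str(first.get("condition", "baseline")),
            )
        )
    return out


def write_tiff_stack(path, stack: np.ndarray) -> None:
    import tifffile

    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


def read_tiff_stack(path) -> np.ndarray:
    import tifffile

    return np.asarray(tifffile.imread(path), dtype=float)


def write_truth_json(path, truth: CalciumTruth) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "roi_event_times": [t.tolist() for t in truth.roi_event_times],
                "roi_event_amplitudes": [a.tolist() for a in truth.roi_event_amplitudes],
                "sync_event_times": truth.sync_event_times.tolist(),
            }
        )
    )


def write_peaks_json(path, peaks: PeakSet, sync: SyncEventSet) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "peak_frames": [f.tolist() for f in peaks.frames],
                "peak_amplitudes": [a.tolist() for a in peaks.amplitudes],
                "sync_frames": sync.frames.tolist(),
                "sync_amplitudes": sync.amplitudes.tolist(),
            }
        )
    )
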