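"""Reading and writing the package's on-disk formats.

Videos travel as multi-page 16-bit grayscale TIFF with a JSON sidecar
(frame rate, exposure, dark offset, seed, schedule); dL/L0 movies as
32-bit float TIFF; traces and schedules as CSV; rendered output as a PNG
sequence.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .containers import TraceSeries, VideoStack
from .synthetic import StimulusSchedule

__all__ = [
    "save_video", "load_video", "save_movie", "load_movie",
    "save_schedule_csv", "load_schedule_csv",
    "save_trace_csv", "load_trace_csv", "save_png_sequence",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def save_video(path, video: VideoStack, *, schedule: StimulusSchedule | None = None,
               dark_offset: float | None = None, seed: int | None = None,
               extra: dict | None = None) -> None:
    """Write a stack as 16-bit TIFF plus a JSON sidecar of metadata.

    Counts are rounded and clipped to the uint16 range.
    """
    path = Path(path)
    data = np.clip(np.round(np.nan_to_num(video.data)), 0, 65535)
    tifffile.imwrite(path, data.astype(np.uint16), photometric="minisblack")
    meta = {"frame_rate": video.frame_rate, "exposure": video.exposure,
            "t0": video.t0}
    if dark_offset is not None:
        meta["dark_offset"] = dark_offset
    if seed is not None:
        meta["seed"] = seed
    if schedule is not None:
        meta["schedule"] = {"onsets": list(schedule.onsets),
                            "on_duration": schedule.on_duration,
                            "cycle_length": schedule.cycle_length,
                            "n_cycles": schedule.n_cycles}
    if extra:
        meta.update(extra)
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def load_video(path) -> tuple[VideoStack, dict]:
    """Read a TIFF stack and its JSON sidecar (empty dict if absent)."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    meta = {}
    if _sidecar_path(path).exists():
        meta = json.loads(_sidecar_path(path).read_text())
    video = VideoStack(data.astype(np.float64),
                       frame_rate=float(meta.get("frame_rate", 1.0)),
                       exposure=float(meta.get("exposure", 1.0)),
                       t0=float(meta.get("t0", 0.0)))
    return video, meta


def schedule_from_meta(meta: dict) -> StimulusSchedule | None:
    sched = meta.get("schedule")
    if sched is None:
        return None
    return StimulusSchedule(tuple(sched["onsets"]), sched["on_duration"],
                            sched["cycle_length"], sched["n_cycles"])


def save_movie(path, movie: np.ndarray) -> None:
    """Write a dL/L0 (or ratio) movie as 32-bit float TIFF."""
    tifffile.imwrite(Path(path), np.asarray(movie, dtype=np.float32),
                     photometric="minisblack")


def load_movie(path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.float64)


def save_schedule_csv(path, schedule: StimulusSchedule) -> None:
    pd.DataFrame({"onset_s": schedule.onsets,
                  "on_s": schedule.on_duration}).to_csv(path, index=False)


def load_schedule_csv(path) -> StimulusSchedule:
    df = pd.read_csv(path)
    onsets = df["onset_s"].to_numpy(dtype=float)
    on = float(df["on_s"].iloc[0])
    cycle = float(np.diff(onsets)[0]) if len(onsets) > 1 else on + 19.0
    return StimulusSchedule(tuple(onsets), on, cycle, len(onsets))


def save_trace_csv(path, trace: TraceSeries) -> None:
    pd.DataFrame({"frame": np.arange(len(trace)),
                  "time_s": trace.times,
                  "value": trace.values}).to_csv(path, index=False)


def load_trace_csv(path) -> TraceSeries:
    df = pd.read_csv(path)
    dt = float(np.diff(df["time_s"].to_numpy())[0])
    return TraceSeries(df["value"].to_numpy(dtype=float), 1.0 / dt,
                       t0=float(df["time_s"].iloc[0]))


def save_png_sequence(out_dir, rgb: np.ndarray, prefix: str = "frame") -> list[Path]:
    """Write a (time, rows, cols, 3) float RGB array as numbered PNGs."""
    import imageio.v3 as iio
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    arr = (np.clip(rgb, 0, 1) * 255).astype(np.uint8)
    for i, frame in enumerate(arr):
        p = out_dir / f"{prefix}_{i:04d}.png"
        iio.imwrite(p, frame)
        paths.append(p)
    return paths
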