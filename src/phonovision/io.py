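"""Reading and writing of the pipeline's on-disk formats.

Frame stacks travel as multi-page 16-bit TIFF (or a directory of numbered
16-bit PNGs) with a YAML sidecar carrying the calibration; waveforms,
edge tracks and signal traces are plain CSV via pandas.  Float columns use
a fixed ``%.9g`` format so that identical arrays serialize byte-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .datatypes import AreaWaveform, Calibration, EdgeTrack, FrameStack, GroundTruth, SignalTrace

FLOAT_FORMAT = "%.9g"
_U16_MAX = 65535


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml") if path.is_dir() else path.with_suffix(".yaml")


def save_frame_stack(stack: FrameStack, path, extra_metadata: dict | None = None) -> Path:
    """Write a stack as multi-page 16-bit TIFF plus a YAML sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.round(np.clip(stack.frames, 0, 1) * _U16_MAX).astype(np.uint16)
    tifffile.imwrite(path, data)
    meta = {
        "fps": float(stack.calib.fps),
        "mm_per_pixel": float(stack.calib.mm_per_pixel),
        "axis_orientation": stack.axis_orientation,
        "bit_depth": 16,
        "n_frames": int(stack.n_frames),
    }
    if extra_metadata:
        meta.update(extra_metadata)
    sidecar = _sidecar_path(path)
    sidecar.write_text(yaml.safe_dump(meta, sort_keys=True))
    return sidecar


def load_frame_stack(path) -> FrameStack:
    """Load a stack from a multi-page TIFF or a directory of numbered PNGs.

    The YAML sidecar written by :func:`save_frame_stack` must sit next to
    the stack and provide ``fps`` and ``mm_per_pixel``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no frame stack at {path}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing calibration sidecar {sidecar}")
    meta = yaml.safe_load(sidecar.read_text())

    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff"))
        if not files:
            raise FileNotFoundError(f"no frame images in directory {path}")
        frames = np.stack([iio.imread(p) for p in files])
    else:
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]

    if np.issubdtype(frames.dtype, np.integer):
        frames = frames.astype(np.float32) / float(np.iinfo(frames.dtype).max)
    stack = FrameStack(
        frames=frames,
        calib=Calibration(fps=float(meta["fps"]), mm_per_pixel=float(meta["mm_per_pixel"])),
        axis_orientation=meta.get("axis_orientation", "rows"),
    )
    if stack.axis_orientation == "columns":
        stack = FrameStack(
            frames=np.transpose(stack.frames, (0, 2, 1)), calib=stack.calib,
            axis_orientation="rows",
        )
    return stack


def save_ground_truth(truth: GroundTruth, area_path, edges_path=None) -> None:
    """Write the simulator ground truth: area CSV and optional per-row edge CSV."""
    area_path = Path(area_path)
    area_path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "frame_index": np.arange(len(truth.true_area)),
            "time_s": truth.time,
            "area_mm2": truth.true_area,
        }
    ).to_csv(area_path, index=False, float_format=FLOAT_FORMAT)
    if edges_path is not None:
        frames_rep = np.repeat(np.arange(truth.true_left_edge.shape[0]),
                               truth.true_left_edge.shape[1])
        fracs = np.tile(truth.row_fractions, truth.true_left_edge.shape[0])
        pd.DataFrame(
            {
                "frame_index": frames_rep,
                "axis_fraction": fracs,
                "left_mm": truth.true_left_edge.ravel(),
                "right_mm": truth.true_right_edge.ravel(),
            }
        ).to_csv(edges_path, index=False, float_format=FLOAT_FORMAT)


def save_area_waveform(wave: AreaWaveform, counts, path) -> None:
    """Write ``frame,time_s,pixels,area_mm2,area_mm2_smooth`` CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "frame": np.arange(len(wave.area_raw)),
            "time_s": wave.time,
            "pixels": np.asarray(counts, dtype=int),
            "area_mm2": wave.area_raw,
            "area_mm2_smooth": wave.area_smooth,
        }
    ).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def save_edge_track(track: EdgeTrack, time_s, path) -> None:
    """Write ``t,left_mm,right_mm,closed`` CSV for one scanline."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "t": np.asarray(time_s),
            "left_mm": track.left_mm,
            "right_mm": track.right_mm,
            "closed": track.closed.astype(int),
        }
    ).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def save_signal_trace(trace: SignalTrace, path) -> None:
    """Write a trace as two-column CSV with a JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    unit = "kpa" if trace.kind == "pressure" else "pa"
    pd.DataFrame({"time_s": trace.time, f"value_{unit}": trace.samples}).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )
    meta = {"kind": trace.kind, "fs": trace.fs, "metadata": trace.metadata}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=str))


def load_signal_trace(path) -> SignalTrace:
    """Load a trace written by :func:`save_signal_trace`."""
    path = Path(path)
    df = pd.read_csv(path)
    value_col = [c for c in df.columns if c.startswith("value")][0]
    meta_path = path.with_suffix(".json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        fs, kind, metadata = meta["fs"], meta["kind"], meta.get("metadata", {})
    else:
        dt = float(np.median(np.diff(df["time_s"].to_numpy())))
        fs = 1.0 / dt
        kind = "pressure" if value_col.endswith("kpa") else "acoustic"
        metadata = {}
    return SignalTrace(samples=df[value_col].to_numpy(), fs=fs, kind=kind, metadata=metadata)
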