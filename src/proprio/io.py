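"""Readers and writers for the pipeline's on-disk formats.

Trial tables and per-trial response tables are plain CSV; traces are one
CSV per session (``time_s, neuron_0, …``); wide-field stacks are
multi-frame TIFF with a JSON sidecar recording the acquisition rate and
channel order; stereo landmark correspondences are CSV and projection
matrices row-major 3×4 JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .twophoton import FluorescenceTrace
from .widefield import DualChannelStack

__all__ = [
    "write_trial_table",
    "read_trial_table",
    "write_traces_csv",
    "read_traces_csv",
    "write_stack",
    "read_stack",
    "write_projection_matrices",
    "read_projection_matrices",
    "read_landmark_pairs",
]


def write_trial_table(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def read_trial_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_traces_csv(traces: list[FluorescenceTrace], path) -> None:
    if not traces:
        raise ValueError("no traces to write")
    fs = traces[0].frame_rate_hz
    n = traces[0].values.size
    if any(t.frame_rate_hz != fs or t.values.size != n for t in traces):
        raise ValueError("traces must share sampling rate and length")
    df = pd.DataFrame({"time_s": traces[0].times_s})
    for i, t in enumerate(traces):
        df[f"neuron_{i}"] = t.values
    df.to_csv(path, index=False, float_format="%.12g")


def read_traces_csv(path) -> list[FluorescenceTrace]:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    fs = 1.0 / float(np.median(np.diff(t)))
    return [
        FluorescenceTrace(values=df[c].to_numpy(), frame_rate_hz=fs,
                          t0_s=float(t[0]), neuron_id=i)
        for i, c in enumerate(c for c in df.columns if c != "time_s")
    ]


def write_stack(stack: DualChannelStack, tiff_path, sidecar_path=None) -> None:
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, stack.frames.astype(np.float32))
    sidecar = sidecar_path or tiff_path.with_suffix(".json")
    meta = {
        "acquisition_rate_hz": stack.acquisition_rate_hz,
        "channel_order": list(map(str, stack.channel_labels[:2])),
        "frame_times_s": [float(t) for t in stack.frame_times_s],
    }
    Path(sidecar).write_text(json.dumps(meta))


def read_stack(tiff_path, sidecar_path=None) -> DualChannelStack:
    tiff_path = Path(tiff_path)
    frames = tifffile.imread(tiff_path).astype(float)
    meta = json.loads(Path(sidecar_path or tiff_path.with_suffix(".json")).read_text())
    order = meta["channel_order"]
    labels = np.array([order[i % 2] for i in range(frames.shape[0])])
    return DualChannelStack(
        frames=frames,
        frame_times_s=np.asarray(meta["frame_times_s"], dtype=float),
        channel_labels=labels,
        acquisition_rate_hz=float(meta["acquisition_rate_hz"]),
    )


def write_projection_matrices(P1, P2, path) -> None:
    Path(path).write_text(
        json.dumps({"camera1": np.asarray(P1).tolist(), "camera2": np.asarray(P2).tolist()})
    )


def read_projection_matrices(path) -> tuple[np.ndarray, np.ndarray]:
    data = json.loads(Path(path).read_text())
    P1 = np.asarray(data["camera1"], dtype=float)
    P2 = np.asarray(data["camera2"], dtype=float)
    if P1.shape != (3, 4) or P2.shape != (3, 4):
        raise ValueError("projection matrices must be 3x4")
    return P1, P2


def read_landmark_pairs(path) -> pd.DataFrame:
    """Landmark correspondence CSV: columns landmark, cam1_u, cam1_v,
    cam2_u, cam2_v, grid_x_cm, grid_y_cm (one row per landmark and pose)."""
    df = pd.read_csv(path)
    required = {"landmark", "cam1_u", "cam1_v", "cam2_u", "cam2_v", "grid_x_cm", "grid_y_cm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"landmark file missing columns {sorted(missing)}")
    return df
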