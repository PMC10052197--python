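"""Disk formats: one ``.npz`` array store per recording plus columnar text
for ground truth, channels, masks and estimates."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GroundTruth, RadarFrameMatrix

__all__ = [
    "save_recording",
    "load_recording",
    "save_ground_truth",
    "load_ground_truth",
]


def save_recording(path: str | Path, frames: RadarFrameMatrix) -> None:
    np.savez_compressed(
        path,
        data=frames.data.astype(np.float32),
        Ts=frames.Ts,
        Tf=frames.Tf,
        range_offset=frames.range_offset,
    )


def load_recording(path: str | Path) -> RadarFrameMatrix:
    with np.load(path) as z:
        return RadarFrameMatrix(
            data=np.asarray(z["data"], dtype=float),
            Ts=float(z["Ts"]),
            Tf=float(z["Tf"]),
            range_offset=float(z["range_offset"]),
        )


def save_ground_truth(path: str | Path, truth: GroundTruth, frame_rate: float = 20.0) -> None:
    n = truth.rr_per_second.size
    # per-second artifact flag: any flagged frame within the second
    per_sec = truth.artifact_mask.copy()
    fpsec = int(round(frame_rate))
    flags = np.array(
        [per_sec[i * fpsec : (i + 1) * fpsec].any() for i in range(n)], dtype=int
    )
    pd.DataFrame(
        {
            "time_s": np.arange(n),
            "rr_rpm": truth.rr_per_second,
            "hr_bpm": truth.hr_per_second,
            "artifact": flags,
        }
    ).to_csv(path, index=False)


def load_ground_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
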