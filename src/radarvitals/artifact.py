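"""Motion/noise artifact detection on the selected radar channel.

The rectified channel is smoothed with a Savitzky–Golay filter (order 2,
21-sample frame, about one second at 20 fps) to form an envelope that keeps
burst peaks while flattening the breathing oscillation. An adaptive threshold
is the sum of three causal moving averages of that envelope with 10, 30 and
100 s windows, so both short jerks and long restless periods stand out; a
frame is flagged wherever the envelope exceeds the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .preprocess import SelectedChannel

__all__ = [
    "ArtifactMask",
    "smooth_envelope",
    "adaptive_threshold",
    "detect",
    "segment_flags",
]

SAVGOL_WINDOW = 21
SAVGOL_ORDER = 2
THRESHOLD_WINDOWS_S = (10.0, 30.0, 100.0)
SEGMENT_FLAG_FRACTION = 0.10


@dataclass
class ArtifactMask:
    flags: np.ndarray       # per-frame boolean
    envelope: np.ndarray
    threshold: np.ndarray


def smooth_envelope(
    channel: SelectedChannel,
    window_length: int = SAVGOL_WINDOW,
    polyorder: int = SAVGOL_ORDER,
) -> np.ndarray:
    """Savitzky–Golay-smoothed |x|."""
    if window_length % 2 == 0 or window_length <= polyorder:
        raise ValueError(
            f"Savitzky-Golay frame length must be odd and > {polyorder}, "
            f"got {window_length}"
        )
    x = np.abs(np.asarray(channel.samples, dtype=float))
    if x.size < window_length:
        raise ValueError(
            f"channel length {x.size} shorter than the {window_length}-sample filter"
        )
    return savgol_filter(x, window_length, polyorder)


def causal_moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Mean over the trailing ``window`` samples (including the current one);
    before the window fills, the mean of all samples seen so far."""
    x = np.asarray(x, dtype=float)
    cs = np.cumsum(x)
    n = x.size
    out = np.empty(n)
    head = min(window, n)
    out[:head] = cs[:head] / (np.arange(head) + 1)
    if n > window:
        out[window:] = (cs[window:] - cs[:-window]) / window
    return out


def adaptive_threshold(
    envelope: np.ndarray,
    frame_rate: float = 20.0,
    windows_s: tuple[float, ...] = THRESHOLD_WINDOWS_S,
) -> np.ndarray:
    """Sum of causal moving averages of the envelope at several time scales."""
    envelope = np.asarray(envelope, dtype=float)
    if envelope.size == 0:
        raise ValueError("empty envelope")
    out = np.zeros_like(envelope)
    for w_s in windows_s:
        out += causal_moving_average(envelope, max(1, int(round(w_s * frame_rate))))
    return out


def detect(
    channel: SelectedChannel,
    window_length: int = SAVGOL_WINDOW,
    polyorder: int = SAVGOL_ORDER,
    windows_s: tuple[float, ...] = THRESHOLD_WINDOWS_S,
) -> ArtifactMask:
    env = smooth_envelope(channel, window_length, polyorder)
    thr = adaptive_threshold(env, channel.frame_rate, windows_s)
    return ArtifactMask(flags=env > thr, envelope=env, threshold=thr)


def segment_flags(
    mask: ArtifactMask,
    frame_rate: float = 20.0,
    window_s: float = 15.0,
    stride_s: float = 1.0,
    fraction: float = SEGMENT_FLAG_FRACTION,
) -> np.ndarray:
    """Per-segment flag: true when more than ``fraction`` of a window's
    frames are artifact-flagged. Windows match the feature segmentation."""
    w = int(round(window_s * frame_rate))
    s = int(round(stride_s * frame_rate))
    flags = np.asarray(mask.flags, dtype=bool)
    if flags.size < w:
        raise ValueError("mask shorter than one segment window")
    n_seg = (flags.size - w) // s + 1
    cs = np.concatenate([[0], np.cumsum(flags)])
    starts = np.arange(n_seg) * s
    frac = (cs[starts + w] - cs[starts]) / w
    return frac > fraction
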