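"""Radar-frame preprocessing: clutter removal, target-bin localization,
channel extraction and band-pass filtering.

Static room clutter (walls, furniture) appears as a DC component along slow
time; it is removed with a causal running mean per fast-time bin. The subject
is located as the fast-time bin with the largest slow-time standard
deviation — periodic chest motion makes the received amplitude fluctuate at
that range. The selected slow-time series is z-score normalized and, for
spectral/CNN features, band-limited to 0.1–5 Hz with fifth-order Butterworth
high- and low-pass stages.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .simulate import RadarFrameMatrix

__all__ = [
    "SelectedChannel",
    "remove_clutter",
    "locate_target",
    "locate_target_sliding",
    "extract_channel",
    "bandpass",
    "bandpass_sos",
]


@dataclass
class SelectedChannel:
    """The z-normalized slow-time series at the located range bin."""

    samples: np.ndarray
    target_bin: int
    frame_rate: float
    std_profile: np.ndarray | None = None


def remove_clutter(frames: RadarFrameMatrix, span_s: float = 20.0) -> RadarFrameMatrix:
    """Subtract a causal running mean (``span_s`` seconds, including the
    current frame) from every fast-time bin.

    The span passes DC and sub-0.05 Hz drift into the estimate (so both are
    removed from the output) while leaving the 0.1–5 Hz vital band nearly
    untouched. A bin that is constant in slow time maps to exactly zero.
    """
    x = np.asarray(frames.data, dtype=float)
    w = int(round(span_s * frames.frame_rate))
    if w < 1:
        raise ValueError(f"span_s {span_s} shorter than one frame period")
    if x.shape[0] < w:
        raise ValueError(
            f"recording has {x.shape[0]} frames, fewer than the "
            f"{w}-frame clutter-estimation span"
        )
    cs = np.cumsum(x, axis=0)
    mean = np.empty_like(x)
    m = x.shape[0]
    idx = np.arange(m)
    # warm-up: mean of all frames seen so far
    head = min(w, m)
    mean[:head] = cs[:head] / (idx[:head, None] + 1)
    if m > w:
        mean[w:] = (cs[w:] - cs[:-w]) / w
    return replace(frames, data=x - mean)


def locate_target(frames: RadarFrameMatrix) -> tuple[int, np.ndarray]:
    """Whole-recording per-bin standard deviation; argmax is the target.

    Ties break toward the smaller (nearer) bin. Raises on an all-zero
    matrix, which carries no target signature.
    """
    x = np.asarray(frames.data, dtype=float)
    profile = x.std(axis=0)
    if not np.any(profile > 0):
        raise ValueError("all-zero frame matrix: no target signature")
    return int(np.argmax(profile)), profile


def locate_target_sliding(
    frames: RadarFrameMatrix,
    window_s: float = 30.0,
    hop_s: float = 1.0,
    hysteresis_bins: int = 3,
) -> np.ndarray:
    """Streaming variant: per-window STD argmax with hysteresis.

    The reported bin only changes when the new argmax moves more than
    ``hysteresis_bins`` away from the current one, suppressing jitter
    between adjacent bins. Returns one bin index per hop.
    """
    x = np.asarray(frames.data, dtype=float)
    w = int(round(window_s * frames.frame_rate))
    hop = int(round(hop_s * frames.frame_rate))
    if x.shape[0] < w:
        raise ValueError("recording shorter than the sliding STD window")
    bins = []
    current: int | None = None
    for start in range(0, x.shape[0] - w + 1, hop):
        cand = int(np.argmax(x[start : start + w].std(axis=0)))
        if current is None or abs(cand - current) > hysteresis_bins:
            current = cand
        bins.append(current)
    return np.asarray(bins, dtype=int)


def extract_channel(frames: RadarFrameMatrix, target_bin: int) -> SelectedChannel:
    """Slow-time series at ``target_bin``, z-scored over the recording."""
    if not 0 <= target_bin < frames.n_bins:
        raise ValueError(f"target_bin {target_bin} outside [0, {frames.n_bins})")
    raw = np.asarray(frames.data[:, target_bin], dtype=float)
    sd = raw.std()
    if sd == 0:
        raise ValueError(f"channel at bin {target_bin} has zero variance")
    return SelectedChannel(
        samples=(raw - raw.mean()) / sd,
        target_bin=int(target_bin),
        frame_rate=frames.frame_rate,
    )


def prepare_channel(frames: RadarFrameMatrix, span_s: float = 20.0) -> SelectedChannel:
    """remove_clutter -> locate_target -> extract_channel in one call."""
    cleaned = remove_clutter(frames, span_s)
    target_bin, profile = locate_target(cleaned)
    ch = extract_channel(cleaned, target_bin)
    ch.std_profile = profile
    return ch


def bandpass_sos(
    frame_rate: float, hp_hz: float = 0.1, lp_hz: float = 5.0, order: int = 5
) -> np.ndarray:
    """Second-order sections of the Butterworth high-pass/low-pass cascade."""
    nyq = frame_rate / 2.0
    if not 0 < hp_hz < nyq:
        raise ValueError(f"high-pass cutoff {hp_hz} Hz not inside (0, {nyq}) Hz")
    if not hp_hz < lp_hz < nyq:
        raise ValueError(f"low-pass cutoff {lp_hz} Hz not inside ({hp_hz}, {nyq}) Hz")
    hp = signal.butter(order, hp_hz, btype="highpass", fs=frame_rate, output="sos")
    lp = signal.butter(order, lp_hz, btype="lowpass", fs=frame_rate, output="sos")
    return np.vstack([hp, lp])


def bandpass(
    channel: SelectedChannel,
    hp_hz: float = 0.1,
    lp_hz: float = 5.0,
    order: int = 5,
    zero_phase: bool = False,
) -> SelectedChannel:
    """0.1–5 Hz Butterworth band limit (order 5 per stage).

    Causal (direct-form) by default to honour the streaming contract; pass
    ``zero_phase=True`` for offline forward-backward filtering.
    """
    sos = bandpass_sos(channel.frame_rate, hp_hz, lp_hz, order)
    if zero_phase:
        y = signal.sosfiltfilt(sos, channel.samples)
    else:
        y = signal.sosfilt(sos, channel.samples)
    return replace(channel, samples=np.asarray(y, dtype=float))
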