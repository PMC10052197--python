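"""Segmentation, time–frequency scalograms and dataset assembly.

The band-passed channel is cut into 15 s windows hopped by 1 s (300 samples
at 20 fps). Each window is paired with a 123x300 scalogram: the magnitude of
a continuous wavelet transform built from generalized Morse wavelets
(gamma=3, beta=20), evaluated at 123 log-spaced center frequencies in
(0.05, 5] Hz. Per-segment labels are the window-mean respiration and heart
rates; datasets are split at the recording level and the training split
drops artifact-flagged segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.fft import fft, ifft, next_fast_len

from . import artifact as _artifact
from . import preprocess as _pre
from .simulate import GroundTruth, RadarFrameMatrix

__all__ = [
    "Segment",
    "SegmentDataset",
    "segment_signal",
    "cwt_scalogram",
    "scalogram_frequencies",
    "rates_from_peaks",
    "build_dataset",
    "MORSE_GAMMA",
    "MORSE_BETA",
    "N_FREQS",
    "FREQ_RANGE_HZ",
]

MORSE_GAMMA = 3.0
MORSE_BETA = 20.0
N_FREQS = 123
FREQ_RANGE_HZ = (0.05, 5.0)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def segment_signal(
    samples: np.ndarray,
    frame_rate: float = 20.0,
    window_s: float = 15.0,
    stride_s: float = 1.0,
) -> np.ndarray:
    """All complete windows of ``window_s`` hopped by ``stride_s``.

    Window ``i`` covers samples ``[stride*i, stride*i + window)``; the count
    is ``floor((L - window)/stride) + 1``.
    """
    x = np.asarray(samples, dtype=float)
    w = int(round(window_s * frame_rate))
    s = int(round(stride_s * frame_rate))
    if x.size < w:
        raise ValueError(f"channel length {x.size} shorter than one {w}-sample window")
    n = (x.size - w) // s + 1
    starts = np.arange(n) * s
    return x[starts[:, None] + np.arange(w)[None, :]]


# ---------------------------------------------------------------------------
# Morse-wavelet CWT
# ---------------------------------------------------------------------------


def scalogram_frequencies(
    n_freqs: int = N_FREQS, freq_range: tuple[float, float] = FREQ_RANGE_HZ
) -> np.ndarray:
    """Log-spaced scalogram row center frequencies, low to high (Hz)."""
    lo, hi = freq_range
    return np.logspace(math.log10(lo), math.log10(hi), n_freqs)


@lru_cache(maxsize=8)
def _morse_filter_bank(
    n: int, frame_rate: float, n_freqs: int, freq_range: tuple[float, float],
    gamma: float, beta: float,
) -> tuple[np.ndarray, int]:
    """Frequency responses of the analytic Morse filter bank.

    Psi(w) ~ w^beta * exp(-w^gamma) for w > 0, unit peak gain (reached at
    w_p = (beta/gamma)^(1/gamma)) and doubled on positive frequencies so a
    unit-amplitude real tone at a row's center frequency produces |W| = 1.
    """
    nfft = next_fast_len(2 * n)
    freqs = scalogram_frequencies(n_freqs, freq_range)
    w_p = (beta / gamma) ** (1.0 / gamma)
    # scale per row: s * (2*pi*f/fs) = w_p at the center frequency
    scales = w_p * frame_rate / (2.0 * np.pi * freqs)
    omega = 2.0 * np.pi * np.fft.fftfreq(nfft)          # digital rad/sample
    H = np.zeros((n_freqs, nfft))
    pos = omega > 0
    sw = scales[:, None] * omega[None, pos]
    ln_peak = beta * math.log(w_p) - w_p**gamma
    H[:, pos] = 2.0 * np.exp(beta * np.log(sw) - sw**gamma - ln_peak)
    return H, nfft


def cwt_scalogram(
    window: np.ndarray,
    frame_rate: float = 20.0,
    n_freqs: int = N_FREQS,
    freq_range: tuple[float, float] = FREQ_RANGE_HZ,
    gamma: float = MORSE_GAMMA,
    beta: float = MORSE_BETA,
) -> np.ndarray:
    """CWT magnitude, shape ``(n_freqs, len(window))``, rows low->high.

    Implemented as an FFT filter bank (zero-padded to suppress circular
    wrap); low-frequency rows whose wavelet outlasts the window are edge
    dominated, which is inherent to the window length, not the transform.
    """
    x = np.asarray(window, dtype=float)
    if x.ndim != 1:
        raise ValueError("window must be 1-D")
    if not np.all(np.isfinite(x)):
        raise ValueError("window contains non-finite values")
    H, nfft = _morse_filter_bank(
        x.size, float(frame_rate), int(n_freqs), tuple(freq_range), gamma, beta
    )
    X = fft(x, nfft)
    W = ifft(H * X[None, :], axis=1)[:, : x.size]
    return np.abs(W)


# ---------------------------------------------------------------------------
# labels
# ---------------------------------------------------------------------------


def rates_from_peaks(peak_times: np.ndarray) -> float:
    """Rate per minute from reference-signal peak times: 60 / mean interval.

    Returns NaN (missing-label marker) with fewer than two peaks.
    """
    t = np.asarray(peak_times, dtype=float)
    if t.size < 2:
        return float("nan")
    return 60.0 / float(np.mean(np.diff(t)))


def window_mean_labels(
    per_second: np.ndarray, n_segments: int, window_s: int = 15, stride_s: int = 1
) -> np.ndarray:
    """Mean ground-truth rate over each segment's time span."""
    x = np.asarray(per_second, dtype=float)
    out = np.empty(n_segments)
    for i in range(n_segments):
        start = i * stride_s
        out[i] = x[start : start + window_s].mean()
    return out


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------


@dataclass
class Segment:
    x1d: np.ndarray
    x2d: np.ndarray
    t_end: float
    rr_label: float
    hr_label: float
    artifact: bool


@dataclass
class SegmentDataset:
    """Paired 1D windows and 2D scalograms with RR/HR labels."""

    x1d: np.ndarray          # (n, window_samples) float32
    x2d: np.ndarray          # (n, n_freqs, window_samples) float32
    y: np.ndarray            # (n, 2): rr_rpm, hr_bpm
    artifact: np.ndarray     # (n,) bool
    t_end: np.ndarray        # (n,) seconds
    recording_id: np.ndarray  # (n,) int
    split_tag: str = ""

    def __len__(self) -> int:
        return self.x1d.shape[0]

    def __getitem__(self, i: int) -> Segment:
        return Segment(
            x1d=self.x1d[i], x2d=self.x2d[i], t_end=float(self.t_end[i]),
            rr_label=float(self.y[i, 0]), hr_label=float(self.y[i, 1]),
            artifact=bool(self.artifact[i]),
        )

    def subset(self, idx: np.ndarray, split_tag: str | None = None) -> "SegmentDataset":
        return SegmentDataset(
            self.x1d[idx], self.x2d[idx], self.y[idx], self.artifact[idx],
            self.t_end[idx], self.recording_id[idx],
            self.split_tag if split_tag is None else split_tag,
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez_compressed(
            path, x1d=self.x1d, x2d=self.x2d, y=self.y,
            artifact=self.artifact, t_end=self.t_end,
            recording_id=self.recording_id, split_tag=self.split_tag,
        )
        pd.DataFrame(
            {
                "t_end": self.t_end, "rr_rpm": self.y[:, 0], "hr_bpm": self.y[:, 1],
                "artifact": self.artifact.astype(int), "recording_id": self.recording_id,
            }
        ).to_csv(path.with_suffix(".manifest.csv"), index=False)

    @classmethod
    def load(cls, path: str | Path) -> "SegmentDataset":
        with np.load(path) as z:
            return cls(
                x1d=z["x1d"], x2d=z["x2d"], y=z["y"], artifact=z["artifact"],
                t_end=z["t_end"], recording_id=z["recording_id"],
                split_tag=str(z["split_tag"]),
            )


def segments_from_recording(
    frames: RadarFrameMatrix,
    truth: GroundTruth | None = None,
    recording_id: int = 0,
    window_s: float = 15.0,
    stride_s: float = 1.0,
    clutter_span_s: float = 20.0,
    n_freqs: int = N_FREQS,
) -> SegmentDataset:
    """Full per-recording feature extraction.

    Clutter removal, STD localization, channel z-score, artifact detection
    on the unfiltered channel, band-pass, segmentation, scalograms, and
    (when ground truth is given) window-mean labels.
    """
    ch = _pre.prepare_channel(frames, clutter_span_s)
    mask = _artifact.detect(ch)
    seg_art = _artifact.segment_flags(
        mask, ch.frame_rate, window_s=window_s, stride_s=stride_s
    )
    bp = _pre.bandpass(ch)
    x1d = segment_signal(bp.samples, ch.frame_rate, window_s, stride_s)
    n = x1d.shape[0]
    w = x1d.shape[1]
    x2d = np.empty((n, n_freqs, w), dtype=np.float32)
    for i in range(n):
        x2d[i] = cwt_scalogram(x1d[i], ch.frame_rate, n_freqs)
    t_end = window_s + np.arange(n) * stride_s
    if truth is not None:
        rr = window_mean_labels(truth.rr_per_second, n, int(window_s), int(stride_s))
        hr = window_mean_labels(truth.hr_per_second, n, int(window_s), int(stride_s))
        y = np.stack([rr, hr], axis=1)
    else:
        y = np.full((n, 2), np.nan)
    return SegmentDataset(
        x1d=x1d.astype(np.float32), x2d=x2d, y=y,
        artifact=seg_art[:n], t_end=t_end,
        recording_id=np.full(n, recording_id), split_tag="",
    )


def _concat(parts: list[SegmentDataset], tag: str) -> SegmentDataset:
    return SegmentDataset(
        x1d=np.concatenate([p.x1d for p in parts]),
        x2d=np.concatenate([p.x2d for p in parts]),
        y=np.concatenate([p.y for p in parts]),
        artifact=np.concatenate([p.artifact for p in parts]),
        t_end=np.concatenate([p.t_end for p in parts]),
        recording_id=np.concatenate([p.recording_id for p in parts]),
        split_tag=tag,
    )


def build_dataset(
    recordings: list[tuple[RadarFrameMatrix, GroundTruth]],
    split_plan: tuple[int, int, int] | dict[str, list[int]] = (10, 5, 15),
    seed: int = 0,
    window_s: float = 15.0,
    stride_s: float = 1.0,
    train_stride_s: float | None = None,
    clutter_span_s: float = 20.0,
) -> dict[str, SegmentDataset]:
    """Recording-level random split into train/val/test segment datasets.

    ``split_plan`` is either (n_train, n_val, n_test) counts — recordings
    are assigned by a seeded permutation — or an explicit mapping of split
    name to recording indices (must be disjoint). The training split drops
    artifact-flagged segments and may use a coarser stride
    (``train_stride_s``) to thin near-duplicate windows; validation and test
    keep every segment, artifacts included.
    """
    n = len(recordings)
    if isinstance(split_plan, dict):
        assign = {k: list(v) for k, v in split_plan.items()}
        seen: set[int] = set()
        for ids in assign.values():
            if seen & set(ids):
                raise ValueError("overlapping split assignment")
            seen |= set(ids)
    else:
        n_train, n_val, n_test = split_plan
        if n_train + n_val + n_test > n:
            raise ValueError(
                f"split plan {split_plan} needs more than the {n} recordings given"
            )
        perm = np.random.default_rng(seed).permutation(n)
        assign = {
            "train": perm[:n_train].tolist(),
            "val": perm[n_train : n_train + n_val].tolist(),
            "test": perm[n_train + n_val : n_train + n_val + n_test].tolist(),
        }

    out: dict[str, SegmentDataset] = {}
    for tag, ids in assign.items():
        stride = stride_s
        if tag == "train" and train_stride_s is not None:
            stride = train_stride_s
        if not ids:
            continue
        parts = [
            segments_from_recording(
                *recordings[i], recording_id=i, window_s=window_s,
                stride_s=stride, clutter_span_s=clutter_span_s,
            )
            for i in ids
        ]
        ds = _concat(parts, tag)
        if tag == "train":
            ds = ds.subset(~ds.artifact, "train")
        out[tag] = ds
    return out
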