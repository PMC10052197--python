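"""End-to-end streaming estimation: radar frames in, per-second RR/HR out.

The whole-recording steps (clutter removal, STD target localization,
recording-level z-score) run once; the selected channel then flows through a
causal, stateful estimator — band-pass, artifact detection, 15 s / 1 s hop
segmentation, scalogram, CNN inference — emitting one (RR, HR) pair per
second after the first window. Feeding the channel in chunks produces
bit-identical output to one call.

During artifact-flagged seconds the emitted value is the mean of a buffer
holding the last five clean estimates (the buffer is frozen while the
artifact lasts), suppressing spurious jumps when the subject moves.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_coeffs, savgol_filter, sosfilt

from . import artifact as _artifact
from . import features as _features
from . import preprocess as _pre
from .model import TrainedModel, predict
from .simulate import GroundTruth, RadarFrameMatrix

__all__ = [
    "VitalEstimate",
    "EvalReport",
    "postprocess",
    "VitalSignEstimator",
    "run_recording",
    "evaluate",
]

POSTPROCESS_BUFFER_S = 5


@dataclass
class VitalEstimate:
    time_s: np.ndarray     # second marks (end of each window)
    rr_raw: np.ndarray
    hr_raw: np.ndarray
    rr_final: np.ndarray
    hr_final: np.ndarray
    artifact: np.ndarray   # per-segment flag
    target_bin: int = -1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s, "rr_raw": self.rr_raw, "hr_raw": self.hr_raw,
                "rr_final": self.rr_final, "hr_final": self.hr_final,
                "artifact": self.artifact.astype(int),
            }
        )


class _RateBuffer:
    """Rolling buffer of the last clean estimates of one vital."""

    def __init__(self, size: int = POSTPROCESS_BUFFER_S) -> None:
        self._buf: deque[float] = deque(maxlen=size)

    def step(self, raw: float, flagged: bool) -> float:
        if flagged:
            # frozen during artifacts; before any clean estimate exists the
            # raw value is the only information available
            return float(np.mean(self._buf)) if self._buf else raw
        self._buf.append(raw)
        return raw


def postprocess(
    rr_raw: np.ndarray, hr_raw: np.ndarray, seg_flags: np.ndarray,
    buffer_len: int = POSTPROCESS_BUFFER_S,
) -> tuple[np.ndarray, np.ndarray]:
    """Replace artifact-section estimates by the pre-artifact buffer mean."""
    rr_raw = np.asarray(rr_raw, dtype=float)
    hr_raw = np.asarray(hr_raw, dtype=float)
    seg_flags = np.asarray(seg_flags, dtype=bool)
    if not (rr_raw.shape == hr_raw.shape == seg_flags.shape):
        raise ValueError("raw streams and artifact flags must be aligned")
    rb, hb = _RateBuffer(buffer_len), _RateBuffer(buffer_len)
    rr = np.array([rb.step(r, f) for r, f in zip(rr_raw, seg_flags)])
    hr = np.array([hb.step(h, f) for h, f in zip(hr_raw, seg_flags)])
    return rr, hr


class VitalSignEstimator:
    """Causal chunk-by-chunk estimator over the selected channel.

    State carried between ``process`` calls: band-pass filter sections,
    the Savitzky–Golay tail, moving-average accumulators of the adaptive
    threshold, the open segment window, and the postprocessing buffers.
    Latency is one window (15 s) plus half the envelope filter (0.5 s).
    """

    def __init__(self, trained: TrainedModel, frame_rate: float = 20.0,
                 window_s: float = 15.0, stride_s: float = 1.0,
                 buffer_len: int = POSTPROCESS_BUFFER_S) -> None:
        self.trained = trained
        self.fs = frame_rate
        self.w = int(round(window_s * frame_rate))
        self.hop = int(round(stride_s * frame_rate))
        self.window_s = window_s

        self.sos = _pre.bandpass_sos(frame_rate)
        self._zi = np.zeros((self.sos.shape[0], 2))
        self._sg = savgol_coeffs(_artifact.SAVGOL_WINDOW, _artifact.SAVGOL_ORDER)
        self._half = _artifact.SAVGOL_WINDOW // 2
        self._ma_windows = [
            max(1, int(round(w_s * frame_rate))) for w_s in _artifact.THRESHOLD_WINDOWS_S
        ]
        self._ma_bufs = [deque() for _ in self._ma_windows]
        self._ma_sums = [0.0 for _ in self._ma_windows]

        self._raw: list[float] = []        # |x| history (for SG edges)
        self._bp = np.empty(0)             # band-passed channel
        self._flags = np.empty(0, dtype=bool)
        self._env_n = 0                    # envelope samples emitted
        self._next_end = self.w            # end sample of the next window
        self._rbuf = _RateBuffer(buffer_len)
        self._hbuf = _RateBuffer(buffer_len)
        self._out: list[tuple[float, float, float, float, float, bool]] = []

    # -- internals ----------------------------------------------------------

    def _emit_envelope(self, value: float) -> None:
        flag = value > self._threshold_step(value)
        self._flags = np.append(self._flags, flag)
        self._env_n += 1

    def _threshold_step(self, env_value: float) -> float:
        thr = 0.0
        for i, w in enumerate(self._ma_windows):
            buf, s = self._ma_bufs[i], self._ma_sums[i] + env_value
            buf.append(env_value)
            if len(buf) > w:
                s -= buf.popleft()
            self._ma_sums[i] = s
            thr += s / len(buf)
        return thr

    def _advance_envelope(self, flush: bool = False) -> None:
        """Emit envelope/flag samples as soon as their SG window is known."""
        n = len(self._raw)
        wl = _artifact.SAVGOL_WINDOW
        if n < wl:
            if flush:
                raise ValueError(f"channel shorter than the {wl}-sample envelope filter")
            return
        absx = self._raw
        if self._env_n < self._half:
            # leading edge: polynomial fit over the first filter window
            head = savgol_filter(np.asarray(absx[:wl]), wl, _artifact.SAVGOL_ORDER)
            for i in range(self._env_n, self._half):
                self._emit_envelope(float(head[i]))
        last_central = n - self._half - 1
        while self._env_n <= last_central:
            i = self._env_n
            seg = np.asarray(absx[i - self._half : i + self._half + 1])
            self._emit_envelope(float(np.dot(self._sg, seg)))
        if flush:
            tail = savgol_filter(np.asarray(absx[-wl:]), wl, _artifact.SAVGOL_ORDER)
            while self._env_n < n:
                self._emit_envelope(float(tail[wl - (n - self._env_n)]))

    def _emit_ready_windows(self) -> None:
        while self._next_end <= self._bp.size and self._next_end <= self._flags.size:
            e = self._next_end
            x1d = self._bp[e - self.w : e][None, :]
            x2d = _features.cwt_scalogram(x1d[0], self.fs)[None, :, :]
            cfg = self.trained.config
            wm = int(round(cfg.window_s * self.fs))
            rr, hr = predict(self.trained, (
                x1d[:, -wm:] if cfg.branches in ("1d", "1d+2d") else None,
                x2d[:, :, -wm:] if cfg.branches in ("2d", "1d+2d") else None,
            ))[0]
            frac = float(np.mean(self._flags[e - self.w : e]))
            flagged = frac > _artifact.SEGMENT_FLAG_FRACTION
            rr_f = self._rbuf.step(float(rr), flagged)
            hr_f = self._hbuf.step(float(hr), flagged)
            self._out.append((e / self.fs, float(rr), float(hr), rr_f, hr_f, flagged))
            self._next_end += self.hop

    # -- public surface -----------------------------------------------------

    def process(self, samples: np.ndarray) -> None:
        """Consume the next chunk of the z-scored selected channel."""
        x = np.asarray(samples, dtype=float).ravel()
        if x.size == 0:
            return
        y, self._zi = sosfilt(self.sos, x, zi=self._zi)
        self._bp = np.append(self._bp, y)
        self._raw.extend(np.abs(x).tolist())
        self._advance_envelope()
        self._emit_ready_windows()

    def flush(self) -> None:
        """Close the stream: resolve the envelope tail and emit what remains."""
        self._advance_envelope(flush=True)
        self._emit_ready_windows()

    def result(self, target_bin: int = -1) -> VitalEstimate:
        if not self._out:
            raise ValueError("no estimates: channel shorter than one window")
        t, rr, hr, rrf, hrf, fl = map(np.asarray, zip(*self._out))
        return VitalEstimate(
            time_s=t.astype(float), rr_raw=rr.astype(float), hr_raw=hr.astype(float),
            rr_final=rrf.astype(float), hr_final=hrf.astype(float),
            artifact=fl.astype(bool), target_bin=target_bin,
        )


def run_recording(
    frames: RadarFrameMatrix, trained: TrainedModel,
    clutter_span_s: float = 20.0, chunk_s: float | None = None,
) -> VitalEstimate:
    """Full pipeline on one recording; ``chunk_s`` streams the channel in
    pieces (the result is identical to one-shot processing)."""
    try:
        channel = _pre.prepare_channel(frames, clutter_span_s)
    except ValueError as e:
        raise ValueError(f"preprocess: {e}") from e
    est = VitalSignEstimator(trained, frame_rate=channel.frame_rate)
    x = channel.samples
    try:
        if chunk_s is None:
            est.process(x)
        else:
            step = int(round(chunk_s * channel.frame_rate))
            for s in range(0, x.size, step):
                est.process(x[s : s + step])
        est.flush()
        return est.result(target_bin=channel.target_bin)
    except ValueError as e:
        raise ValueError(f"estimate: {e}") from e


@dataclass
class EvalReport:
    per_recording: pd.DataFrame
    summary: pd.DataFrame

    def __str__(self) -> str:
        return (
            "Per-recording MAE:\n" + self.per_recording.to_string(index=False)
            + "\n\nCohort summary:\n" + self.summary.to_string()
        )


def _truth_window_means(per_second: np.ndarray, times: np.ndarray, window_s: int) -> np.ndarray:
    out = np.empty(times.size)
    for i, t in enumerate(times):
        e = int(round(t))
        out[i] = per_second[max(0, e - window_s) : e].mean()
    return out


def evaluate(
    pairs: list[tuple[VitalEstimate, GroundTruth]], window_s: int = 15
) -> EvalReport:
    """Per-recording and cohort MAE of both the raw and postprocessed
    streams, against window-mean ground truth."""
    rows = []
    for rid, (est, truth) in enumerate(pairs):
        n_sec = truth.rr_per_second.size
        keep = est.time_s <= n_sec
        if not np.any(keep):
            raise ValueError(f"recording {rid}: no time overlap between estimate and truth")
        t = est.time_s[keep]
        rr_t = _truth_window_means(truth.rr_per_second, t, window_s)
        hr_t = _truth_window_means(truth.hr_per_second, t, window_s)
        rows.append({
            "recording": rid,
            "rr_mae_raw": float(np.mean(np.abs(est.rr_raw[keep] - rr_t))),
            "hr_mae_raw": float(np.mean(np.abs(est.hr_raw[keep] - hr_t))),
            "rr_mae_final": float(np.mean(np.abs(est.rr_final[keep] - rr_t))),
            "hr_mae_final": float(np.mean(np.abs(est.hr_final[keep] - hr_t))),
        })
    per = pd.DataFrame(rows)
    cols = ["rr_mae_raw", "hr_mae_raw", "rr_mae_final", "hr_mae_final"]
    summary = pd.DataFrame({"mean": per[cols].mean(), "std": per[cols].std(ddof=0)})
    return EvalReport(per_recording=per, summary=summary)
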