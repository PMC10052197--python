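"""Physics-based IR-UWB radar simulator for vital-sign monitoring.

Renders synthetic slow-time x fast-time frame matrices for a single subject
whose chest wall moves with respiration and heartbeat:

    d(t) = d0 + m_r sin(2*pi*f_r*t) + m_h sin(2*pi*f_h*t)

Each frame is the superposition of the body echo ``Ad * p(tau - tau_d(t))``
with ``tau_d = 2 d(t) / c`` (two-way travel), static clutter echoes
``Ai * p(tau - tau_i)`` from walls and furniture, and white Gaussian noise.
The received pulse ``p`` carries the RF carrier, so sub-millimetre heartbeat
motion is visible through carrier phase (4*pi*fc*d/c) even though it is far
below the range-bin spacing.

All quantities are SI (metres, seconds, Hz) unless a name says otherwise
(rr in respirations/min, hr in beats/min).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.constants import c as SPEED_OF_LIGHT

__all__ = [
    "VitalScenario",
    "RadarConfig",
    "RadarFrameMatrix",
    "GroundTruth",
    "displacement_trace",
    "pulse_waveform",
    "render_recording",
    "make_cohort",
    "quadrature_distance",
    "COHORT_RANGES",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class VitalScenario:
    """Ground-truth kinematics of one recording.

    ``fr_trace`` / ``fh_trace`` may be scalars (constant rate) or per-second
    arrays; per-second traces are integrated into a cumulative phase so the
    instantaneous rate matches the labels.
    """

    duration: float = 600.0          # s
    d0: float = 1.0                  # nominal subject-radar distance, m
    mr: float = 5e-3                 # respiration displacement amplitude, m
    fr_trace: float | np.ndarray = 0.25   # Hz (scalar or per-second)
    mh: float = 4e-4                 # heartbeat displacement amplitude, m
    fh_trace: float | np.ndarray = 1.25   # Hz (scalar or per-second)
    breath_hold: tuple[float, float] | None = None   # (start, length) s
    motion_events: list[tuple[float, float, float]] = field(default_factory=list)
    #: echo-amplitude surge per metre of motion excursion: gross body
    #: movement exposes a larger, fluctuating reflecting surface, so a
    #: 0.05-0.3 m event boosts the received amplitude ~8-45x over vitals
    motion_amp_gain: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mr < 0:
            raise ValueError(f"mr (respiration amplitude) must be >= 0, got {self.mr}")
        if self.mh < 0:
            raise ValueError(f"mh (heartbeat amplitude) must be >= 0, got {self.mh}")
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        fr = np.asarray(self.fr_trace, dtype=float)
        if np.any(fr <= 0) or np.any(fr > 1.0):
            raise ValueError("fr_trace must lie within (0, 1.0] Hz")
        fh = np.asarray(self.fh_trace, dtype=float)
        if np.any(fh <= 0) or np.any(fh > 3.0):
            raise ValueError("fh_trace must lie within (0, 3.0] Hz")
        for ev in self.motion_events:
            start, length, _ = ev
            if not (0.0 <= start < self.duration) or length <= 0:
                raise ValueError(f"motion event {ev} outside [0, {self.duration})")


@dataclass
class RadarConfig:
    """Radar front-end parameters (defaults follow a Novelda-class module)."""

    frame_rate: float = 20.0             # slow-time frames / s
    fast_time_rate: float = 23.328e9     # fast-time samples / s
    center_frequency: float = 7.3e9      # Hz
    bandwidth: float = 1.5e9             # -10 dB two-sided spectral width, Hz
    range_window: tuple[float, float] = (0.3, 3.0)   # m
    body_amplitude: float = 1.0          # Ad
    #: the torso is an extended target: scatterers
    #: (offset m, gain, respiration weight, heartbeat weight) around d(t).
    #: Echo energy spreads over ~0.5 m of range as real body reflections do,
    #: and motion is differential — the abdomen carries the full breathing
    #: displacement with little heartbeat coupling, the upper chest /
    #: precordium a fraction of the breathing motion with the strongest
    #: heartbeat coupling (textbook respiratory mechanics). Gross-motion
    #: excursions move every scatterer. Length-2 tuples (offset, gain) are
    #: accepted and imply full coupling to both vitals.
    body_extent: tuple[tuple[float, ...], ...] = (
        (-0.24, 0.2, 1.0, 0.1),
        (-0.12, 0.5, 0.9, 0.3),
        (0.0, 1.0, 0.7, 0.6),
        (0.12, 0.5, 0.45, 1.0),
        (0.24, 0.2, 0.25, 0.8),
    )
    clutter: list[tuple[float, float]] = field(default_factory=list)  # (Ai, tau_i)
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        nyq_needed = 2.0 * (self.center_frequency + self.bandwidth / 2.0)
        if self.fast_time_rate <= nyq_needed:
            raise ValueError(
                f"fast_time_rate {self.fast_time_rate:g} must exceed "
                f"2*(fc + B/2) = {nyq_needed:g}"
            )
        lo, hi = self.range_window
        if not lo < hi:
            raise ValueError(f"range_window min must be < max, got {self.range_window}")
        tau_lo, tau_hi = 2.0 * lo / SPEED_OF_LIGHT, 2.0 * hi / SPEED_OF_LIGHT
        for amp, tau in self.clutter:
            if not (tau_lo <= tau <= tau_hi):
                raise ValueError(
                    f"clutter delay {tau:g} s outside the range window "
                    f"[{tau_lo:g}, {tau_hi:g}] s"
                )

    @property
    def Tf(self) -> float:
        return 1.0 / self.fast_time_rate

    @property
    def Ts(self) -> float:
        return 1.0 / self.frame_rate

    @property
    def bin_spacing_m(self) -> float:
        """Range per fast-time bin: c*Tf/2."""
        return SPEED_OF_LIGHT * self.Tf / 2.0

    def n_bins(self) -> int:
        lo, hi = self.range_window
        return int(math.floor((hi - lo) / self.bin_spacing_m)) + 1


@dataclass
class RadarFrameMatrix:
    """R[m, n]: M slow-time frames x N fast-time bins."""

    data: np.ndarray
    Ts: float
    Tf: float
    range_offset: float   # range of bin 0, m

    @property
    def frame_rate(self) -> float:
        return 1.0 / self.Ts

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_bins(self) -> int:
        return self.data.shape[1]

    def bin_range_m(self, n: int | np.ndarray) -> np.ndarray:
        return self.range_offset + np.asarray(n) * SPEED_OF_LIGHT * self.Tf / 2.0


@dataclass
class GroundTruth:
    rr_per_second: np.ndarray   # respirations / min, one per second
    hr_per_second: np.ndarray   # beats / min, one per second
    target_bin: int
    artifact_mask: np.ndarray   # per-frame boolean


# ---------------------------------------------------------------------------
# displacement model
# ---------------------------------------------------------------------------


def _phase(trace: float | np.ndarray, time_grid: np.ndarray) -> np.ndarray:
    """Sinusoid argument: 2*pi*f*t for a constant rate, otherwise the
    cumulative phase 2*pi * sum f dt (left Riemann on the given grid)."""
    trace = np.asarray(trace, dtype=float)
    if trace.ndim == 0:
        return 2.0 * np.pi * float(trace) * time_grid
    seconds = np.arange(trace.size, dtype=float)
    f = np.interp(time_grid, seconds, trace)
    dt = np.diff(time_grid)
    phase = np.empty_like(time_grid)
    phase[0] = 0.0
    phase[1:] = 2.0 * np.pi * np.cumsum(f[:-1] * dt)
    return phase


def _hold_envelope(scenario: VitalScenario, time_grid: np.ndarray) -> np.ndarray:
    """Respiration amplitude envelope: 1 -> 0 over 1 s into the hold, held at
    0, ramped back over the final second of the hold interval."""
    env = np.ones_like(time_grid)
    if scenario.breath_hold is None:
        return env
    start, length = scenario.breath_hold
    end = start + length
    ramp = min(1.0, length / 2.0)
    t = time_grid
    down = (t >= start) & (t < start + ramp)
    env[down] = 1.0 - (t[down] - start) / ramp
    env[(t >= start + ramp) & (t < end - ramp)] = 0.0
    up = (t >= end - ramp) & (t < end)
    env[up] = 1.0 - (end - t[up]) / ramp
    return env


def _motion_offset(scenario: VitalScenario, time_grid: np.ndarray) -> np.ndarray:
    """Smooth large-scale excursions: a sin^2 bump per motion event."""
    off = np.zeros_like(time_grid)
    for start, length, excursion in scenario.motion_events:
        inside = (time_grid >= start) & (time_grid < start + length)
        u = (time_grid[inside] - start) / length
        off[inside] += excursion * np.sin(np.pi * u) ** 2
    return off


def _vital_components(
    scenario: VitalScenario, time_grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(respiration, heartbeat, gross-motion) displacement components."""
    time_grid = np.asarray(time_grid, dtype=float)
    if time_grid.ndim != 1 or time_grid.size == 0:
        raise ValueError("time_grid must be a non-empty 1-D array")
    if time_grid.size > 1 and np.any(np.diff(time_grid) <= 0):
        raise ValueError("time_grid must be strictly increasing")
    resp = scenario.mr * np.sin(_phase(scenario.fr_trace, time_grid))
    resp *= _hold_envelope(scenario, time_grid)
    heart = scenario.mh * np.sin(_phase(scenario.fh_trace, time_grid))
    return resp, heart, _motion_offset(scenario, time_grid)


def displacement_trace(scenario: VitalScenario, time_grid: np.ndarray) -> np.ndarray:
    """Radial chest distance d(t) over an arbitrary strictly increasing grid."""
    resp, heart, motion = _vital_components(scenario, np.asarray(time_grid, dtype=float))
    return scenario.d0 + resp + heart + motion


# ---------------------------------------------------------------------------
# pulse and frame rendering
# ---------------------------------------------------------------------------


def _envelope_sigma(config: RadarConfig) -> float:
    # Gaussian envelope whose amplitude spectrum is -10 dB at +/- B/2:
    # exp(-(pi*B*sigma)^2 / 2) = 10^(-1/2)  =>  sigma = sqrt(ln 10)/(pi*B)
    return math.sqrt(math.log(10.0)) / (math.pi * config.bandwidth)


def pulse_waveform(config: RadarConfig, tau_grid: np.ndarray) -> np.ndarray:
    """Normalized received pulse p(tau): Gaussian envelope at the carrier.

    Peak magnitude is 1 at tau = 0; the -10 dB spectral width equals the
    configured bandwidth and the spectrum is centred on ``center_frequency``.
    """
    tau_grid = np.asarray(tau_grid, dtype=float)
    sigma = _envelope_sigma(config)
    lo, hi = config.range_window
    if 6.0 * sigma * SPEED_OF_LIGHT / 2.0 >= (hi - lo):
        raise ValueError("pulse envelope wider than the configured range window")
    env = np.exp(-0.5 * (tau_grid / sigma) ** 2)
    return env * np.cos(2.0 * np.pi * config.center_frequency * tau_grid)


def quadrature_distance(config: RadarConfig, near: float) -> float:
    """Nearest distance to ``near`` whose carrier round-trip phase
    4*pi*fc*d/c sits in quadrature (odd multiple of pi/2), maximising the
    first-order sensitivity of received amplitude to chest displacement."""
    lam = SPEED_OF_LIGHT / config.center_frequency
    k = round((4.0 * near / lam) - 0.5)
    return (k + 0.5) * lam / 4.0


def render_recording(
    scenario: VitalScenario, config: RadarConfig
) -> tuple[RadarFrameMatrix, GroundTruth]:
    """Render Eq.-style frames: R[m, n] = r(t = m*Ts, tau = n*Tf)."""
    M = int(math.floor(scenario.duration * config.frame_rate))
    if M < 1:
        raise ValueError("duration too short for a single frame")
    N = config.n_bins()
    lo, _ = config.range_window
    tau0 = 2.0 * lo / SPEED_OF_LIGHT
    tau_grid = tau0 + np.arange(N) * config.Tf

    t = np.arange(M) / config.frame_rate
    resp, heart, motion = _vital_components(scenario, t)
    scatterers = [
        (e[0], e[1], e[2] if len(e) > 2 else 1.0, e[3] if len(e) > 3 else 1.0)
        for e in config.body_extent
    ]
    margin = 3.0 * _envelope_sigma(config) * SPEED_OF_LIGHT / 2.0
    lo_m, hi_m = config.range_window
    sigma = _envelope_sigma(config)
    amp = config.body_amplitude * (1.0 + scenario.motion_amp_gain * motion)
    body = np.zeros((M, N))
    for offset, gain, w_r, w_h in scatterers:
        d_k = scenario.d0 + offset + w_r * resp + w_h * heart + motion
        bad = (d_k < lo_m + margin) | (d_k > hi_m - margin)
        if np.any(bad):
            i = int(np.argmax(bad))
            raise ValueError(
                f"displacement leaves the usable range window at t = {t[i]:.2f} s "
                f"(d = {d_k[i]:.3f} m, scatterer offset {offset:+.2f} m)"
            )
        tau_d = 2.0 * d_k / SPEED_OF_LIGHT
        arg = tau_grid[None, :] - tau_d[:, None]      # (M, N)
        body += (gain * amp)[:, None] * (
            np.exp(-0.5 * (arg / sigma) ** 2)
            * np.cos(2.0 * np.pi * config.center_frequency * arg)
        )

    static = np.zeros(N)
    for amp, tau_i in config.clutter:
        static += amp * pulse_waveform(config, tau_grid - tau_i)

    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, config.seed]))
    data = body + static[None, :]
    if config.noise_sd > 0:
        data = data + rng.normal(0.0, config.noise_sd, size=(M, N))

    frames = RadarFrameMatrix(
        data=data, Ts=config.Ts, Tf=config.Tf, range_offset=lo
    )

    n_sec = int(math.floor(scenario.duration))
    sec = np.arange(n_sec, dtype=float)
    fr = np.asarray(scenario.fr_trace, dtype=float)
    fh = np.asarray(scenario.fh_trace, dtype=float)
    rr = 60.0 * (np.full(n_sec, float(fr)) if fr.ndim == 0 else np.interp(sec, np.arange(fr.size), fr))
    hr = 60.0 * (np.full(n_sec, float(fh)) if fh.ndim == 0 else np.interp(sec, np.arange(fh.size), fh))
    # breathing truly stops during a hold: the label says so
    hold_env_sec = _hold_envelope(scenario, sec + 0.5)
    rr = np.where(hold_env_sec < 0.5, 0.0, rr)

    target_bin = int(round((scenario.d0 - lo) / config.bin_spacing_m))
    mask = np.zeros(M, dtype=bool)
    for start, length, _ in scenario.motion_events:
        mask |= (t >= start) & (t < start + length)

    truth = GroundTruth(
        rr_per_second=rr, hr_per_second=hr, target_bin=target_bin, artifact_mask=mask
    )
    return frames, truth


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

#: Default per-recording sampling ranges. Displacement amplitudes follow the
#: physiological span of chest-wall motion (breathing a few mm, heartbeat a
#: few tenths of a mm); rates cover the healthy resting bands 12-20 RPM and
#: 60-100 BPM. ``rr_walk_sd`` / ``hr_walk_sd`` bound the per-second drift of
#: the rate traces. A 15-20 s breath hold shortly after the start mimics the
#: cross-device synchronisation manoeuvre used in sleep studies.
COHORT_RANGES: dict = {
    "duration": 600.0,
    "d0": (0.7, 2.0),
    "mr": (4e-3, 7e-3),
    "mh": (3e-4, 5e-4),
    "rr_rpm": (12.0, 20.0),
    "hr_bpm": (60.0, 100.0),
    "rr_walk_sd": 0.15,
    "hr_walk_sd": 0.4,
    "breath_hold": (2.0, (15.0, 20.0)),   # start, (min len, max len); None disables
    "motion_events": None,                # or (n_min, n_max, exc_min, exc_max)
    "n_clutter": (2, 4),
    "clutter_amplitude": (0.5, 2.0),
    "noise_sd": 0.05,
}


def _bounded_walk(
    rng: np.random.Generator, n: int, lo: float, hi: float, step_sd: float
) -> np.ndarray:
    """Smooth per-second rate trace: reflected Gaussian random walk with
    steps clipped to 3*step_sd, so the per-second change is bounded."""
    x = np.empty(n)
    x[0] = rng.uniform(lo, hi)
    steps = np.clip(rng.normal(0.0, step_sd, n - 1), -3 * step_sd, 3 * step_sd)
    for i in range(1, n):
        v = x[i - 1] + steps[i - 1]
        if v < lo:
            v = lo + (lo - v)
        elif v > hi:
            v = hi - (v - hi)
        x[i] = min(max(v, lo), hi)
    return x


def make_cohort(
    n_recordings: int,
    parameter_ranges: dict | None = None,
    seed: int = 0,
    config: RadarConfig | None = None,
) -> list[tuple[RadarFrameMatrix, GroundTruth]]:
    """Sample ``n_recordings`` independent subjects and render them.

    ``parameter_ranges`` overrides entries of :data:`COHORT_RANGES`.
    Deterministic under ``seed``.
    """
    if n_recordings < 1:
        raise ValueError(f"n_recordings must be >= 1, got {n_recordings}")
    ranges = dict(COHORT_RANGES)
    if parameter_ranges:
        ranges.update(parameter_ranges)
    base = config if config is not None else RadarConfig()

    ss = np.random.SeedSequence(seed)
    out = []
    for child in ss.spawn(n_recordings):
        rng = np.random.default_rng(child)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        duration = float(ranges["duration"])
        n_sec = int(math.floor(duration))
        rr = _bounded_walk(rng, n_sec, *ranges["rr_rpm"], ranges["rr_walk_sd"])
        hr = _bounded_walk(rng, n_sec, *ranges["hr_bpm"], ranges["hr_walk_sd"])

        hold = None
        if ranges["breath_hold"] is not None:
            start, (lmin, lmax) = ranges["breath_hold"]
            hold = (float(start), float(rng.uniform(lmin, lmax)))

        events: list[tuple[float, float, float]] = []
        if ranges["motion_events"] is not None:
            n_min, n_max, exc_min, exc_max = ranges["motion_events"]
            for _ in range(int(rng.integers(n_min, n_max + 1))):
                length = float(rng.uniform(2.0, min(10.0, duration / 6)))
                lo = min(60.0, 0.3 * duration)
                hi = max(lo + 1.0, duration - length - 2.0)
                start = float(rng.uniform(lo, hi))
                events.append((start, length, float(rng.uniform(exc_min, exc_max))))

        scenario = VitalScenario(
            duration=duration,
            d0=float(rng.uniform(*ranges["d0"])),
            mr=float(rng.uniform(*ranges["mr"])),
            fr_trace=rr / 60.0,
            mh=float(rng.uniform(*ranges["mh"])),
            fh_trace=hr / 60.0,
            breath_hold=hold,
            motion_events=events,
            seed=sub_seed,
        )

        n_cl = int(rng.integers(*ranges["n_clutter"]))
        lo, hi = base.range_window
        taus = rng.uniform(2 * lo / SPEED_OF_LIGHT, 2 * hi / SPEED_OF_LIGHT, n_cl)
        amps = rng.uniform(*ranges["clutter_amplitude"], n_cl)
        cfg = replace(
            base,
            clutter=list(zip(amps.tolist(), taus.tolist())),
            noise_sd=float(ranges["noise_sd"]),
            seed=sub_seed + 1,
        )
        out.append(render_recording(scenario, cfg))
    return out
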