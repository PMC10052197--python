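# Methods

`radarvitals` estimates per-second respiration rate (RR, respirations/min)
and heart rate (HR, beats/min) from impulse-radio ultra-wideband (IR-UWB)
radar recordings of a sleeping subject, and ships a physics-based simulator
so the whole chain is testable end to end without clinical data. This note
records the models, the parameters that matter, and the design choices made
where more than one reasonable option existed.

## Signal model and simulator

Chest kinematics follow the standard two-sinusoid displacement law

    d(t) = d0 + m_r sin(2π f_r t) + m_h sin(2π f_h t),

with `d0` the nominal subject–radar distance, `m_r`/`f_r` the respiration
displacement amplitude and frequency, and `m_h`/`f_h` the heartbeat pair.
When the rates vary over time (they do, per second, in every simulated
recording) the sinusoid argument is the cumulative phase `2π ∫ f dt`, so the
instantaneous frequency always matches the per-second ground-truth labels.

The received frame is a superposition of echoes

    r(t, τ) = A(t) Σ_k g_k p(τ − 2(d(t)+o_k)/c) + Σ_i A_i p(τ − τ_i) + n(t, τ),

sampled into a slow-time × fast-time matrix `R[m, n] = r(mTs, nTf)` with
`Ts = 1/20 s` (frame rate 20 fps) and `Tf = 1/23.328 GHz`. The pulse `p` is
a Gaussian envelope on a 7.3 GHz carrier whose −10 dB spectral width equals
the 1.5 GHz bandwidth. The carrier matters: the range-bin spacing is
`c·Tf/2 ≈ 6.4 mm`, far coarser than a 0.3–0.5 mm heartbeat, so cardiac
motion is only visible through the carrier phase `4π f_c d(t)/c`
(≈ 306 rad/m — a half-millimetre of motion is ≈ 0.15 rad of phase, which
amplitude-modulates the sampled echo).

Simulator choices that are *choices*, not physics:

- **Extended target with differential motion.** The torso is five
  scatterers at offsets `±0.24, ±0.12, 0 m` with gains
  `0.2, 0.5, 1, 0.5, 0.2` and per-scatterer coupling weights
  (respiration, heartbeat) running from `(1.0, 0.1)` at the abdomen end to
  `(0.25, 0.8)` at the upper chest. Two facts of real bodies motivate
  this. First, a point target has a carrier-phase null problem — at
  unlucky `d0` the first-order amplitude response vanishes; spreading
  energy over ~0.5 m of range puts some bin at a favourable phase.
  Second, motion is not rigid: the abdomen carries the full breathing
  displacement with little cardiac coupling, while the precordium moves a
  fraction of the breathing amplitude and the most heartbeat. Coupling
  every scatterer fully to both vitals would suppress the heart line by
  `J0(4π f_c m_r / c)` at *every* range cell — at `m_r ≳ 5.5 mm` a ~10×
  attenuation no real subject exhibits, because no one breathes 6 mm at
  the precordium. Gross-motion excursions move all scatterers rigidly.
- **Motion artifacts.** A motion event is a smooth `sin²` excursion
  (default 0.05–0.2 m over 2–10 s) *plus* an echo-amplitude surge of
  150 × excursion (so 8–30× the resting echo). Gross movement exposes
  larger, fluctuating reflecting surfaces (arms, trunk); without the surge
  a z-scored channel shows almost no artifact signature, which matches
  neither bedside radar recordings nor the adaptive-threshold detector's
  premise.
- **Breath hold.** Sleep-lab protocols begin with a 15–20 s voluntary
  breath hold for cross-device synchronization. The respiration term ramps
  to zero over 1 s, holds, and ramps back; ground-truth RR is set to 0
  during the hold (the breathing truly stops — labels stay honest).
- **Amplitudes.** `m_r ∈ [4, 7] mm`, `m_h ∈ [0.3, 0.5] mm` (physiological
  chest-wall ranges), body echo amplitude 1, clutter reflectors 2–4 per
  scene with amplitudes 0.5–2, additive white noise σ = 0.05. None of these
  are measurements; they are defaults chosen to put the heart line an order
  of magnitude below breathing, which is the regime the method must handle.
- **Rate trajectories.** Per-second RR and HR are reflected Gaussian random
  walks inside [12, 20] RPM and [60, 100] BPM with steps clipped at
  3σ (σ = 0.15 RPM/s, 0.4 BPM/s), giving smooth, bounded per-second drift.

What the simulator does *not* emulate: non-sinusoidal breathing waveforms,
apnea/hypopnea events, multiple people, antenna patterns, posture changes,
blankets, or RF multipath beyond static clutter. Passing tests on synthetic
cohorts therefore demonstrates that the pipeline recovers rates from
carrier-phase-modulated echoes under clutter, noise and motion — not that
it reaches any particular accuracy on clinical recordings.

## Preprocessing

- **Clutter removal**: causal running mean over slow time, span 20 s per
  fast-time bin, subtracted from the current frame. Static echoes map to
  (exactly, after warm-up) zero; the 0.1–5 Hz vital band passes with < 5%
  attenuation. The span is a config knob; 20 s keeps the high-pass corner
  of this implicit filter well below the slowest breathing of interest.
- **Localization**: the fast-time bin with the largest slow-time standard
  deviation over the whole recording (chest motion makes the subject's
  range the most variable one). Ties break to the nearer bin. A sliding
  variant (30 s window, 1 s hop, 3-bin hysteresis) exists for streaming
  scenarios where the subject may move.
- **Channel**: the selected bin's slow-time series, z-scored over the
  recording. Artifact detection runs on this unfiltered channel; the
  band-passed copy feeds segmentation. (The processing order between
  filtering and artifact detection is ambiguous in the field; detecting on
  the unfiltered channel keeps low-frequency motion energy visible to the
  detector.)
- **Band-pass**: fifth-order Butterworth high-pass at 0.1 Hz followed by
  fifth-order low-pass at 5 Hz, causal (direct-form SOS) by default to
  honour the real-time contract; a zero-phase offline mode exists.

## Artifact detection

The rectified channel |x| is smoothed with a Savitzky–Golay filter
(polynomial order 2, 21-sample frame ≈ 1 s at 20 fps) — long enough to
flatten breathing oscillation, short enough to preserve burst peaks. The
adaptive threshold is the *sum* of three causal moving averages of this
envelope with 10, 30 and 100 s windows (growing windows during warm-up), so
short jerks and long restless periods both register; a frame is flagged
when envelope > threshold. A 15 s segment is artifact-flagged when more
than 10% of its frames are flagged (the fraction is configurable).

## Features

The band-passed channel is segmented into 15 s windows hopped by 1 s
(300 samples). Each window is paired with a 123 × 300 scalogram: the
magnitude of a continuous wavelet transform using generalized Morse
wavelets (γ = 3, β = 20 — a symmetric, exactly analytic default), evaluated
at 123 log-spaced center frequencies in (0.05, 5] Hz via an FFT filter
bank. The 0.05 Hz floor sits below the 0.1 Hz high-pass corner; a true
0 Hz bound is unattainable for any wavelet. Rows are ordered low→high
frequency. Wavelets at the lowest rows outlast the window, so those rows
are edge-dominated — inherent to a 15 s window, and identical for training
and inference. Per-segment labels are the window-mean ground-truth rates;
for real reference signals (nasal-cannula airflow, ECG) the peak-based
rate helper (60 / mean inter-peak interval) produces the same labels.

Datasets are split at the recording level (a seeded permutation or an
explicit disjoint assignment). The training split drops artifact-flagged
segments; validation and test keep everything, artifacts included, because
streaming inference will see them. The training split may be thinned with
a coarser stride (adjacent 1 s-hop windows overlap by 93% and carry almost
identical labels).

## Model

Two convolutional branches — 1D on the window, 2D on the scalogram — each
stack `n` blocks of [conv (kernel 3, stride 2, valid) → batch norm → ReLU →
max-pool (kernel 2, stride 1)], flatten, and map to 10 units with ReLU;
the concatenated branch outputs feed one linear layer emitting (RR, HR).
The stride/padding/pooling combination is the unique one reproducing the
reference feature-map chain (300 → 149 → 148 → 73 → 72 → 35 → 34;
123×300 → 61×149 → … → 12×34); it is unit-tested against every printed
shape and per-layer parameter count, and the full-model figure (962,878
parameters for the 3-layer 128-filter dual configuration) is the per-layer
sum. The network, backpropagation and Adam are implemented in NumPy
(`radarvitals.nn`), channel-last with im2col convolutions.

Two standardizations happen inside `train()` and travel with the
checkpoint:

- **Labels** are z-scored with train-set statistics (MAE on raw RPM/BPM
  scales would let the ~80 BPM heart target dominate the shared loss and
  makes Adam's sign-driven steps drift the output bias for thousands of
  steps). Predictions are mapped back to physical units.
- **Inputs**: the 1D window globally, the scalogram per frequency row.
  Respiration rows carry orders of magnitude more energy than the heart
  band; without row-wise scaling the heart line is numerically invisible
  to the convolutions (a band-peak readout oracle improves from ~30 to
  ~9 BPM MAE with this scaling alone).

Training: Adam (β = 0.9/0.999), MAE loss, at most 50 epochs, early stop
after 7 epochs without validation improvement, weights reverted to the
best epoch. The learning rate comes from an exponential sweep from 1e-5
(one Adam step per probe batch); the sweep stops when the smoothed loss
exceeds 1.3× its best value — MAE saturates rather than explodes, so the
classical 4× criterion never fires — and the rate one decade below the
stop point is returned (max probed/10 if it never stops). Batch size
defaults to 256 (64 is used in the shipped experiments; on one CPU the
smaller batch gives more frequent updates at identical throughput).
Hyperparameter search covers layers {1,2,3} × filters {32,64,128} ×
branches {1D, 2D, 1D+2D} × window {5,10,15} s = 81 configurations,
selected by the sum of validation RR and HR MAE. Shorter-window
configurations read the most recent seconds of each 15 s segment.

## Streaming pipeline and postprocessing

Whole-recording steps (clutter removal, localization, channel z-score) run
once; the channel then flows through a stateful causal estimator —
band-pass filter state, Savitzky–Golay tail, moving-average accumulators,
open segment window, postprocessing buffers — emitting one (RR, HR) pair
per second after the first 15 s window. Chunked feeding is bit-identical
to one-shot processing; latency is one window plus half the envelope
filter (≈ 0.5 s).

Postprocessing keeps a rolling buffer of the last five *clean* per-second
estimates for each vital. During artifact-flagged seconds the output is
the buffer mean and the buffer is frozen (ingesting buffer means would let
the held value drift); outside artifacts the raw estimate passes through
and refills the buffer. If an artifact occurs before any clean estimate
exists, the raw value is passed (the only information available).
Evaluation reports per-recording MAE for both raw and postprocessed
streams against window-mean ground truth, plus cohort mean ± SD.

## Problem sizes in the shipped experiments

The packaged acceptance study trains the 1D+2D model (2 conv layers,
32 filters, 15 s window) on a clean cohort — 10 training, 2 validation and
3 test recordings of 10 minutes, no motion events or breath holds,
noise σ = 0.05 — with a 5 s training/validation stride, batch 64, up to
10 epochs at a fixed learning rate of 1e-4 (picked by a coarse stability
sweep during development; the LR finder remains the library default when
no rate is given). Test recordings are evaluated at the native 1 s stride. The postprocessing study reuses that
model on three recordings with injected motion events. These sizes are the
package's desk-scale study design; the layer/filter/window grids and the
training recipe accept the full-scale settings unchanged.

## Known limitations

- The simulator's breathing is sinusoidal; real respiratory waveforms are
  asymmetric with their own harmonics, and apnea/hypopnea is absent.
- HR estimation degrades when the heart line transits a respiration
  carrier harmonic (k·f_r ≈ f_h) — physically inherent; joint RR+HR
  estimation mitigates but does not remove it.
- Cohort draws combining large breathing displacement with a small
  heartbeat amplitude (m_r near 7 mm with m_h near 0.3 mm) can leave a
  recording whose heart band is barely readable even for a band-peak
  oracle; with only three held-out recordings in the desk-scale study, a
  single such draw moves the cohort HR MAE by several BPM, so cohort-level
  results vary noticeably with the simulation seed.
- The whole-recording STD localizer assumes one mostly stationary subject.
- NumPy training is single-threaded; the full 81-point grid at full
  cohort scale is a long batch job, not an interactive run.
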