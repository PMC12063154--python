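"""Synthetic photometry sessions with ground truth.

Emulates the three in vivo paradigms the analysis chain is built for —
Pavlovian fear conditioning (30 s tone, foot shock in the last 2 s), Pavlovian
reward (5 s tone predicting a sugar pellet, consumption jittered after
delivery), and optogenetic pulse-train stimulation — on top of a common signal
model:

    ch465(t) = bleach465(t) * (1 + c465 * a(t) + s(t)) + noise
    ch405(t) = bleach405(t) * (1 + c405 * a(t))        + noise

where ``s(t)`` is a sum of event-locked difference-of-exponential sensor
transients (fractional dF/F), ``a(t)`` is a shared low-pass-filtered Gaussian
artifact process (unit variance), bleach is a double exponential plus constant,
and the additive measurement noise is i.i.d. Gaussian per channel.  With the
artifact and noise off and a flat bleach, the detrended dF/F equals
``100 * s(t)`` exactly — the identity every recovery test leans on.

Every generator is a pure function of its seed: equal seeds give bit-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d

from .session import (
    EventTable,
    MovementTrace,
    RawPhotometrySession,
    TimeSeries,
    TrackTrace,
)

__all__ = [
    "TransientKernel",
    "BleachModel",
    "ArtifactModel",
    "SessionDesign",
    "GroundTruth",
    "ConfigurationError",
    "fear_design",
    "reward_design",
    "opto_design",
    "generate_fear_session",
    "generate_reward_session",
    "generate_opto_session",
    "generate_behavior_streams",
]


class ConfigurationError(ValueError):
    """Design parameters are inconsistent with the requested paradigm."""


@dataclass(frozen=True)
class TransientKernel:
    """Difference-of-exponentials sensor transient, peak-normalized.

    ``amplitude`` is the peak fractional dF/F (0.05 = a 5% transient), so
    parameter-recovery tests compare measured peaks to it directly.  Defaults
    approximate fast GCaMP kinetics (~100 ms rise, ~1 s decay).
    """

    tau_rise: float = 0.1
    tau_decay: float = 1.0
    amplitude: float = 0.05

    def __post_init__(self) -> None:
        if not self.tau_rise > 0:
            raise ConfigurationError("tau_rise must be positive")
        if not self.tau_decay > self.tau_rise:
            raise ConfigurationError("tau_decay must exceed tau_rise")
        if self.amplitude < 0:
            raise ConfigurationError("amplitude must be non-negative")

    @property
    def peak_time_s(self) -> float:
        """Time of the kernel maximum: (τr τd / (τd − τr)) · ln(τd / τr)."""
        r, d = self.tau_rise, self.tau_decay
        return r * d / (d - r) * math.log(d / r)

    def evaluate(self, t: np.ndarray, amplitude: float | None = None) -> np.ndarray:
        """Kernel values at times ``t`` (zero for t < 0), peak = amplitude."""
        a = self.amplitude if amplitude is None else amplitude
        t = np.asarray(t, dtype=float)
        tt = np.maximum(t, 0.0)
        raw = np.where(t >= 0, np.exp(-tt / self.tau_decay) - np.exp(-tt / self.tau_rise), 0.0)
        tp = self.peak_time_s
        peak = math.exp(-tp / self.tau_decay) - math.exp(-tp / self.tau_rise)
        return a * raw / peak


@dataclass(frozen=True)
class BleachModel:
    """Double-exponential-plus-constant photobleaching baseline, in a.u.

    Defaults give a baseline starting near 100 a.u. that loses ~30% over tens
    of minutes, a typical session-scale bleach for a chronically implanted
    fiber.  Magnitudes are a package default, not a measured property.
    """

    A1: float = 10.0
    tau1_s: float = 120.0
    A2: float = 20.0
    tau2_s: float = 1200.0
    C: float = 70.0

    def __post_init__(self) -> None:
        if min(self.A1, self.A2, self.C) < 0:
            raise ConfigurationError("bleach amplitudes must be non-negative")
        if min(self.tau1_s, self.tau2_s) <= 0:
            raise ConfigurationError("bleach time constants must be positive")
        if self.A1 + self.A2 + self.C <= 0:
            raise ConfigurationError("bleach baseline must be strictly positive")

    def baseline(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.A1 * np.exp(-t / self.tau1_s) + self.A2 * np.exp(-t / self.tau2_s) + self.C

    def scaled(self, gain: float) -> "BleachModel":
        return replace(self, A1=self.A1 * gain, A2=self.A2 * gain, C=self.C * gain)


FLAT_BLEACH = BleachModel(A1=0.0, tau1_s=1.0, A2=0.0, tau2_s=1.0, C=1.0)


@dataclass(frozen=True)
class ArtifactModel:
    """Shared low-frequency artifact process (motion / fiber bending).

    A unit-variance Gaussian process low-passed at ``bandwidth_hz``, entering
    both channels multiplicatively with independent gains — the minimal
    structure the isosbestic regression is designed to remove.
    """

    coupling_465: float = 0.0
    coupling_405: float = 0.0
    bandwidth_hz: float = 0.5

    def __post_init__(self) -> None:
        if not self.bandwidth_hz > 0:
            raise ConfigurationError("bandwidth_hz must be positive")

    def sample(self, n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
        # Gaussian-smoothed white noise generated at a low intermediate rate
        # (circular smoothing keeps the process stationary with no filter edge
        # transients) and linearly interpolated onto the session grid.  The
        # unit-variance draw is softly saturated at +-3.2 sigma so the
        # multiplicative term (1 + c * a) stays positive for couplings <= 0.3;
        # only the extreme tail is affected.
        fs_lo = 40.0 * self.bandwidth_hz
        n_lo = max(int(math.ceil(n / fs * fs_lo)) + 2, 32)
        white = rng.standard_normal(n_lo)
        # -3 dB point of the Gaussian smoother at bandwidth_hz
        sigma_samples = math.sqrt(math.log(2.0)) / (2.0 * math.pi * self.bandwidth_hz) * fs_lo
        x_lo = gaussian_filter1d(white, sigma_samples, mode="wrap")
        sd = x_lo.std()
        if sd > 0:
            x_lo = x_lo / sd
        x_lo = 3.2 * np.tanh(x_lo / 3.2)
        t_lo = np.arange(n_lo) / fs_lo
        return np.interp(np.arange(n) / fs, t_lo, x_lo)


@dataclass(frozen=True)
class SessionDesign:
    """Trial structure of a synthetic session.

    Fear: ``n_trials`` tones of ``cue_s`` seconds with the unconditioned
    stimulus at ``us_delay_s`` after tone onset; inter-onset intervals
    quasi-random (uniform on [0.5, 1.5] x ``iti_s``).  Reward: ``cue_s`` tone
    then pellet delivery, consumption jittered.  Opto: fixed-ITI pulse-train
    blocks over ``pulse_conditions``.
    """

    paradigm: str
    n_trials: int = 6
    iti_s: float = 180.0
    cue_s: float = 30.0
    us_delay_s: float = 28.0
    fs: float = 1017.3
    seed: int = 0
    video_fs: float = 30.0
    # reward-specific
    n_omission: int = 0
    n_unpredicted: int = 0
    consumption_jitter_mean_s: float = 1.0
    consumption_jitter_law: str = "exponential"  # or "constant"
    # opto-specific
    pulse_conditions: tuple[int, ...] = (2, 5, 10, 20, 40)
    trials_per_condition: int = 10
    opto_iti_s: float = 45.0
    pulse_rate_hz: float = 20.0
    # acquisition-chain emulation: 6th-order low-pass applied to both channels
    # (zero-phase, so injected event timing stays aligned); None disables
    lowpass_hz: float | None = 6.0

    def __post_init__(self) -> None:
        if self.paradigm not in ("fear", "reward", "opto"):
            raise ConfigurationError(f"unknown paradigm '{self.paradigm}'")
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be >= 1")
        if self.paradigm in ("fear", "reward") and not self.iti_s > self.cue_s:
            raise ConfigurationError("iti_s must exceed cue_s")


def fear_design(n_trials: int = 6, iti_s: float = 180.0, seed: int = 0, **kw) -> SessionDesign:
    """6 trials of a 30 s tone with the shock in the last 2 s, mean ITI 3 min."""
    return SessionDesign(paradigm="fear", n_trials=n_trials, iti_s=iti_s,
                         cue_s=30.0, us_delay_s=28.0, seed=seed, **kw)


def reward_design(n_trials: int = 30, iti_s: float = 60.0, seed: int = 0, **kw) -> SessionDesign:
    """30 trials of a 5 s tone predicting pellet delivery, mean ITI 60 s."""
    return SessionDesign(paradigm="reward", n_trials=n_trials, iti_s=iti_s,
                         cue_s=5.0, us_delay_s=5.0, seed=seed, **kw)


def opto_design(seed: int = 0, **kw) -> SessionDesign:
    """2/5/10/20/40-pulse trains at 20 Hz, 10 trials per condition, 45 s ITI."""
    return SessionDesign(paradigm="opto", n_trials=1, seed=seed, **kw)


@dataclass
class GroundTruth:
    """Everything injected into a synthetic session, for recovery tests."""

    transient_times_s: np.ndarray
    amplitudes: np.ndarray
    bleach_465: BleachModel
    bleach_405: BleachModel
    artifact: TimeSeries
    noise_sigma: tuple[float, float]  # per-channel additive sd, a.u.
    movement_lag_s: float | None = None
    movement_gain: float | None = None
    consumption_times_s: np.ndarray | None = None
    omission_trials: np.ndarray | None = None
    unpredicted_trials: np.ndarray | None = None
    pulse_counts: np.ndarray | None = None
    conditions: np.ndarray | None = None


# Default additive noise: the net dF/F noise at the native rate is 1% of
# baseline (SNR ~5 against the default 5% transient before downsampling).
# Both channels contribute to dF/F noise -- the control channel's noise is
# amplified by the regression slope -- so each channel carries
# DEFAULT_NOISE_FRAC / sqrt(2) of its own baseline, which combine to ~1%.
DEFAULT_NOISE_FRAC = 0.01

# Movement-trace coupling defaults (percent pixels changed per % dF/F).
DEFAULT_MOVEMENT_GAIN = 0.8
DEFAULT_MOVEMENT_BASELINE = 1.0
DEFAULT_MOVEMENT_NOISE = 0.3


def _quasi_random_onsets(n: int, mean_interval_s: float, start_s: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Onsets with inter-onset intervals uniform on [0.5, 1.5] x mean."""
    intervals = rng.uniform(0.5 * mean_interval_s, 1.5 * mean_interval_s, size=n - 1) if n > 1 else np.array([])
    return start_s + np.concatenate([[0.0], np.cumsum(intervals)])

def _transient_sum(t: np.ndarray, times: np.ndarray, amps: np.ndarray,
                   kernel: TransientKernel, fs: float) -> np.ndarray:
    """Sum of kernels at event times, added on a finite support window."""
    s = np.zeros_like(t)
    # 30 decay constants keeps the truncated tail below 1e-13 of the peak
    support = int(round((kernel.peak_time_s + 30 * kernel.tau_decay) * fs))
    for t_ev, a in zip(times, amps):
        i0 = max(int(math.ceil((t_ev - t[0]) * fs - 1e-9)), 0)
        i1 = min(i0 + support, len(t))
        if i0 >= len(t):
            continue
        s[i0:i1] += kernel.evaluate(t[i0:i1] - t_ev, amplitude=a)
    return s


def _channel_sigmas(noise_sigma, bleach465: BleachModel, bleach405: BleachModel):
    """Per-channel additive noise sd in a.u.

    ``None`` applies the default: each channel carries
    DEFAULT_NOISE_FRAC / sqrt(2) of its own t=0 baseline so the two combine
    to ~1% net dF/F noise.  A scalar is used verbatim for both channels.
    """
    if noise_sigma is None:
        f = DEFAULT_NOISE_FRAC / math.sqrt(2.0)
        zero = np.zeros(1)
        return f * float(bleach465.baseline(zero)[0]), f * float(bleach405.baseline(zero)[0])
    return float(noise_sigma), float(noise_sigma)


def _assemble_channels(t, s, artifact_trace, bleach465, bleach405, art: ArtifactModel,
                       sigmas, rng, fs, t0=0.0, lowpass_hz: float | None = 6.0):
    b465 = bleach465.baseline(t)
    b405 = bleach405.baseline(t)
    if (b465 <= 0).any() or (b405 <= 0).any():
        raise ConfigurationError("bleach baseline not strictly positive over session")
    a = artifact_trace
    s465, s405 = sigmas
    ch465 = b465 * (1.0 + art.coupling_465 * a + s) + s465 * rng.standard_normal(len(t))
    ch405 = b405 * (1.0 + art.coupling_405 * a) + s405 * rng.standard_normal(len(t))
    if lowpass_hz is not None and len(t) > 50:
        # the acquisition chain band-limits everything it digitizes; applied
        # zero-phase so injected event timing is preserved for recovery tests
        sos = sps.butter(6, lowpass_hz / (fs / 2), btype="low", output="sos")
        ch465 = sps.sosfiltfilt(sos, ch465)
        ch405 = sps.sosfiltfilt(sos, ch405)
    return (
        TimeSeries(ch465, fs, t0, unit="a.u."),
        TimeSeries(ch405, fs, t0, unit="a.u."),
    )


def _movement_from_drive(t_video, s_raw, fs_raw, lag_s, gain, baseline, noise_sd,
                         rng, video_fs) -> MovementTrace:
    # movement follows the neural signal by lag_s (positive lag = signal leads)
    idx = np.clip(np.round((t_video - lag_s) * fs_raw).astype(int), 0, len(s_raw) - 1)
    drive = 100.0 * s_raw[idx]  # % dF/F units
    noise = gaussian_filter1d(rng.standard_normal(len(t_video)), sigma=0.2 * video_fs)
    vals = np.clip(baseline + gain * drive + noise_sd * noise / max(noise.std(), 1e-12), 0.0, 100.0)
    return MovementTrace(vals, video_fs)


def generate_fear_session(
    design: SessionDesign,
    kernel: TransientKernel = TransientKernel(),
    bleach: BleachModel = BleachModel(),
    artifact: ArtifactModel = ArtifactModel(),
    *,
    noise_sigma: float | None = None,
    bleach_405_gain: float = 0.6,
    movement_lag_s: float = 0.0,
    movement_gain: float = DEFAULT_MOVEMENT_GAIN,
) -> tuple[RawPhotometrySession, MovementTrace, GroundTruth]:
    """Fear-conditioning session: tones, shocks, shock-locked transients and a
    movement trace coupled to the transient drive at ``movement_lag_s``."""
    if design.paradigm != "fear":
        raise ConfigurationError("design paradigm must be 'fear'")
    rng = np.random.default_rng(design.seed)
    tone_onsets = _quasi_random_onsets(design.n_trials, design.iti_s, 30.0, rng)
    shock_onsets = tone_onsets + design.us_delay_s
    duration = shock_onsets[-1] + 2.0 + 30.0
    n = int(round(duration * design.fs))
    t = np.arange(n) / design.fs

    amps = np.full(design.n_trials, kernel.amplitude)
    s = _transient_sum(t, shock_onsets, amps, kernel, design.fs)
    a = artifact.sample(n, design.fs, rng)
    bleach405 = bleach.scaled(bleach_405_gain)
    sigmas = _channel_sigmas(noise_sigma, bleach, bleach405)
    ch465, ch405 = _assemble_channels(t, s, a, bleach, bleach405, artifact, sigmas, rng,
                                      design.fs, lowpass_hz=design.lowpass_hz)

    events = EventTable.from_records(
        [("tone", on, on + design.cue_s) for on in tone_onsets]
        + [("shock", on, on + 2.0) for on in shock_onsets]
    )
    session = RawPhotometrySession(ch465, ch405, events,
                                   meta={"subject": f"sim{design.seed}", "sensor": "GCaMP8m",
                                         "paradigm": "fear", "fs": design.fs})
    n_video = int(round(duration * design.video_fs))
    t_video = np.arange(n_video) / design.video_fs
    movement = _movement_from_drive(t_video, s, design.fs, movement_lag_s, movement_gain,
                                    DEFAULT_MOVEMENT_BASELINE, DEFAULT_MOVEMENT_NOISE, rng,
                                    design.video_fs)
    gt = GroundTruth(shock_onsets, amps, bleach, bleach405,
                     TimeSeries(a, design.fs, unit="z"), sigmas,
                     movement_lag_s=movement_lag_s, movement_gain=movement_gain)
    return session, movement, gt


def generate_reward_session(
    design: SessionDesign,
    kernel: TransientKernel = TransientKernel(),
    bleach: BleachModel = BleachModel(),
    artifact: ArtifactModel = ArtifactModel(),
    *,
    noise_sigma: float | None = None,
    bleach_405_gain: float = 0.6,
) -> tuple[RawPhotometrySession, GroundTruth]:
    """Reward session: cue -> pellet delivery -> jittered consumption, with
    transients locked to consumption (not delivery).  Supports omission and
    unpredicted-delivery trials."""
    if design.paradigm != "reward":
        raise ConfigurationError("design paradigm must be 'reward'")
    if design.n_omission + design.n_unpredicted > design.n_trials:
        raise ConfigurationError("omission + unpredicted trials exceed n_trials")
    rng = np.random.default_rng(design.seed)
    cue_onsets = _quasi_random_onsets(design.n_trials, design.iti_s, 30.0, rng)
    delivery = cue_onsets + design.cue_s

    idx = rng.permutation(design.n_trials)
    omission = np.sort(idx[: design.n_omission])
    unpredicted = np.sort(idx[design.n_omission: design.n_omission + design.n_unpredicted])

    if design.consumption_jitter_law == "constant":
        jitter = np.full(design.n_trials, design.consumption_jitter_mean_s)
    elif design.consumption_jitter_law == "exponential":
        jitter = rng.exponential(design.consumption_jitter_mean_s, size=design.n_trials)
    else:
        raise ConfigurationError(f"unknown jitter law '{design.consumption_jitter_law}'")
    consumed = np.setdiff1d(np.arange(design.n_trials), omission)
    consumption = delivery[consumed] + jitter[consumed]

    duration = delivery[-1] + 30.0
    n = int(round(duration * design.fs))
    t = np.arange(n) / design.fs
    amps = np.full(len(consumption), kernel.amplitude)
    s = _transient_sum(t, consumption, amps, kernel, design.fs)
    a = artifact.sample(n, design.fs, rng)
    bleach405 = bleach.scaled(bleach_405_gain)
    sigmas = _channel_sigmas(noise_sigma, bleach, bleach405)
    ch465, ch405 = _assemble_channels(t, s, a, bleach, bleach405, artifact, sigmas, rng,
                                      design.fs, lowpass_hz=design.lowpass_hz)

    records = []
    for i, on in enumerate(cue_onsets):
        if i not in unpredicted:
            records.append(("cue", on, on + design.cue_s))
    for i, d in enumerate(delivery):
        if i not in omission:
            records.append(("pellet", d, None))
    records += [("consumption", c, None) for c in consumption]
    records.sort(key=lambda r: r[1])
    events = EventTable.from_records(records)
    session = RawPhotometrySession(ch465, ch405, events,
                                   meta={"subject": f"sim{design.seed}", "sensor": "GCaMP8m",
                                         "paradigm": "reward", "fs": design.fs})
    gt = GroundTruth(consumption, amps, bleach, bleach405,
                     TimeSeries(a, design.fs, unit="z"), sigmas,
                     consumption_times_s=consumption,
                     omission_trials=omission, unpredicted_trials=unpredicted)
    return session, gt


def generate_opto_session(
    design: SessionDesign,
    kernel: TransientKernel = TransientKernel(),
    bleach: BleachModel = BleachModel(),
    artifact: ArtifactModel = ArtifactModel(),
    response_gain_per_pulse: float = 0.0025,
    *,
    saturation_amplitude: float | None = None,
    noise_sigma: float | None = None,
    bleach_405_gain: float = 0.6,
) -> tuple[RawPhotometrySession, GroundTruth]:
    """Opto session: pulse-train conditions in shuffled order at a fixed ITI;
    evoked amplitude = gain x pulse count (optional saturation cap)."""
    if design.paradigm != "opto":
        raise ConfigurationError("design paradigm must be 'opto'")
    rng = np.random.default_rng(design.seed)
    pulses = np.repeat(design.pulse_conditions, design.trials_per_condition)
    rng.shuffle(pulses)
    n_stim = len(pulses)
    onsets = 30.0 + design.opto_iti_s * np.arange(n_stim)
    duration = onsets[-1] + design.opto_iti_s
    n = int(round(duration * design.fs))
    t = np.arange(n) / design.fs

    amps = response_gain_per_pulse * pulses.astype(float)
    if saturation_amplitude is not None:
        amps = np.minimum(amps, saturation_amplitude)
    s = _transient_sum(t, onsets, amps, kernel, design.fs)
    a = artifact.sample(n, design.fs, rng)
    bleach405 = bleach.scaled(bleach_405_gain)
    sigmas = _channel_sigmas(noise_sigma, bleach, bleach405)
    ch465, ch405 = _assemble_channels(t, s, a, bleach, bleach405, artifact, sigmas, rng,
                                      design.fs, lowpass_hz=design.lowpass_hz)

    train_dur = (pulses - 1) / design.pulse_rate_hz + 0.010
    events = EventTable.from_records(
        [("stim", on, on + d) for on, d in zip(onsets, train_dur)]
    )
    session = RawPhotometrySession(ch465, ch405, events,
                                   meta={"subject": f"sim{design.seed}", "sensor": "dLight1.2",
                                         "paradigm": "opto", "fs": design.fs})
    gt = GroundTruth(onsets, amps, bleach, bleach405,
                     TimeSeries(a, design.fs, unit="z"), sigmas,
                     pulse_counts=pulses, conditions=pulses)
    return session, gt


@dataclass
class BehaviorGroundTruth:
    """Per-frame changed-pixel percentages as constructed by the generator."""

    pct_pixels_changed: np.ndarray
    blob_positions_px: np.ndarray  # n_frames x 2 (row, col)


def generate_behavior_streams(
    n_frames: int = 300,
    frame_shape: tuple[int, int] = (64, 64),
    fps: float = 30.0,
    arena_cm: tuple[float, float] = (45.0, 45.0),
    blob_half_px: int = 3,
    step_cm: float = 1.0,
    seed: int = 0,
    x_limits_cm: tuple[float, float] | None = None,
) -> tuple[np.ndarray, TrackTrace, BehaviorGroundTruth]:
    """Grayscale frames of a bright square blob random-walking in an arena.

    Returns the uint8 frame stack, the matching position track in cm, and the
    per-frame changed-pixel ground truth (first frame 0 by convention).
    ``x_limits_cm`` confines the walk to a sub-range of the x axis (for zone
    tests).  Frames are binary 0/255 so any threshold in (0, 255) recovers the
    constructed pixel counts exactly.
    """
    h, w = frame_shape
    if h <= 0 or w <= 0 or n_frames < 2:
        raise ConfigurationError("need a non-empty frame size and >= 2 frames")
    rng = np.random.default_rng(seed)
    ax, ay = arena_cm
    xlim = x_limits_cm if x_limits_cm is not None else (0.0, ax)

    x = np.empty(n_frames)
    y = np.empty(n_frames)
    x[0], y[0] = rng.uniform(*xlim), rng.uniform(0, ay)
    for k in range(1, n_frames):
        x[k] = np.clip(x[k - 1] + rng.normal(0, step_cm), xlim[0], xlim[1] - 1e-9)
        y[k] = np.clip(y[k - 1] + rng.normal(0, step_cm), 0, ay - 1e-9)

    px_per_cm_x = w / ax
    px_per_cm_y = h / ay
    frames = np.zeros((n_frames, h, w), dtype=np.uint8)
    pos = np.empty((n_frames, 2), dtype=int)
    masks = []
    for k in range(n_frames):
        c = int(np.clip(round(x[k] * px_per_cm_x), blob_half_px, w - 1 - blob_half_px))
        r = int(np.clip(round(y[k] * px_per_cm_y), blob_half_px, h - 1 - blob_half_px))
        pos[k] = (r, c)
        mask = np.zeros((h, w), dtype=bool)
        mask[r - blob_half_px: r + blob_half_px + 1, c - blob_half_px: c + blob_half_px + 1] = True
        frames[k][mask] = 255
        masks.append(mask)

    pct = np.zeros(n_frames)
    for k in range(1, n_frames):
        pct[k] = 100.0 * np.count_nonzero(masks[k] ^ masks[k - 1]) / (h * w)

    track = TrackTrace(x, y, fps)
    return frames, track, BehaviorGroundTruth(pct, pos)
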