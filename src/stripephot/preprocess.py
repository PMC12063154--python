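"""Raw dual-channel sessions -> % dF/F.

The chain mirrors standard isosbestic practice: block-mean downsample (100 Hz
for peri-event work, 10 Hz for movement correlation), fit the 405 nm control
channel to the 465 nm signal channel by degree-1 least squares, and take

    dF/F (%) = 100 * (ch465 - fitted) / fitted

either over the whole session or per trial window.  For session-long
movement-correlation work, `iterative_flatten` additionally removes residual
slow drift: the baseline estimate is iterated as a centered moving average of
the elementwise minimum of the signal and the previous estimate (an iterative
lower-envelope smoother), then subtracted, leaving a flat baseline around 0%
while preserving positive transients.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .session import RawPhotometrySession, TimeSeries, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "IsosbesticFit",
    "DffTrace",
    "downsample_block_mean",
    "fit_isosbestic",
    "compute_dff",
    "detrend_session",
    "iterative_flatten",
]

#: Analysis rates used throughout the pipeline.
PERIEVENT_FS = 100.0
MOVEMENT_FS = 10.0


@dataclass
class IsosbesticFit:
    """Degree-1 OLS fit of the 405 control onto the 465 signal.

    ``fitted`` is the predicted 465 (slope * ch405 + intercept) on the fit
    window; it must be strictly positive for dF/F to be defined there.
    """

    slope: float
    intercept: float
    window: tuple[float, float]
    fitted: np.ndarray
    degenerate: bool = False


@dataclass
class DffTrace:
    """Detrended trace in % dF/F with the provenance of its isosbestic fit(s).

    In ``per_trial`` mode values outside the detrended trial windows are NaN.
    """

    trace: TimeSeries
    fits: list[IsosbesticFit]
    mode: str = "whole_session"
    flattened: bool = False

    @property
    def values(self) -> np.ndarray:
        return self.trace.values

    @property
    def fs(self) -> float:
        return self.trace.fs

    def times(self) -> np.ndarray:
        return self.trace.times()


def downsample_block_mean(ts: TimeSeries, target_fs: float) -> TimeSeries:
    """Non-overlapping block means; a trailing partial block is dropped.

    The block size is ``round(ts.fs / target_fs)`` so the output rate is
    ``ts.fs / block`` (exactly ``target_fs`` only when the ratio is integer).
    """
    if target_fs > ts.fs:
        raise ValueError(f"target_fs {target_fs} exceeds source fs {ts.fs}")
    block = int(round(ts.fs / target_fs))
    if block < 1:
        raise ValueError("downsampling factor must be >= 1")
    if block == 1:
        return TimeSeries(ts.values.copy(), ts.fs, ts.t0, ts.unit)
    n_out = len(ts.values) // block
    vals = ts.values[: n_out * block].reshape(n_out, block).mean(axis=1)
    out_fs = ts.fs / block
    # stamp each block mean at its block center so downstream alignment
    # (event extraction, stream cross-correlation) carries no half-block bias
    t0 = ts.t0 + (block - 1) / (2.0 * ts.fs)
    return TimeSeries(vals, out_fs, t0, ts.unit)


def fit_isosbestic(seg465: np.ndarray, seg405: np.ndarray,
                   window: tuple[float, float] = (0.0, 0.0)) -> IsosbesticFit:
    """Least-squares straight line predicting the 465 channel from the 405.

    A zero-variance control channel cannot anchor a regression; the fit then
    degrades to predicting a constant (slope 0) with a logged warning rather
    than failing, so batch runs survive a dead channel.  The constant is the
    *median* of the 465 segment: with sparse positive transients the median
    sits on the baseline, whereas the mean would be pulled up by the
    transients and bias dF/F downward.
    """
    seg465 = np.asarray(seg465, dtype=float)
    seg405 = np.asarray(seg405, dtype=float)
    if seg465.shape != seg405.shape:
        raise ValueError("channel segments differ in length")
    if len(seg465) < 3:
        raise ValueError("need at least 3 samples to fit")
    var405 = np.var(seg405)
    if var405 <= 1e-30 * max(1.0, np.mean(seg405) ** 2):
        logger.warning("degenerate isosbestic fit: 405 channel has zero variance")
        level = float(np.median(seg465))
        fitted = np.full_like(seg465, level)
        return IsosbesticFit(0.0, level, window, fitted, degenerate=True)
    slope, intercept = np.polyfit(seg405, seg465, 1)
    fitted = slope * seg405 + intercept
    return IsosbesticFit(float(slope), float(intercept), window, fitted)


def compute_dff(seg465: np.ndarray, fit: IsosbesticFit) -> np.ndarray:
    """100 * (signal - predicted) / predicted, in %."""
    seg465 = np.asarray(seg465, dtype=float)
    bad = fit.fitted <= 0
    if bad.any():
        k = int(np.argmax(bad))
        raise FloatingPointError(
            f"predicted signal non-positive at sample {k}; dF/F undefined"
        )
    return 100.0 * (seg465 - fit.fitted) / fit.fitted


def _trial_windows(session: RawPhotometrySession, label: str,
                   pre_s: float, post_s: float) -> list[tuple[float, float]]:
    onsets = session.events.onsets(label)
    if len(onsets) == 0:
        raise ValidationError(f"no events with label '{label}'")
    t0, t1 = session.signal_465.t0, session.signal_465.t0 + session.duration_s
    wins = [(max(on - pre_s, t0), min(on + post_s, t1)) for on in onsets]
    for (a0, a1), (b0, b1) in zip(wins, wins[1:]):
        if b0 < a1:
            raise ValidationError(
                f"overlapping trial windows [{a0:g},{a1:g}) and [{b0:g},{b1:g})"
            )
    return wins


def detrend_session(
    session: RawPhotometrySession,
    mode: str = "whole_session",
    *,
    label: str | None = None,
    pre_s: float = 5.0,
    post_s: float = 5.0,
    target_fs: float = PERIEVENT_FS,
) -> DffTrace:
    """Downsample then detrend a session to % dF/F.

    ``whole_session``: one isosbestic fit over the full duration.
    ``per_trial``: one fit per ``[onset - pre_s, onset + post_s)`` window
    around each event with ``label`` (the paper's per-trial detrending);
    samples outside every window are NaN.
    """
    if mode not in ("whole_session", "per_trial"):
        raise ValueError(f"unknown mode '{mode}'")
    s465 = downsample_block_mean(session.signal_465, target_fs)
    s405 = downsample_block_mean(session.control_405, target_fs)

    if mode == "whole_session":
        fit = fit_isosbestic(s465.values, s405.values, (s465.t0, s465.t0 + s465.duration_s))
        dff = compute_dff(s465.values, fit)
        return DffTrace(TimeSeries(dff, s465.fs, s465.t0, unit="% dF/F"), [fit], mode)

    if label is None:
        raise ValueError("per_trial mode requires an event label")
    wins = _trial_windows(session, label, pre_s, post_s)
    out = np.full(len(s465.values), np.nan)
    fits: list[IsosbesticFit] = []
    for w0, w1 in wins:
        i0 = s465.index_at_or_after(w0)
        i1 = s465.index_at_or_after(w1)
        fit = fit_isosbestic(s465.values[i0:i1], s405.values[i0:i1], (w0, w1))
        out[i0:i1] = compute_dff(s465.values[i0:i1], fit)
        fits.append(fit)
    return DffTrace(TimeSeries(out, s465.fs, s465.t0, unit="% dF/F"), fits, mode)


def _moving_average(x: np.ndarray, n: int) -> np.ndarray:
    """Centered moving average with linear end extrapolation.

    Ends are padded by first-order fits to the terminal windows so a linear
    ramp passes through unchanged (constant padding would bend the estimate
    at the trace edges).
    """
    if n <= 1:
        return x.copy()
    h = n // 2
    k = min(n, len(x))
    idx = np.arange(k)
    c_lo = np.polyfit(idx, x[:k], 1)
    c_hi = np.polyfit(idx, x[-k:], 1)
    left = np.polyval(c_lo, np.arange(-h, 0))
    right = np.polyval(c_hi, np.arange(k, k + h))
    xp = np.concatenate([left, x, right])
    c = np.cumsum(np.concatenate([[0.0], xp]))
    return (c[n:] - c[:-n]) / n


def iterative_flatten(dff: DffTrace, window_s: float = 15.0, iterations: int = 100) -> DffTrace:
    """Remove residual slow drift, leaving a flat baseline around 0% dF/F.

    Baseline recursion: b0 = signal; b_{k+1} = centered moving average
    (window ``window_s``) of elementwise min(signal, b_k).  After
    ``iterations`` passes the baseline hugs the signal's lower envelope at
    the window scale; the output is signal - baseline.  Positive transients
    shorter than the window survive nearly unchanged.
    """
    x = dff.values
    if np.isnan(x).any():
        raise ValueError("iterative_flatten requires a gap-free (whole-session) trace")
    n = int(round(window_s * dff.fs))
    n += (n + 1) % 2  # force odd so the window is centered
    if n > len(x):
        raise ValueError("flattening window longer than the trace")
    b = x.copy()
    for _ in range(iterations):
        b = _moving_average(np.minimum(x, b), n)
    out = x - b
    ts = replace(dff.trace, values=out)
    return DffTrace(ts, dff.fits, dff.mode, flattened=True)
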