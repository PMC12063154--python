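"""Movement quantification and the dF/F-movement cross-correlation.

Body movement is measured as the percentage of pixels that change between
consecutive video frames (above an intensity threshold).  Its relation to the
neural signal is assessed with a per-lag Pearson-style cross-correlogram over
lags of -10..+10 s, both series z-scored over the session and each lag's sum
normalized by its overlap length.  Sign convention: a **positive lag means the
photometry signal leads movement** (r(l) correlates dff(t) with movement(t+l)).

Locomotion measures (total path length, time per arena zone) operate on x/y
position tracks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .preprocess import DffTrace
from .session import MovementTrace, TrackTrace, ValidationError

__all__ = [
    "XCorrResult",
    "ZoneSpec",
    "pixel_change_trace",
    "inactivity_time",
    "align_movement",
    "crosscorr_movement",
    "distance_traveled",
    "time_in_zone",
]

DEFAULT_DIFF_THRESHOLD = 10.0  # on a 0-255 intensity scale
DEFAULT_INACTIVITY_THRESHOLD = 0.05  # % pixels changed
DEFAULT_MIN_BOUT_S = 1.0


@dataclass
class XCorrResult:
    """Cross-correlogram between a photometry trace and movement.

    Positive ``lags_s`` mean the photometry signal leads movement.
    """

    lags_s: np.ndarray
    r: np.ndarray

    @property
    def r0(self) -> float:
        """Correlation at lag zero."""
        return float(self.r[len(self.r) // 2])

    @property
    def peak_lag_s(self) -> float:
        return float(self.lags_s[int(np.argmax(self.r))])

    @property
    def peak_r(self) -> float:
        return float(np.max(self.r))


@dataclass
class ZoneSpec:
    """Named axis-aligned rectangles in arena cm, half-open [x0,x1) x [y0,y1)."""

    zones: dict[str, tuple[float, float, float, float]]  # name -> (x0, y0, x1, y1)

    def __post_init__(self) -> None:
        rects = list(self.zones.items())
        for name, (x0, y0, x1, y1) in rects:
            if not (x1 > x0 and y1 > y0):
                raise ValidationError(f"zone '{name}' is degenerate")
        for i, (na, a) in enumerate(rects):
            for nb, b in rects[i + 1:]:
                if a[0] < b[2] and b[0] < a[2] and a[1] < b[3] and b[1] < a[3]:
                    raise ValidationError(f"zones '{na}' and '{nb}' overlap")


def pixel_change_trace(frames: np.ndarray, diff_threshold: float = DEFAULT_DIFF_THRESHOLD,
                       fps: float = 30.0) -> MovementTrace:
    """Percent of pixels changing by more than ``diff_threshold`` per frame.

    Value at frame k (k >= 1) compares frame k with frame k-1; the first
    frame has no predecessor and is assigned 0.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValidationError("need a stack of >= 2 equal-size frames")
    diffs = np.abs(np.diff(frames.astype(np.int64), axis=0))
    changed = (diffs > diff_threshold).sum(axis=(1, 2))
    total = frames.shape[1] * frames.shape[2]
    pct = np.concatenate([[0.0], 100.0 * changed / total])
    return MovementTrace(pct, fps)


def inactivity_time(movement: MovementTrace, threshold: float = DEFAULT_INACTIVITY_THRESHOLD,
                    min_bout_s: float = DEFAULT_MIN_BOUT_S) -> float:
    """Total seconds spent in sub-threshold bouts lasting at least ``min_bout_s``.

    A bout is a maximal run of consecutive samples with movement strictly
    below ``threshold``; its duration is the run length over the frame rate.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    below = movement.values < threshold
    if not below.any():
        return 0.0
    # run-length encode
    edges = np.flatnonzero(np.diff(below.astype(np.int8)))
    starts = np.concatenate([[0], edges + 1])
    ends = np.concatenate([edges + 1, [len(below)]])
    total = 0.0
    min_len = min_bout_s * movement.fs
    for s, e in zip(starts, ends):
        if below[s] and (e - s) >= min_len - 1e-9:
            total += (e - s) / movement.fs
    return total


def align_movement(dff: DffTrace, movement: MovementTrace) -> MovementTrace:
    """Linearly interpolate a movement trace onto the photometry clock.

    Video frame rates and the acquisition rate are never exact multiples of
    each other, so the 10 Hz streams entering the cross-correlation come from
    slightly different grids; interpolation onto the dF/F grid removes the
    clock drift that would otherwise smear the correlogram over a session.
    Samples outside the movement trace's span repeat its edge values.
    """
    t_target = dff.times()
    vals = np.interp(t_target, movement.times(), movement.values)
    return MovementTrace(vals, dff.fs, t0=dff.trace.t0)


def crosscorr_movement(dff10: DffTrace, movement10: MovementTrace,
                       max_lag_s: float = 10.0) -> XCorrResult:
    """Per-lag normalized cross-correlation between dF/F and movement.

    Both series are z-scored over the whole session (population sd); for lag
    l the estimator is sum_t z_x(t) z_y(t+l) / N_overlap(l), where x is the
    photometry trace and y the movement trace, so r at lag 0 is the ordinary
    Pearson correlation and positive lags mean the neural signal leads.
    """
    if abs(dff10.fs - movement10.fs) > 1e-9:
        raise ValueError(f"sampling rates differ: {dff10.fs} vs {movement10.fs}")
    x = np.asarray(dff10.values, dtype=float)
    y = np.asarray(movement10.values, dtype=float)
    n = min(len(x), len(y))
    x, y = x[:n], y[:n]
    fs = dff10.fs
    L = int(round(max_lag_s * fs))
    if n < 10 * L:
        raise ValueError("need overlap of at least 10x the maximum lag")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for a zero-variance input")
    zx = (x - x.mean()) / x.std()
    zy = (y - y.mean()) / y.std()
    # full cross-correlation: index n-1+l holds sum_t zx[t] * zy[t+l]
    full = sps.correlate(zy, zx, mode="full", method="auto")
    lags = np.arange(-L, L + 1)
    overlap = n - np.abs(lags)
    r = full[n - 1 - L: n + L] / overlap
    return XCorrResult(lags / fs, r)


def distance_traveled(track: TrackTrace) -> float:
    """Total path length: sum of Euclidean step lengths, in cm."""
    if len(track) < 2:
        raise ValueError("need at least 2 track points")
    return float(np.hypot(np.diff(track.x_cm), np.diff(track.y_cm)).sum())


def time_in_zone(track: TrackTrace, zones: ZoneSpec) -> dict[str, float]:
    """Seconds spent in each zone: in-zone sample count over the frame rate."""
    out = {}
    for name, (x0, y0, x1, y1) in zones.zones.items():
        inside = (track.x_cm >= x0) & (track.x_cm < x1) & (track.y_cm >= y0) & (track.y_cm < y1)
        out[name] = float(inside.sum() / track.fs)
    return out
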