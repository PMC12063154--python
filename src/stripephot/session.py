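"""Core data model for photometry sessions and their on-disk bundle format.

A *session bundle* is a plain directory of text files::

    signals.csv   time_s,ch465,ch405      demodulated channels on a common clock
    events.csv    label,onset_s,offset_s  behavioral TTL events (offset may be empty)
    meta.json     subject, sensor, paradigm, fs

Movement and position streams live in sibling files (``movement.csv``,
``track.csv``).  Time is seconds from session start, samples are 0-based, and
every analysis window in the package is half-open ``[start, end)``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TimeSeries",
    "EventTable",
    "RawPhotometrySession",
    "MovementTrace",
    "TrackTrace",
    "FormatError",
    "ValidationError",
    "read_session_bundle",
    "write_session_bundle",
    "validate_session",
    "read_movement",
    "write_movement",
    "read_track",
    "write_track",
]

#: Relative tolerance for declaring a timestamp grid uniform.
UNIFORM_RTOL = 1e-6


class FormatError(ValueError):
    """A bundle file is missing or malformed."""


class ValidationError(ValueError):
    """Data violates a type invariant."""


@dataclass
class TimeSeries:
    """A uniformly sampled signal.

    Sample ``k`` has timestamp ``t0 + k / fs``.  The physical unit travels in
    ``unit`` (``"a.u."`` for raw channels, ``"% dF/F"`` for detrended traces,
    ``"% pixels/frame"`` for movement).
    """

    values: np.ndarray
    fs: float
    t0: float = 0.0
    unit: str = "a.u."

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("TimeSeries values must be 1-D")
        if not self.fs > 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) / self.fs

    def slice_seconds(self, start_s: float, end_s: float) -> np.ndarray:
        """Samples with timestamps in the half-open window ``[start_s, end_s)``."""
        i0 = int(math.ceil((start_s - self.t0) * self.fs - 1e-9))
        i1 = int(math.ceil((end_s - self.t0) * self.fs - 1e-9))
        i0, i1 = max(i0, 0), min(i1, len(self.values))
        return self.values[i0:i1]

    def index_at_or_after(self, t_s: float) -> int:
        """Index of the first sample at or after time ``t_s``."""
        return int(math.ceil((t_s - self.t0) * self.fs - 1e-9))


class MovementTrace(TimeSeries):
    """Percent-of-pixels-changed-per-frame body-movement series (values in [0, 100])."""

    def __init__(self, values, fs, t0=0.0):
        super().__init__(np.asarray(values, dtype=float), fs, t0, unit="% pixels/frame")


@dataclass
class EventTable:
    """Labeled behavioral events with onset (and optionally offset) times.

    Backed by a DataFrame with columns ``label``, ``onset_s``, ``offset_s``;
    a missing offset (instantaneous TTL) is NaN.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.df, columns=["label", "onset_s", "offset_s"]).copy()
        df["label"] = df["label"].astype(str)
        df["onset_s"] = df["onset_s"].astype(float)
        df["offset_s"] = df["offset_s"].astype(float)
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_records(cls, records) -> "EventTable":
        """Build from an iterable of (label, onset_s[, offset_s]) tuples."""
        rows = []
        for rec in records:
            label, onset = rec[0], rec[1]
            offset = rec[2] if len(rec) > 2 and rec[2] is not None else np.nan
            rows.append((label, onset, offset))
        return cls(pd.DataFrame(rows, columns=["label", "onset_s", "offset_s"]))

    @classmethod
    def empty(cls) -> "EventTable":
        return cls(pd.DataFrame(columns=["label", "onset_s", "offset_s"]))

    def __len__(self) -> int:
        return len(self.df)

    def labels(self) -> list[str]:
        return sorted(self.df["label"].unique())

    def onsets(self, label: str) -> np.ndarray:
        return self.df.loc[self.df["label"] == label, "onset_s"].to_numpy()

    def findings(self) -> list[str]:
        out = []
        df = self.df
        if (df["label"].str.len() == 0).any():
            out.append("event with empty label")
        for label, grp in df.groupby("label", sort=False):
            if not grp["onset_s"].is_monotonic_increasing:
                out.append(f"event onsets not sorted for label '{label}'")
        bad = df["offset_s"].notna() & (df["offset_s"] < df["onset_s"])
        if bad.any():
            out.append(
                f"event offset before onset at row(s) {list(df.index[bad])}"
            )
        if not np.isfinite(df["onset_s"]).all():
            out.append("non-finite event onset")
        return out


@dataclass
class RawPhotometrySession:
    """Paired 465 nm signal / 405 nm isosbestic channels plus event table.

    Both channels share ``t0``, ``fs`` and length; ``meta`` carries subject id,
    sensor name (GCaMP8m / GCaMP6s / dLight1.2 / iGluSnFR) and a paradigm tag.
    """

    signal_465: TimeSeries
    control_405: TimeSeries
    events: EventTable
    meta: dict = field(default_factory=dict)

    @property
    def fs(self) -> float:
        return self.signal_465.fs

    @property
    def duration_s(self) -> float:
        return self.signal_465.duration_s


@dataclass
class TrackTrace:
    """Uniformly sampled x/y position track in arena centimeters."""

    x_cm: np.ndarray
    y_cm: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.x_cm = np.asarray(self.x_cm, dtype=float)
        self.y_cm = np.asarray(self.y_cm, dtype=float)
        if self.x_cm.shape != self.y_cm.shape:
            raise ValidationError("x and y tracks differ in length")
        if not self.fs > 0:
            raise ValidationError("fs must be positive")

    def __len__(self) -> int:
        return len(self.x_cm)

    @property
    def duration_s(self) -> float:
        return len(self.x_cm) / self.fs


def validate_session(session: RawPhotometrySession) -> list[str]:
    """Check every type invariant; return human-readable findings (empty iff valid)."""
    findings: list[str] = []
    s465, s405 = session.signal_465, session.control_405
    if len(s465) != len(s405):
        findings.append("channel length mismatch")
    if s465.fs != s405.fs:
        findings.append("channel fs mismatch")
    if s465.t0 != s405.t0:
        findings.append("channel t0 mismatch")
    if len(s465) == 0:
        findings.append("empty session")
    for name, ch in (("ch465", s465), ("ch405", s405)):
        if not np.all(np.isfinite(ch.values)):
            findings.append(f"non-finite sample in {name}")
    findings.extend(session.events.findings())
    dur = s465.duration_s
    ev = session.events.df
    if len(ev) and (ev["onset_s"].min() < s465.t0 - 1e-9 or ev["onset_s"].max() > s465.t0 + dur + 1e-9):
        findings.append("event outside session time span")
    return findings


# ---------------------------------------------------------------------------
# Bundle I/O


def _infer_fs(time_s: np.ndarray) -> float:
    dt = np.diff(time_s)
    if len(dt) == 0:
        raise ValidationError("cannot infer fs from a single sample")
    med = float(np.median(dt))
    if med <= 0:
        raise ValidationError("timestamps not strictly increasing")
    if np.max(np.abs(dt - med)) > UNIFORM_RTOL * med + 1e-12:
        raise ValidationError("non-uniform sampling grid")
    return 1.0 / med


def write_session_bundle(session: RawPhotometrySession, path) -> Path:
    """Write a session as ``signals.csv`` + ``events.csv`` + ``meta.json``.

    Numeric fields are serialized at 17 significant digits so the
    write-then-read round trip is the identity.
    """
    findings = validate_session(session)
    if findings:
        raise ValidationError("refusing to write invalid session: " + "; ".join(findings))
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    t = session.signal_465.times()
    sig = pd.DataFrame(
        {"time_s": t, "ch465": session.signal_465.values, "ch405": session.control_405.values}
    )
    sig.to_csv(path / "signals.csv", index=False, float_format="%.17g")
    session.events.df.to_csv(path / "events.csv", index=False, float_format="%.17g")
    meta = dict(session.meta)
    meta.setdefault("fs", session.fs)
    with open(path / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=float)
    return path


def read_session_bundle(path) -> RawPhotometrySession:
    """Read and validate a session bundle directory.

    ``fs`` is inferred from the median timestamp spacing and cross-checked
    against ``meta.json``; on conflict the timestamps win with a logged warning.
    """
    path = Path(path)
    for fname in ("signals.csv", "events.csv", "meta.json"):
        if not (path / fname).exists():
            raise FormatError(f"bundle missing {fname}")
    sig = pd.read_csv(path / "signals.csv")
    for col in ("time_s", "ch465", "ch405"):
        if col not in sig.columns:
            raise FormatError(f"signals.csv missing column {col}")
    ev = pd.read_csv(path / "events.csv")
    for col in ("label", "onset_s", "offset_s"):
        if col not in ev.columns:
            raise FormatError(f"events.csv missing column {col}")
    with open(path / "meta.json") as fh:
        meta = json.load(fh)

    time_s = sig["time_s"].to_numpy(dtype=float)
    fs = _infer_fs(time_s)
    meta_fs = meta.get("fs")
    if meta_fs is not None and abs(meta_fs - fs) > UNIFORM_RTOL * fs:
        logger.warning(
            "meta fs=%g disagrees with timestamp-inferred fs=%g; using timestamps", meta_fs, fs
        )
    meta["fs"] = fs
    t0 = float(time_s[0])
    session = RawPhotometrySession(
        signal_465=TimeSeries(sig["ch465"].to_numpy(dtype=float), fs, t0, unit="a.u."),
        control_405=TimeSeries(sig["ch405"].to_numpy(dtype=float), fs, t0, unit="a.u."),
        events=EventTable(ev),
        meta=meta,
    )
    findings = validate_session(session)
    if findings:
        raise ValidationError("invalid bundle: " + "; ".join(findings))
    return session


def write_movement(trace: MovementTrace, path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": trace.times(), "pct_pixels": trace.values}).to_csv(
        path, index=False, float_format="%.17g"
    )
    return path


def read_movement(path) -> MovementTrace:
    df = pd.read_csv(path)
    for col in ("time_s", "pct_pixels"):
        if col not in df.columns:
            raise FormatError(f"movement csv missing column {col}")
    t = df["time_s"].to_numpy(dtype=float)
    fs = _infer_fs(t)
    vals = df["pct_pixels"].to_numpy(dtype=float)
    if vals.min() < -1e-9 or vals.max() > 100 + 1e-9:
        raise ValidationError("movement values outside [0, 100]")
    return MovementTrace(vals, fs, t0=float(t[0]))


def write_track(track: TrackTrace, path) -> Path:
    path = Path(path)
    t = track.t0 + np.arange(len(track)) / track.fs
    pd.DataFrame({"time_s": t, "x_cm": track.x_cm, "y_cm": track.y_cm}).to_csv(
        path, index=False, float_format="%.17g"
    )
    return path


def read_track(path) -> TrackTrace:
    df = pd.read_csv(path)
    for col in ("time_s", "x_cm", "y_cm"):
        if col not in df.columns:
            raise FormatError(f"track csv missing column {col}")
    t = df["time_s"].to_numpy(dtype=float)
    fs = _infer_fs(t)
    x = df["x_cm"].to_numpy(dtype=float)
    y = df["y_cm"].to_numpy(dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("non-finite track coordinate")
    return TrackTrace(x, y, fs, t0=float(t[0]))
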