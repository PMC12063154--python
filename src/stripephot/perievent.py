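"""Event-aligned trial extraction and peak/AUC quantification.

Trials are rows of a trials x relative-time matrix cut around each event
onset; the sample at relative time 0 is the first sample at or after the
onset.  Two summary metrics follow the conventions of peri-event photometry
work:

* **peak delta** — per-trial maximum dF/F in a response window minus the
  maximum in a (disjoint, earlier) baseline window;
* **AUC delta** — trapezoidal area over a post-onset window minus the area
  over an equal-duration pre-onset window, in %·s.  Areas are signed, so a
  signal dipping below baseline subtracts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .preprocess import DffTrace

logger = logging.getLogger(__name__)

__all__ = [
    "PeriEventTensor",
    "PeakDelta",
    "AucDelta",
    "EmptyTensorError",
    "extract_trials",
    "extract_trials_by_label",
    "summarize_mean_sem",
    "peak_delta",
    "peak_delta_of_mean",
    "auc_delta",
]


class EmptyTensorError(ValueError):
    """No usable trials for the requested event label."""


@dataclass
class PeriEventTensor:
    """Trials x samples matrix of % dF/F around one event label."""

    data: np.ndarray          # (n_trials, n_samples)
    rel_time_s: np.ndarray    # (n_samples,), contains 0
    label: str
    onsets_s: np.ndarray      # per-row event onset, session time
    trial_indices: np.ndarray  # index of each kept trial in the event list
    fs: float

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def window_columns(self, start_s: float, end_s: float) -> np.ndarray:
        """Column mask for the half-open relative-time window [start_s, end_s)."""
        return (self.rel_time_s >= start_s - 1e-9) & (self.rel_time_s < end_s - 1e-9)


@dataclass
class PeakDelta:
    """Per-trial max(response) - max(baseline) peaks, % dF/F."""

    per_trial: np.ndarray
    response_win: tuple[float, float]
    baseline_win: tuple[float, float]

    @property
    def per_animal(self) -> float:
        """Mean of the trial deltas (the default per-animal summary)."""
        return float(np.mean(self.per_trial))


@dataclass
class AucDelta:
    """Per-trial AUC(post) - AUC(pre) around stimulation onsets, %·s."""

    per_trial: np.ndarray
    onsets_s: np.ndarray
    pre_s: float
    post_s: float

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_trial))

    @property
    def median(self) -> float:
        return float(np.median(self.per_trial))


def extract_trials(dff: DffTrace, onsets_s: np.ndarray, label: str,
                   pre_s: float, post_s: float) -> PeriEventTensor:
    """Cut rows of ``[onset - pre_s, onset + post_s)`` around each onset.

    Events whose window falls off the trace (or covers undetrended NaN gaps
    in per-trial traces) are dropped with a warning; if none survive an
    :class:`EmptyTensorError` is raised.
    """
    if pre_s <= 0 or post_s <= 0:
        raise ValueError("pre_s and post_s must be positive")
    onsets_s = np.asarray(onsets_s, dtype=float)
    if len(onsets_s) == 0:
        raise EmptyTensorError(f"no events for label '{label}'")
    fs = dff.fs
    n_pre = int(round(pre_s * fs))
    n_post = int(round(post_s * fs))
    x = dff.values
    rows, kept_onsets, kept_idx = [], [], []
    for i, on in enumerate(np.sort(onsets_s)):
        i0 = dff.trace.index_at_or_after(on)
        lo, hi = i0 - n_pre, i0 + n_post
        if lo < 0 or hi > len(x):
            logger.warning("trial %d at %.3f s too close to trace edge; dropped", i, on)
            continue
        row = x[lo:hi]
        if np.isnan(row).any():
            logger.warning("trial %d at %.3f s overlaps undetrended samples; dropped", i, on)
            continue
        rows.append(row)
        kept_onsets.append(on)
        kept_idx.append(i)
    if not rows:
        raise EmptyTensorError(f"no usable trials for label '{label}'")
    rel = np.arange(-n_pre, n_post) / fs
    return PeriEventTensor(np.vstack(rows), rel, label,
                           np.asarray(kept_onsets), np.asarray(kept_idx), fs)


def extract_trials_by_label(dff: DffTrace, events, label: str,
                            pre_s: float, post_s: float) -> PeriEventTensor:
    """Convenience wrapper taking an :class:`~stripephot.session.EventTable`."""
    return extract_trials(dff, events.onsets(label), label, pre_s, post_s)


def summarize_mean_sem(tensor: PeriEventTensor) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and SEM (sd / sqrt(n), ddof=1) over trials."""
    n = tensor.n_trials
    if n < 1:
        raise EmptyTensorError("empty tensor")
    mean = tensor.data.mean(axis=0)
    if n == 1:
        logger.warning("single trial: SEM is identically zero")
        return mean, np.zeros_like(mean)
    sem = tensor.data.std(axis=0, ddof=1) / np.sqrt(n)
    return mean, sem


def peak_delta(tensor: PeriEventTensor, response_win: tuple[float, float],
               baseline_win: tuple[float, float]) -> PeakDelta:
    """Per-trial max over the response window minus max over the baseline.

    Windows are half-open in relative time; the baseline must precede the
    response window and the two may not overlap.  Peaks are raw sample
    maxima (no smoothing or prominence criterion).
    """
    a, b = response_win
    c, d = baseline_win
    if not (c < d <= a < b):
        raise ValueError("baseline window must precede the response window, disjoint")
    resp = tensor.window_columns(a, b)
    base = tensor.window_columns(c, d)
    if not resp.any() or not base.any():
        raise ValueError("a metric window contains no samples after discretization")
    deltas = tensor.data[:, resp].max(axis=1) - tensor.data[:, base].max(axis=1)
    return PeakDelta(deltas, response_win, baseline_win)


def peak_delta_of_mean(tensor: PeriEventTensor, response_win: tuple[float, float],
                       baseline_win: tuple[float, float]) -> float:
    """Alternative summary: the peak delta of the trial-averaged trace."""
    mean, _ = summarize_mean_sem(tensor)
    resp = tensor.window_columns(*response_win)
    base = tensor.window_columns(*baseline_win)
    if not resp.any() or not base.any():
        raise ValueError("a metric window contains no samples after discretization")
    return float(mean[resp].max() - mean[base].max())


def auc_delta(dff: DffTrace, stim_onsets: np.ndarray,
              pre_s: float = 3.0, post_s: float = 3.0) -> AucDelta:
    """Trapezoidal AUC over [onset, onset+post] minus [onset-pre, onset], %·s.

    Both windows span their nominal duration exactly (closed sample spans
    sharing the onset sample), so adding a constant to the trace shifts both
    areas equally and cancels in the delta.  Onsets whose windows fall off
    the trace are dropped with a warning.
    """
    if pre_s != post_s:
        raise ValueError("pre and post AUC windows must have equal duration")
    fs = dff.fs
    x = dff.values
    n_pre = int(round(pre_s * fs))
    n_post = int(round(post_s * fs))
    vals, kept = [], []
    for on in np.asarray(stim_onsets, dtype=float):
        i0 = dff.trace.index_at_or_after(on)
        if i0 - n_pre < 0 or i0 + n_post >= len(x):
            logger.warning("stim at %.3f s has a truncated window; dropped", on)
            continue
        pre_seg = x[i0 - n_pre: i0 + 1]
        post_seg = x[i0: i0 + n_post + 1]
        if np.isnan(pre_seg).any() or np.isnan(post_seg).any():
            logger.warning("stim at %.3f s overlaps undetrended samples; dropped", on)
            continue
        vals.append(np.trapezoid(post_seg, dx=1.0 / fs) - np.trapezoid(pre_seg, dx=1.0 / fs))
        kept.append(on)
    if not vals:
        raise EmptyTensorError("no stimulation onset had a full analysis window")
    return AucDelta(np.asarray(vals), np.asarray(kept), pre_s, post_s)
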