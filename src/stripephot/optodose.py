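"""Dose-response quantification of optogenetically evoked dF/F.

Two titrations are supported, mirroring common stimulation protocols:

* **pulse-count titration** — trains of e.g. 2/5/10/20/40 pulses; the
  response per trial is the AUC delta (area 3 s after onset minus area 3 s
  before) and conditions are summarized by the mean over their trials;
* **light-intensity titration** — fixed pulse trains delivered in blocks of
  one intensity each; the response per trial is the maximal dF/F within 1 s
  of onset, and each block is summarized by the **median** of its trial
  peaks.  A 0 mW control block is scored from the 1 s *before* onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .perievent import AucDelta, auc_delta
from .preprocess import DffTrace
from .synthetic import ConfigurationError

__all__ = ["StimBlock", "auc_dose_response", "intensity_peak_response"]


@dataclass
class StimBlock:
    """Trials sharing one stimulation condition (pulse count or mW)."""

    condition: float
    onsets_s: np.ndarray
    order: int = 0

    def __post_init__(self) -> None:
        self.onsets_s = np.sort(np.asarray(self.onsets_s, dtype=float))
        if len(self.onsets_s) == 0:
            raise ValueError("a stimulation block needs at least one trial")


def blocks_from_arrays(conditions: np.ndarray, onsets_s: np.ndarray) -> list[StimBlock]:
    """Group per-trial (condition, onset) pairs into one block per condition."""
    conditions = np.asarray(conditions, dtype=float)
    onsets_s = np.asarray(onsets_s, dtype=float)
    return [
        StimBlock(c, onsets_s[conditions == c], order=i)
        for i, c in enumerate(np.unique(conditions))
    ]


def _check_spacing(blocks: list[StimBlock], needed_s: float) -> None:
    all_onsets = np.sort(np.concatenate([b.onsets_s for b in blocks]))
    gaps = np.diff(all_onsets)
    if len(gaps) and gaps.min() < needed_s - 1e-9:
        raise ConfigurationError(
            f"inter-trial interval {gaps.min():g} s too short for the "
            f"{needed_s:g} s analysis windows"
        )


def auc_dose_response(dff: DffTrace, blocks: list[StimBlock],
                      pre_s: float = 3.0, post_s: float = 3.0,
                      summary: str = "mean") -> dict[float, float]:
    """Per-condition summary (default mean) of trial AUC deltas, %·s."""
    _check_spacing(blocks, pre_s + post_s)
    out = {}
    for blk in blocks:
        delta = auc_delta(dff, blk.onsets_s, pre_s=pre_s, post_s=post_s)
        out[blk.condition] = delta.mean if summary == "mean" else delta.median
    return out


def intensity_peak_response(dff: DffTrace, blocks: list[StimBlock],
                            peak_window_s: float = 1.0) -> dict[float, float]:
    """Per-block median of per-trial peak dF/F within 1 s of stimulation onset.

    Blocks with condition 0 (no light) are scored from the window 1 s before
    onset instead, giving the noise floor of the same statistic.
    """
    _check_spacing(blocks, 2 * peak_window_s)
    fs = dff.fs
    nw = int(round(peak_window_s * fs))
    x = dff.values
    out = {}
    for blk in blocks:
        peaks = []
        for on in blk.onsets_s:
            i0 = dff.trace.index_at_or_after(on)
            lo, hi = (i0 - nw, i0) if blk.condition == 0 else (i0, i0 + nw)
            if lo < 0 or hi > len(x):
                continue
            seg = x[lo:hi]
            if len(seg) == 0 or np.isnan(seg).any():
                continue
            peaks.append(seg.max())
        if not peaks:
            raise ValueError(f"no usable trials in block condition={blk.condition:g}")
        out[blk.condition] = float(np.median(peaks))
    return out
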