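"""dF/F response metrics on ROI traces.

A raw fluorescence trace is smoothed with a cubic Savitzky-Golay filter,
then each stimulus event yields a peak response

    dF/F = (F_t - F_b) / F_b

with F_b the mean fluorescence in the 1-s window before stimulus onset and
F_t the maximum in the 5-s window after onset.  The peak is taken on the
smoothed trace; smoothing after the max would not remove the noise-driven
upward bias of the max statistic, so the order is fixed (smooth, then peak).

Windows are mapped to frames by rounding the onset to the nearest frame;
the baseline window is half-open [onset - pre, onset) and the response
window is (onset, onset + post].  At the nominal 13 frames/s this gives 13
baseline frames and 65 response frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .segmentation import Trace

__all__ = [
    "StimulusEvent",
    "PeakResponse",
    "smooth_trace",
    "peak_dff",
    "dff_timecourse",
    "condition_compare",
]


@dataclass(frozen=True)
class StimulusEvent:
    """A stimulus onset: time (s), kind, and its IPI / level where relevant."""

    onset: float
    kind: str = "pulse"
    ipi_ms: float | None = None
    level_db: float | None = None


@dataclass(frozen=True)
class PeakResponse:
    """Peak dF/F for one event, with the raw F_t / F_b it came from."""

    peak_dff: float
    f_t: float
    f_b: float
    onset: float


def smooth_trace(trace: Trace, window: int = 11, polyorder: int = 3) -> Trace:
    """Cubic Savitzky-Golay smoothing (length-preserving).

    ``window`` must be odd and >= polyorder + 2 (>= 5 for the cubic).  Edges
    are handled by fitting the local polynomial on the truncated window
    (scipy's 'interp' mode).  Polynomials of degree <= 3 pass through
    unchanged.
    """
    if window % 2 == 0 or window < polyorder + 2:
        raise ValueError(
            f"window must be odd and >= {polyorder + 2}, got {window}")
    if window >= len(trace.values):
        raise ValueError(
            f"window ({window}) must be shorter than the trace "
            f"({len(trace.values)} frames)")
    smoothed = savgol_filter(trace.values, window, polyorder, mode="interp")
    return Trace(smoothed, trace.frame_rate, trace.roi_id)


def _event_windows(trace: Trace, onset: float, pre_s: float, post_s: float
                   ) -> tuple[slice, slice]:
    fr = trace.frame_rate
    onset_f = int(round(onset * fr))
    pre_f = int(round(pre_s * fr))
    post_f = int(round(post_s * fr))
    base = slice(onset_f - pre_f, onset_f)          # [onset - pre, onset)
    resp = slice(onset_f + 1, onset_f + post_f + 1)  # (onset, onset + post]
    if base.start < 0 or resp.stop > len(trace.values):
        raise ValueError(
            f"event at {onset:.2f}s: windows [{base.start}, {resp.stop}) "
            f"fall outside the {len(trace.values)}-frame trace")
    return base, resp


def peak_dff(trace: Trace, onset: float | StimulusEvent,
             pre_s: float = 1.0, post_s: float = 5.0) -> PeakResponse:
    """Event-locked peak dF/F = (F_t - F_b) / F_b.

    F_b is the mean over the ``pre_s`` window before onset, F_t the maximum
    over the ``post_s`` window after onset.  The trace is used as given
    (smooth first with :func:`smooth_trace`).
    """
    if isinstance(onset, StimulusEvent):
        onset = onset.onset
    base, resp = _event_windows(trace, onset, pre_s, post_s)
    f_b = float(trace.values[base].mean())
    if f_b <= 0:
        raise ValueError(
            f"baseline fluorescence F_b = {f_b:.3g} is not positive; "
            "dF/F is undefined for an uncalibrated baseline")
    f_t = float(trace.values[resp].max())
    return PeakResponse((f_t - f_b) / f_b, f_t, f_b, float(onset))


def dff_timecourse(trace: Trace, baseline: tuple[float, float]) -> Trace:
    """Full dF/F trace relative to the mean over ``baseline`` = (t0, t1) s."""
    t0, t1 = baseline
    if t1 <= t0:
        raise ValueError("baseline window must have positive length")
    fr = trace.frame_rate
    sel = slice(int(round(t0 * fr)), int(round(t1 * fr)))
    if sel.start < 0 or sel.stop > len(trace.values) or sel.stop <= sel.start:
        raise ValueError("baseline window falls outside the trace")
    f0 = float(trace.values[sel].mean())
    if f0 <= 0:
        raise ValueError("baseline mean must be positive")
    return Trace((trace.values - f0) / f0, fr, trace.roi_id)


def condition_compare(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Per-condition summary (mean, SD, SEM, n) of response groups.

    Used for before/drug/wash style comparisons; significance testing is
    delegated to :mod:`songtune.stats`.
    """
    if len(groups) < 2:
        raise ValueError("need at least two condition groups")
    rows = []
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        n = len(vals)
        sd = float(vals.std(ddof=1)) if n > 1 else 0.0
        rows.append({"condition": name, "n": n, "mean": float(vals.mean()),
                     "sd": sd, "sem": sd / np.sqrt(n) if n > 0 else np.nan})
    return pd.DataFrame(rows)
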