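"""Response statistics: cortical traces, early/late AUC, group comparison.

The trial-averaged movie is reduced to a cortical dL/L0 trace, which is
split at a configurable post-stimulus time (default 2 s) into an early
window dominated by the fast calcium component and a late window carrying
the hemodynamic response.  Areas under the curve are trapezoidal integrals
on the native sampling grid, and groups of per-subject AUCs are compared
with Student's t-tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .containers import MaskImage, TraceSeries

__all__ = [
    "ResponseTrace",
    "ResponseStats",
    "GroupComparison",
    "TimecourseSummary",
    "roi_response_trace",
    "rezero_prestim",
    "split_auc",
    "compare_groups",
    "summarize_timecourse",
]

logger = logging.getLogger(__name__)


@dataclass
class ResponseTrace:
    """A stimulus-locked dL/L0 trace; times are seconds from stimulus onset
    (negative = pre-stimulus)."""

    times: np.ndarray
    dl_over_l0: np.ndarray
    n_trials_averaged: int = 0
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.dl_over_l0 = np.asarray(self.dl_over_l0, dtype=float)
        if self.times.shape != self.dl_over_l0.shape or self.times.ndim != 1:
            raise ValueError("times and values must be matching 1-D arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class ResponseStats:
    """Early and late response areas (dL/L0 * s) for one subject."""

    early_auc: float
    late_auc: float
    split_time: float
    early_window: tuple[float, float]
    late_window: tuple[float, float]


@dataclass
class GroupComparison:
    """Student's t comparison of two groups of per-subject scalars."""

    group_a: tuple[float, ...]
    group_b: tuple[float, ...]
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    paired: bool


@dataclass
class TimecourseSummary:
    """Peak value, time to peak (s) and trapezoidal integral of a trace."""

    peak_value: float
    time_to_peak: float
    total_integrated: float


def roi_response_trace(movie: np.ndarray, mask: MaskImage,
                       pre_window: float, frame_rate: float,
                       n_trials_averaged: int = 0,
                       subject_id: str = "") -> ResponseTrace:
    """Mean dL/L0 over the mask per timepoint, re-zeroed at stimulus onset.

    ``movie`` holds L/L0 ratios (as produced by the pipeline); the returned
    trace is dL/L0 = ratio - 1.
    """
    movie = np.asarray(movie, dtype=float)
    if movie.shape[1:] != mask.data.shape:
        raise ValueError("movie and mask spatial shapes differ")
    fg = movie[:, mask.data]
    if fg.shape[1] == 0:
        raise ValueError("mask has no foreground pixels")
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        values = np.nanmean(fg, axis=1) - 1.0
    times = np.arange(movie.shape[0]) / frame_rate - pre_window
    return ResponseTrace(times, values, n_trials_averaged, subject_id)


def rezero_prestim(trace: ResponseTrace,
                   window: tuple[float, float] = (-1.0, 0.0)) -> ResponseTrace:
    """Subtract the mean pre-stimulus dL/L0 level from a response trace.

    Ratio normalization against a short, noisy baseline is slightly biased
    upward (E[X/B] > E[X]/E[B] by ~var(B)/E[B]^2), which offsets every
    frame outside the normalization window by a common constant.  The
    offset is estimated from pre-stimulus frames *outside* that window --
    frames inside it sit at zero by construction and would dilute the
    estimate -- and subtracted, so that response areas integrate signal
    rather than normalization bias.  Default window: [-1, 0) s, the second
    half of the standard 2 s pre-stimulus period.
    """
    sel = (trace.times >= window[0]) & (trace.times < window[1])
    if not sel.any():
        raise ValueError(f"no samples in the re-zeroing window {window}")
    offset = float(np.nanmean(trace.dl_over_l0[sel]))
    return ResponseTrace(trace.times.copy(), trace.dl_over_l0 - offset,
                         trace.n_trials_averaged, trace.subject_id)


def _window_auc(times: np.ndarray, values: np.ndarray,
                lo: float, hi: float) -> float:
    """Trapezoidal integral over [lo, hi] with interpolated endpoints."""
    eps = 1e-9
    if lo < times[0] - eps or hi > times[-1] + eps:
        raise ValueError(f"window [{lo:g}, {hi:g}] s exceeds the trace range "
                         f"[{times[0]:g}, {times[-1]:g}] s")
    inner = (times > lo) & (times < hi)
    xs = np.concatenate(([lo], times[inner], [hi]))
    ys = np.concatenate(([np.interp(lo, times, values)],
                         values[inner],
                         [np.interp(hi, times, values)]))
    return float(np.trapezoid(ys, xs))


def split_auc(trace: ResponseTrace, split_time: float = 2.0,
              early_window: tuple[float, float] | None = None,
              late_window: tuple[float, float] | None = None) -> ResponseStats:
    """Integrate dL/L0 before and after the split time.

    Defaults follow the early-calcium / late-hemodynamic separation:
    early window [0, split_time] s and late window [split_time, 6] s, both
    post-onset.
    """
    early = early_window if early_window is not None else (0.0, split_time)
    late = late_window if late_window is not None else (split_time, 6.0)
    for name, (lo, hi) in (("early", early), ("late", late)):
        if not 0.0 <= lo < hi:
            raise ValueError(f"{name} window must be post-onset with lo < hi")
    if early[1] > late[0] + 1e-9:
        raise ValueError("early and late windows must be disjoint")
    return ResponseStats(
        early_auc=_window_auc(trace.times, trace.dl_over_l0, *early),
        late_auc=_window_auc(trace.times, trace.dl_over_l0, *late),
        split_time=float(split_time),
        early_window=(float(early[0]), float(early[1])),
        late_window=(float(late[0]), float(late[1])),
    )


def compare_groups(a, b, paired: bool = False) -> GroupComparison:
    """Two-tailed Student's t-test between two groups of scalars.

    Unpaired uses the pooled-variance (equal-variance Student's) form with
    df = n_a + n_b - 2; paired uses the paired t on the differences.  A
    degenerate zero-variance comparison with equal means returns t = 0,
    p = 1 by convention (logged).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired groups must have equal length")
        if len(a) < 2:
            raise ValueError("paired test requires at least 2 pairs")
        diffs = a - b
        if np.ptp(diffs) == 0:
            if diffs[0] == 0:
                logger.warning("compare_groups: zero-variance identical "
                               "pairs; returning t=0, p=1 by convention")
                return GroupComparison(tuple(a), tuple(b), 0.0,
                                       float(len(a) - 1), 1.0, True)
            raise ValueError("paired differences are constant and nonzero; "
                             "the t statistic is undefined (zero variance)")
        res = sps.ttest_rel(a, b)
        df = float(len(a) - 1)
    else:
        if len(a) < 2 or len(b) < 2:
            raise ValueError("unpaired test requires n >= 2 per group")
        df = float(len(a) + len(b) - 2)
        pooled = ((len(a) - 1) * a.var(ddof=1) +
                  (len(b) - 1) * b.var(ddof=1)) / df
        if pooled == 0 and a.mean() == b.mean():
            logger.warning("compare_groups: zero pooled variance with equal "
                           "means; returning t=0, p=1 by convention")
            return GroupComparison(tuple(a), tuple(b), 0.0, df, 1.0, False)
        res = sps.ttest_ind(a, b, equal_var=True)
    return GroupComparison(tuple(a), tuple(b), float(res.statistic), df,
                           float(res.pvalue), paired)


def summarize_timecourse(trace: TraceSeries) -> TimecourseSummary:
    """Peak value, its time (s), and trapezoidal integral of a time course.

    Used for whole-recording brightness curves (e.g. substrate kinetics
    sampled at 1/min: pass frame_rate in Hz and read times in seconds).
    NaNs are ignored; an all-missing trace raises.
    """
    values = trace.values
    if len(values) < 2:
        raise ValueError("need at least 2 samples")
    finite = np.isfinite(values)
    if not finite.any():
        raise ValueError("trace is entirely missing")
    idx = int(np.nanargmax(values))
    times = trace.times
    total = float(np.trapezoid(values[finite], times[finite]))
    return TimecourseSummary(float(values[idx]), float(times[idx]), total)
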