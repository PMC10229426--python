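"""Frame-level analysis chain: raw stack to trial-averaged dL/L0 movie.

The chain mirrors the standard stimulus-locked wide-field workflow for
bioluminescence, where the global brightness rises and decays with substrate
pharmacokinetics and must be divided out before trial averaging:

1. dark-baseline subtraction;
2. an intensity-based binary head mask (pixels outside become NaN);
3. the masked mean intensity per frame, smoothed with a zero-phase
   Butterworth lowpass filter;
4. division of every frame by the smoothed trace (decay correction);
5. epoching into trials starting ``pre_window`` seconds before each
   stimulus onset and spanning the cycle length;
6. per-pixel normalization of each trial to its mean over the first
   ``baseline`` seconds (values become L/L0 ratios);
7. averaging of the first ``n_first`` trials.

Values are stored as L/L0 ratios throughout; the fractional change
dL/L0 = ratio - 1 is applied only at statistics/rendering boundaries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal
from skimage import measure
from skimage.filters import threshold_otsu

from .containers import MaskImage, TraceSeries, TrialTensor, VideoStack
from .synthetic import StimulusSchedule

__all__ = [
    "subtract_dark",
    "compute_head_mask",
    "apply_mask",
    "masked_mean_trace",
    "interpolate_missing",
    "lowpass_smooth",
    "decay_correct",
    "epoch_trials",
    "normalize_trials",
    "average_trials",
    "integrate_frames",
    "render_pseudocolor",
    "AnalysisResult",
    "analyze_stack",
]

logger = logging.getLogger(__name__)


def subtract_dark(video: VideoStack, dark) -> VideoStack:
    """Subtract the dark baseline (scalar or per-pixel image), clipping at 0."""
    dark = np.asarray(dark, dtype=float)
    if not np.all(np.isfinite(dark)):
        raise ValueError("dark baseline must be finite")
    # keep float32 stacks float32 (half the memory traffic); promote ints
    dtype = video.data.dtype if video.data.dtype.kind == "f" else np.float64
    data = video.data.astype(dtype, copy=True)
    dark = dark.astype(dtype, copy=False)
    data -= dark
    np.clip(data, 0.0, None, out=data)
    if np.nanmax(data) == 0.0:
        warnings.warn("dark baseline exceeds the stack everywhere; "
                      "the subtracted video is all zero", stacklevel=2)
    return VideoStack(data, video.frame_rate, video.exposure, video.t0)


def compute_head_mask(video: VideoStack, method: str = "otsu", *,
                      fraction: float = 0.5,
                      keep_largest: bool = True) -> MaskImage:
    """Compute one static head mask from the temporal-mean image.

    ``method='otsu'`` thresholds the mean image by maximizing between-class
    variance (256-bin histogram); ``method='fraction'`` thresholds at
    ``fraction`` of the mean image's maximum.  By default only the largest
    connected component is kept, discarding stray bright pixels.
    """
    mean_img = np.nanmean(video.data, axis=0)
    finite = mean_img[np.isfinite(mean_img)]
    if finite.size == 0:
        raise ValueError("mean image has no finite pixels")
    if method == "otsu":
        thr = threshold_otsu(finite)
    elif method == "fraction":
        if not 0 < fraction < 1:
            raise ValueError("fraction must be in (0, 1)")
        thr = fraction * finite.max()
    else:
        raise ValueError(f"unknown mask method {method!r}")
    mask = np.isfinite(mean_img) & (mean_img > thr)
    if keep_largest and mask.any():
        labels = measure.label(mask)
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        mask = labels == counts.argmax()
    if not mask.any():
        raise ValueError(f"mask is empty at threshold {thr:g}; "
                         "try a lower threshold")
    return MaskImage(mask)


def apply_mask(video: VideoStack, mask: MaskImage) -> VideoStack:
    """Set pixels outside the mask to NaN (they stay excluded downstream)."""
    if mask.data.shape != video.frame_shape:
        raise ValueError("mask and video spatial shapes differ")
    dtype = video.data.dtype if video.data.dtype.kind == "f" else np.float64
    data = video.data.astype(dtype, copy=True)
    data[:, ~mask.data] = np.nan
    return VideoStack(data, video.frame_rate, video.exposure, video.t0)


def masked_mean_trace(video: VideoStack, mask: MaskImage) -> TraceSeries:
    """Per-frame mean intensity over foreground pixels, ignoring NaNs.

    A frame whose foreground is entirely missing yields NaN in the trace.
    """
    if mask.data.shape != video.frame_shape:
        raise ValueError("mask and video spatial shapes differ")
    fg = video.data[:, mask.data]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN frames
        values = np.nanmean(fg, axis=1)
    return TraceSeries(values, video.frame_rate, label="masked mean",
                       t0=video.t0)


def interpolate_missing(trace: TraceSeries) -> TraceSeries:
    """Linearly interpolate NaNs (edge NaNs take the nearest valid value)."""
    values = trace.values.copy()
    bad = ~np.isfinite(values)
    if bad.all():
        raise ValueError("trace has no finite values to interpolate from")
    if bad.any():
        idx = np.arange(len(values))
        values[bad] = np.interp(idx[bad], idx[~bad], values[~bad])
    return TraceSeries(values, trace.frame_rate, trace.label, trace.t0)


def lowpass_smooth(trace: TraceSeries, cutoff: float = 0.02,
                   order: int = 4) -> TraceSeries:
    """Zero-phase (forward-backward) Butterworth lowpass filtering.

    DC gain is exactly 1 and the output length equals the input length.
    The effective amplitude gain at frequency f is 1 / (1 + (f/fc)^(2n))
    because the filter is applied twice.  Edges are padded by odd
    reflection over several filter time constants so that the slow decay
    is tracked up to the ends of the recording.
    """
    nyquist = trace.frame_rate / 2.0
    if not 0 < cutoff < nyquist:
        raise ValueError(f"cutoff must lie in (0, {nyquist:g}) Hz "
                         f"(Nyquist), got {cutoff:g}")
    if not np.all(np.isfinite(trace.values)):
        raise ValueError("trace contains missing values; "
                         "interpolate_missing() first")
    b, a = signal.butter(order, cutoff, btype="low", fs=trace.frame_rate)
    padlen = int(min(len(trace) - 1, round(3.0 * trace.frame_rate / cutoff)))
    values = signal.filtfilt(b, a, trace.values, padtype="odd", padlen=padlen)
    return TraceSeries(values, trace.frame_rate,
                       label=f"{trace.label} (lowpass {cutoff:g} Hz)",
                       t0=trace.t0)


def decay_correct(video: VideoStack, smoothed: TraceSeries) -> VideoStack:
    """Divide each frame by the smoothed masked-mean intensity.

    Removes the slow substrate rise-and-decay so that the masked mean of
    the corrected stack is ~1 throughout.
    """
    if len(smoothed) != video.n_frames:
        raise ValueError("smoothed trace length differs from frame count")
    bad = np.flatnonzero(~(smoothed.values > 0))
    if bad.size:
        raise ValueError(f"smoothed trace is not strictly positive at frame "
                         f"{bad[0]} (value {smoothed.values[bad[0]]:g})")
    dtype = video.data.dtype if video.data.dtype.kind == "f" else np.float64
    data = video.data.astype(dtype, copy=False) / \
        smoothed.values.astype(dtype, copy=False)[:, None, None]
    return VideoStack(data, video.frame_rate, video.exposure, video.t0)


def epoch_trials(video: VideoStack, schedule: StimulusSchedule,
                 pre_window: float = 2.0, span: float = 20.0) -> TrialTensor:
    """Split the stack into stimulus-locked trials.

    Trial i covers ``[onset_i - pre_window, onset_i - pre_window + span)``
    mapped to frames by nearest-frame rounding.  Trials that would overrun
    the recording are dropped with a logged count.
    """
    if not 0 <= pre_window < span:
        raise ValueError("require 0 <= pre_window < span")
    rate = video.frame_rate
    n_time = int(round(span * rate))
    starts = np.round((np.asarray(schedule.onsets) - pre_window - video.t0)
                      * rate).astype(int)
    keep = (starts >= 0) & (starts + n_time <= video.n_frames)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("epoch_trials: dropped %d of %d trials that fall "
                    "outside the recording", dropped, len(starts))
    if not keep.any():
        raise ValueError("no trial fits inside the recording")
    trials = np.stack([video.data[s:s + n_time] for s in starts[keep]])
    onsets = tuple(np.asarray(schedule.onsets)[keep])
    return TrialTensor(trials, float(pre_window), float(span), rate, onsets)


def normalize_trials(trials: TrialTensor, baseline: float = 1.0) -> TrialTensor:
    """Divide each pixel of each trial by its own pre-stimulus baseline mean.

    The baseline is the first ``baseline`` seconds of the trial (which start
    ``pre_window`` seconds before the stimulus).  Pixels with a nonpositive
    or missing baseline mean become NaN, with a warning giving the count.
    """
    if baseline <= 0 or baseline > trials.pre_window:
        raise ValueError("require 0 < baseline <= pre_window")
    nb = int(round(baseline * trials.frame_rate))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        base = np.nanmean(trials.data[:, :nb], axis=1)
    # pixels that are entirely missing (e.g. outside the mask) stay NaN
    # silently; warn only where real data had a degenerate baseline
    had_data = ~np.isnan(trials.data).all(axis=1)
    invalid = ~(base > 0) & had_data
    if invalid.any():
        warnings.warn(f"{int(invalid.sum())} trial-pixels have nonpositive "
                      "or missing baseline means and were set to NaN",
                      stacklevel=2)
        base = np.where(invalid, np.nan, base)
    data = trials.data / base[:, None]
    return TrialTensor(data, trials.pre_window, trials.span,
                       trials.frame_rate, trials.trial_onsets)


def average_trials(trials: TrialTensor, n_first: int | str = 20) -> np.ndarray:
    """Pointwise mean over the first ``n_first`` trials (NaNs ignored).

    ``n_first='all'`` averages every trial.  Returns a time x rows x cols
    movie of L/L0 ratios.
    """
    if n_first == "all":
        n = trials.n_trials
    else:
        n = int(n_first)
        if n < 1:
            raise ValueError("n_first must be >= 1")
        if n > trials.n_trials:
            raise ValueError(f"n_first={n} exceeds the {trials.n_trials} "
                             "available trials")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(trials.data[:n], axis=0)


def integrate_frames(video: VideoStack, t_start: float,
                     t_end: float) -> np.ndarray:
    """Per-pixel sum of frames with time in ``[t_start, t_end)``."""
    if not t_start < t_end:
        raise ValueError("require t_start < t_end")
    times = video.times
    sel = (times >= t_start) & (times < t_end)
    if not sel.any():
        raise ValueError(f"no frames fall in [{t_start:g}, {t_end:g}) s")
    return video.data[sel].sum(axis=0)


def render_pseudocolor(dl_movie: np.ndarray, vmin: float = -0.3,
                       vmax: float = 0.3, luminance=None,
                       cmap: str = "coolwarm") -> np.ndarray:
    """Map dL/L0 values through a diverging lookup table.

    Values are clamped to ``[vmin, vmax]`` (defaults -0.3 and 0.3) before
    lookup; per-pixel brightness is multiplied by ``luminance`` normalized
    to its own maximum (a 2-D image or a per-frame trace); missing values
    render black.  Returns float RGB in [0, 1] with a trailing axis of 3.
    """
    if not vmin < vmax:
        raise ValueError("require vmin < vmax")
    from matplotlib import colormaps
    lut = colormaps[cmap]
    dl = np.asarray(dl_movie, dtype=float)
    missing = ~np.isfinite(dl)
    normed = np.clip((np.where(missing, 0.0, dl) - vmin) / (vmax - vmin),
                     0.0, 1.0)
    rgb = np.asarray(lut(normed))[..., :3]
    if luminance is not None:
        lum = (luminance.values if isinstance(luminance, TraceSeries)
               else np.asarray(luminance, dtype=float))
        lum = np.clip(lum / np.nanmax(lum), 0.0, 1.0)
        lum = np.where(np.isfinite(lum), lum, 0.0)
        if lum.ndim == 1:                      # per-frame modulation
            lum = lum.reshape((-1,) + (1,) * (dl.ndim - 1))
        rgb = rgb * lum[..., None]
    rgb[missing] = 0.0
    return rgb


@dataclass
class AnalysisResult:
    """Everything the chain produces for one recording."""

    mask: MaskImage
    raw_trace: TraceSeries
    smoothed_trace: TraceSeries
    trials: TrialTensor
    movie: np.ndarray            # time x rows x cols, L/L0 ratios
    n_trials_averaged: int
    n_trials_dropped: int
    params: dict


def analyze_stack(video: VideoStack, schedule: StimulusSchedule, *,
                  dark=0.0, mask: MaskImage | None = None,
                  mask_method: str = "otsu",
                  pre_window: float = 2.0, span: float = 20.0,
                  baseline: float = 1.0, n_first: int | str = 20,
                  cutoff: float = 0.02, order: int = 4) -> AnalysisResult:
    """Run the full chain from raw stack to trial-averaged L/L0 movie."""
    sub = subtract_dark(video, dark)
    if mask is None:
        mask = compute_head_mask(sub, method=mask_method)
    masked = apply_mask(sub, mask)
    raw_trace = masked_mean_trace(masked, mask)
    smoothed = lowpass_smooth(interpolate_missing(raw_trace),
                              cutoff=cutoff, order=order)
    corrected = decay_correct(masked, smoothed)
    trials = epoch_trials(corrected, schedule, pre_window, span)
    dropped = schedule.n_cycles - trials.n_trials
    normed = normalize_trials(trials, baseline)
    movie = average_trials(normed, n_first)
    n_used = normed.n_trials if n_first == "all" else int(n_first)
    params = dict(dark=float(np.mean(dark)), pre_window=pre_window, span=span,
                  baseline=baseline, n_first=n_first, cutoff=cutoff,
                  order=order, mask_method=mask_method,
                  n_trials_dropped=dropped)
    return AnalysisResult(mask, raw_trace, smoothed, normed, movie,
                          n_used, dropped, params)
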