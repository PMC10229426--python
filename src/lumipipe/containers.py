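"""Core in-memory containers shared across the package.

All image data are plain numpy arrays wrapped with the minimal acquisition
metadata needed to convert frame indices to seconds.  Frame ``f`` of a
:class:`VideoStack` corresponds to time ``t0 + f / frame_rate`` (0-based).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VideoStack", "MaskImage", "TraceSeries", "TrialTensor"]


@dataclass
class VideoStack:
    """A frames x rows x cols intensity stack with frame timing metadata.

    Missing values (NaN) are allowed and are propagated, never silently
    replaced, by every downstream operation.
    """

    data: np.ndarray
    frame_rate: float
    exposure: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError("video data must be a (frames, rows, cols) array "
                             "with at least one frame")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")
        if not self.exposure > 0:
            raise ValueError("exposure must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of each frame in seconds."""
        return self.t0 + np.arange(self.n_frames) / self.frame_rate


@dataclass
class MaskImage:
    """A static boolean foreground mask with the same spatial shape as its
    source stack."""

    data: np.ndarray
    n_foreground: int = field(init=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 2:
            raise ValueError("mask must be a 2-D boolean image")
        self.n_foreground = int(self.data.sum())
        if self.n_foreground < 1:
            raise ValueError("mask has no foreground pixels")


@dataclass
class TraceSeries:
    """A per-frame scalar time series (e.g. the masked mean intensity)."""

    values: np.ndarray
    frame_rate: float
    label: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace values must be 1-D")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) / self.frame_rate


@dataclass
class TrialTensor:
    """Trials x time x rows x cols stack of L/L0 ratios.

    Values are stored as ratios; the fractional change dL/L0 = ratio - 1 is
    applied only at the statistics / rendering boundary.  The time axis of
    trial ``i`` covers ``[onset_i - pre_window, onset_i - pre_window + span)``.
    """

    data: np.ndarray
    pre_window: float
    span: float
    frame_rate: float
    trial_onsets: tuple[float, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("trial tensor must be (trials, time, rows, cols)")
        self.trial_onsets = tuple(float(t) for t in self.trial_onsets)
        if self.data.shape[0] != len(self.trial_onsets):
            raise ValueError("one onset per trial required")
        expected = int(round(self.span * self.frame_rate))
        if self.data.shape[1] != expected:
            raise ValueError(
                f"time axis has {self.data.shape[1]} frames, expected "
                f"round(span * frame_rate) = {expected}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    @property
    def trial_times(self) -> np.ndarray:
        """Within-trial times in seconds relative to stimulus onset."""
        return np.arange(self.n_timepoints) / self.frame_rate - self.pre_window
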