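"""Synthetic head-fixed mouse-brain bioluminescence recordings.

Emulates wide-field EM-CCD video of a luciferase-expressing mouse head:
a slow rise-and-decay of global brightness governed by substrate
pharmacokinetics (one-compartment absorption/elimination), stimulus-locked
fractional modulations -- a late hemodynamic component and an optional early
calcium component -- applied uniformly (bilaterally) inside an elliptical
head profile on a dark field, and shot noise with EM-gain excess noise plus
Gaussian read noise.  Each simulation also returns the exact component
traces and true head mask it used, so every downstream analysis stage can
be validated against ground truth.

Simulated counts are arbitrary camera units; no absolute radiometric
calibration is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .containers import VideoStack

__all__ = [
    "SubstrateKinetics",
    "CalciumIndicatorModel",
    "ResponseKernel",
    "CameraModel",
    "StimulusSchedule",
    "HeadGeometry",
    "SimulationTruth",
    "make_stimulus_schedule",
    "substrate_trace",
    "calcium_to_brightness",
    "kernel_traces",
    "simulate_video",
]


@dataclass(frozen=True)
class SubstrateKinetics:
    """One-compartment absorption/elimination (Bateman) brightness kinetics.

    Parameters
    ----------
    amplitude
        Photon-rate scale factor: expected photons/s per pixel at the head
        profile peak, before camera gain (arbitrary units).
    k_abs, k_elim
        Absorption and elimination rate constants, 1/min.  Defaults place
        the brightness peak ~4 min after injection.
    t_offset
        Delay between substrate injection and acquisition start, s.  The
        trace is zero at and before the injection instant.
    """

    amplitude: float = 1500.0
    k_abs: float = 0.45
    k_elim: float = 0.11
    t_offset: float = 60.0

    def __post_init__(self) -> None:
        if not self.amplitude > 0:
            raise ValueError("amplitude must be > 0")
        if not (self.k_abs > 0 and self.k_elim > 0):
            raise ValueError("k_abs and k_elim must be > 0")

    def peak_time(self) -> float:
        """Closed-form time of peak brightness, seconds since injection."""
        ka, ke = self.k_abs, self.k_elim
        if math.isclose(ka, ke, rel_tol=1e-12):
            return 60.0 / ka
        return 60.0 * math.log(ka / ke) / (ka - ke)


def substrate_trace(kinetics: SubstrateKinetics, times: np.ndarray) -> np.ndarray:
    """Evaluate the Bateman rise-and-decay brightness factor.

    ``times`` are seconds from acquisition start (injection occurred
    ``t_offset`` seconds earlier).  The equal-rate case k_abs == k_elim is
    evaluated through its analytic limit ``k * t * exp(-k t)``.
    """
    times = np.asarray(times, dtype=float)
    if times.size and np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    tau = (times + kinetics.t_offset) / 60.0  # minutes since injection
    ka, ke = kinetics.k_abs, kinetics.k_elim
    out = np.zeros_like(tau)
    pos = tau > 0
    t = tau[pos]
    if math.isclose(ka, ke, rel_tol=1e-9):
        out[pos] = kinetics.amplitude * ka * t * np.exp(-ka * t)
    else:
        out[pos] = (kinetics.amplitude * ka / (ka - ke)
                    * (np.exp(-ke * t) - np.exp(-ka * t)))
    return out


@dataclass(frozen=True)
class CalciumIndicatorModel:
    """Hill-binding brightness model of a bioluminescent calcium indicator.

    Defaults describe the CaMBI110 indicator: dissociation constant 110 nM
    and an eightfold saturated-to-apo brightness ratio, with one-site
    (Hill coefficient 1) binding.
    """

    kd: float = 110.0           # nM
    dynamic_range: float = 8.0  # saturated / apo brightness
    hill_n: float = 1.0

    def __post_init__(self) -> None:
        if not self.kd > 0:
            raise ValueError("kd must be > 0")
        if not self.dynamic_range >= 1:
            raise ValueError("dynamic_range must be >= 1")
        if not self.hill_n > 0:
            raise ValueError("hill_n must be > 0")


def calcium_to_brightness(ca_conc, model: CalciumIndicatorModel):
    """Brightness multiplier at free-calcium concentration ``ca_conc`` (nM).

    multiplier = 1 + (R - 1) * ca^n / (ca^n + Kd^n), which runs from 1 in
    the apo state to the dynamic range R at saturation.  ``np.inf`` is
    accepted and returns R exactly.
    """
    ca = np.asarray(ca_conc, dtype=float)
    if np.any(ca < 0):
        raise ValueError("calcium concentration must be >= 0")
    with np.errstate(over="ignore", invalid="ignore"):
        x = ca ** model.hill_n
        occ = x / (x + model.kd ** model.hill_n)
    occ = np.where(np.isinf(ca), 1.0, occ)  # saturating limit, exactly
    out = 1.0 + (model.dynamic_range - 1.0) * occ
    return float(out) if np.isscalar(ca_conc) else out


@dataclass(frozen=True)
class ResponseKernel:
    """A stimulus-locked fractional (dL/L0) response waveform.

    The kernel is causal (zero before ``onset_delay`` after the stimulus),
    nonnegative, peaks ``latency_to_peak`` seconds after the stimulus, and
    has finite support ``[onset_delay, onset_delay + duration]``.

    Two shapes are provided:

    * ``hemodynamic`` -- a gamma-variate in delayed time, emulating the
      blood-flow-driven luminescence increase that occurs 2-6 s after a
      stimulus and peaks 2-4 s after it;
    * ``calcium`` -- a difference of exponentials (rise ``tau_rise``,
      decay ``tau_decay``) peaking ~1 s after the stimulus, emulating the
      fast indicator response to a calcium transient.
    """

    kind: Literal["hemodynamic", "calcium"]
    amplitude: float
    onset_delay: float
    latency_to_peak: float
    duration: float
    alpha: float | None = None      # gamma-variate shape (hemodynamic)
    tau_rise: float | None = None   # s (calcium)
    tau_decay: float | None = None  # s (calcium)

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0 (kernels are nonnegative)")
        if self.onset_delay < 0:
            raise ValueError("onset_delay must be >= 0 (kernels are causal)")
        if not self.duration > 0:
            raise ValueError("duration must be > 0")
        if not self.onset_delay < self.latency_to_peak <= self.onset_delay + self.duration:
            raise ValueError("latency_to_peak must lie inside the kernel support")
        if self.kind == "hemodynamic" and not (self.alpha and self.alpha > 0):
            raise ValueError("hemodynamic kernel requires alpha > 0")
        if self.kind == "calcium":
            if not (self.tau_rise and self.tau_decay):
                raise ValueError("calcium kernel requires tau_rise and tau_decay")
            if not 0 < self.tau_rise < self.tau_decay:
                raise ValueError("require 0 < tau_rise < tau_decay")

    @classmethod
    def hemodynamic(cls, amplitude: float = 0.10, onset_delay: float = 2.0,
                    latency_to_peak: float = 3.0, duration: float = 4.0,
                    alpha: float = 2.0) -> "ResponseKernel":
        """Default late response: support [2, 6] s, peak 3 s, peak dL/L0 0.10."""
        return cls("hemodynamic", amplitude, onset_delay, latency_to_peak,
                   duration, alpha=alpha)

    @classmethod
    def calcium(cls, amplitude: float = 0.10, latency_to_peak: float = 1.0,
                duration: float = 10.0, tau_ratio: float = 4.0) -> "ResponseKernel":
        """Default early response: difference of exponentials peaking at
        ``latency_to_peak`` with decay/rise time-constant ratio ``tau_ratio``."""
        # peak time of e^{-t/td} - e^{-t/tr} is ln(td/tr) * tr*td/(td-tr)
        tau_rise = latency_to_peak * (tau_ratio - 1.0) / (tau_ratio * math.log(tau_ratio))
        return cls("calcium", amplitude, 0.0, latency_to_peak, duration,
                   tau_rise=tau_rise, tau_decay=tau_ratio * tau_rise)

    def evaluate(self, t) -> np.ndarray:
        """Kernel value at time ``t`` (s) after the stimulus onset."""
        t = np.asarray(t, dtype=float)
        tp = t - self.onset_delay
        inside = (tp >= 0) & (tp <= self.duration)
        out = np.zeros_like(t)
        if self.kind == "hemodynamic":
            tpk = self.latency_to_peak - self.onset_delay
            x = np.where(inside, tp / tpk, 0.0)
            out[inside] = (x[inside] ** self.alpha
                           * np.exp(self.alpha * (1.0 - x[inside])))
        else:
            tr, td = self.tau_rise, self.tau_decay
            tstar = math.log(td / tr) * tr * td / (td - tr)
            norm = math.exp(-tstar / td) - math.exp(-tstar / tr)
            out[inside] = (np.exp(-tp[inside] / td)
                           - np.exp(-tp[inside] / tr)) / norm
        return self.amplitude * out


@dataclass(frozen=True)
class CameraModel:
    """EM-CCD acquisition parameters and noise statistics.

    Noise model: with per-pixel expected photon count ``lam`` per frame,

        counts = dark_offset + g * (lam + F * (Poisson(lam) - lam)) + N(0, read_noise_sd)

    where ``g`` is the EM gain and ``F`` the excess noise factor, so the
    mean is ``dark_offset + g * lam`` (unbiased) and the variance grows as
    ``g^2 * F^2 * lam + read_noise_sd^2``, the standard EM-CCD behaviour.
    """

    exposure: float = 0.2
    frame_rate: float = 5.0
    binning: int = 4
    em_gain: float = 30.0
    read_noise_sd: float = 10.0
    excess_noise_factor: float = math.sqrt(2.0)
    dark_offset: float = 100.0

    def __post_init__(self) -> None:
        if not (self.exposure > 0 and self.frame_rate > 0):
            raise ValueError("exposure and frame_rate must be > 0")
        if self.frame_rate * self.exposure > 1.0 + 1e-12:
            raise ValueError("frame_rate * exposure must be <= 1")
        if self.binning < 1 or int(self.binning) != self.binning:
            raise ValueError("binning must be a positive integer")
        if min(self.em_gain, self.read_noise_sd, self.excess_noise_factor,
               self.dark_offset) < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass(frozen=True)
class StimulusSchedule:
    """Regularly spaced stimulus onsets (s from acquisition start)."""

    onsets: tuple[float, ...]
    on_duration: float
    cycle_length: float
    n_cycles: int

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        object.__setattr__(self, "onsets", tuple(onsets))
        if len(onsets) != self.n_cycles or self.n_cycles < 1:
            raise ValueError("n_cycles must match the number of onsets (>= 1)")
        if len(onsets) > 1:
            gaps = np.diff(onsets)
            if np.any(gaps <= 0):
                raise ValueError("onsets must be strictly increasing")
            if not np.allclose(gaps, self.cycle_length):
                raise ValueError("consecutive onsets must be separated by "
                                 "exactly cycle_length")
        if not 0 < self.on_duration < self.cycle_length:
            raise ValueError("require 0 < on_duration < cycle_length")

    @property
    def end_time(self) -> float:
        """Time at which the last cycle completes."""
        return self.onsets[-1] + self.cycle_length


def make_stimulus_schedule(n_cycles: int, on_duration: float,
                           off_duration: float,
                           start_delay: float = 0.0) -> StimulusSchedule:
    """Build the periodic stimulation schedule used in head-fixed imaging.

    The default experiment applies 57 cycles of a 1 s foot vibration
    followed by 19 s rest, starting 60 s into the acquisition:
    ``make_stimulus_schedule(57, 1, 19, 60)``.
    """
    if int(n_cycles) != n_cycles or n_cycles < 1:
        raise ValueError("n_cycles must be an integer >= 1")
    if not (on_duration > 0 and off_duration > 0):
        raise ValueError("on_duration and off_duration must be > 0")
    if start_delay < 0:
        raise ValueError("start_delay must be >= 0")
    cycle = on_duration + off_duration
    onsets = start_delay + cycle * np.arange(int(n_cycles))
    return StimulusSchedule(tuple(onsets), float(on_duration), float(cycle),
                            int(n_cycles))


@dataclass(frozen=True)
class HeadGeometry:
    """Elliptical head profile with smooth edge falloff on a dark field.

    The profile is a super-Gaussian ``exp(-ln 2 * rho^(2 * edge_power))`` of
    the normalized elliptical radius ``rho``, equal to 1 at the center and
    0.5 on the ellipse boundary; the true head mask is ``rho <= 1``.
    """

    shape: tuple[int, int] = (64, 64)
    center: tuple[float, float] | None = None
    semi_axes: tuple[float, float] = (18.0, 24.0)
    edge_power: float = 4.0

    def profile(self) -> np.ndarray:
        rows, cols = self.shape
        cr, cc = self.center if self.center is not None else ((rows - 1) / 2,
                                                              (cols - 1) / 2)
        rr, cc_ = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        rho2 = ((rr - cr) / self.semi_axes[0]) ** 2 + \
               ((cc_ - cc) / self.semi_axes[1]) ** 2
        return np.exp(-math.log(2.0) * rho2 ** self.edge_power)

    def mask_true(self) -> np.ndarray:
        return self.profile() >= 0.5


@dataclass
class SimulationTruth:
    """Ground-truth components emitted alongside a simulated video."""

    substrate_trace: np.ndarray   # photons/s at profile peak, per frame
    hemo_trace: np.ndarray        # fractional modulation, per frame
    calcium_trace: np.ndarray     # fractional modulation, per frame
    head_mask_true: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        n = len(self.substrate_trace)
        if not (len(self.hemo_trace) == len(self.calcium_trace) == n):
            raise ValueError("truth traces must have equal length")
        if not np.any(self.head_mask_true):
            raise ValueError("true head mask is empty")

    @property
    def modulation(self) -> np.ndarray:
        """1 + hemodynamic + calcium fractional modulation per frame."""
        return 1.0 + self.hemo_trace + self.calcium_trace


def kernel_traces(kernels: Sequence[ResponseKernel],
                  schedule: StimulusSchedule,
                  times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sum each kernel over all stimulus onsets, split by kind."""
    times = np.asarray(times, dtype=float)
    hemo = np.zeros_like(times)
    calcium = np.zeros_like(times)
    for kernel in kernels:
        acc = hemo if kernel.kind == "hemodynamic" else calcium
        for onset in schedule.onsets:
            acc += kernel.evaluate(times - onset)
    return hemo, calcium


def simulate_video(kinetics: SubstrateKinetics,
                   camera: CameraModel,
                   schedule: StimulusSchedule,
                   geometry: HeadGeometry = HeadGeometry(),
                   kernels: Sequence[ResponseKernel] = (),
                   seed: int = 0,
                   duration: float | None = None,
                   noise: bool = True) -> tuple[VideoStack, SimulationTruth]:
    """Simulate a stimulus-locked bioluminescence recording.

    The per-pixel expected photon count of frame ``f`` at time ``t`` is

        profile * substrate_trace(t) * (1 + hemo(t) + calcium(t)) * exposure

    to which the camera model adds gain, excess-noise-scaled shot noise and
    Gaussian read noise (see :class:`CameraModel`).  ``duration`` defaults
    to the end of the last stimulus cycle.  Identical parameters and seed
    give bit-identical stacks.

    Returns the video (float32 counts when noisy, float64 expectation when
    ``noise=False``) together with the ground-truth traces.
    """
    rate = camera.frame_rate
    if duration is None:
        duration = schedule.end_time
    n_frames = int(round(duration * rate))
    if n_frames < 1:
        raise ValueError("duration too short for a single frame")
    times = np.arange(n_frames) / rate
    if schedule.onsets[-1] > times[-1]:
        fitting = [o for o in schedule.onsets if o <= times[-1]]
        last = f"{fitting[-1]:g} s" if fitting else "none"
        raise ValueError(
            f"stimulus schedule extends past the video end ({times[-1]:g} s); "
            f"last onset that fits: {last}")

    substrate = substrate_trace(kinetics, times)
    hemo, calcium = kernel_traces(kernels, schedule, times)
    modulation = 1.0 + hemo + calcium

    profile = geometry.profile()
    scale = camera.exposure * substrate * modulation

    if noise:
        # float32 is ample for simulated counts and halves the memory traffic
        rng = np.random.default_rng(seed)
        g, fx = np.float32(camera.em_gain), np.float32(camera.excess_noise_factor)
        lam = scale.astype(np.float32)[:, None, None] * \
            profile.astype(np.float32)
        shot = rng.poisson(lam).astype(np.float32)
        shot -= lam
        data = np.float32(camera.dark_offset) + g * (lam + fx * shot)
        if camera.read_noise_sd > 0:
            noise_arr = rng.standard_normal(data.shape, dtype=np.float32)
            noise_arr *= np.float32(camera.read_noise_sd)
            data += noise_arr
        np.clip(data, 0.0, None, out=data)
    else:
        lam = scale[:, None, None] * profile
        data = camera.dark_offset + camera.em_gain * lam

    video = VideoStack(data=data, frame_rate=rate, exposure=camera.exposure)
    truth = SimulationTruth(substrate, hemo, calcium, geometry.mask_true(),
                            int(seed))
    return video, truth
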