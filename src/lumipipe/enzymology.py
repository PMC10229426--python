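"""Michaelis-Menten fitting, relative kcat, binding curves, spectra.

Substrate titrations are fit to v = Vmax * S / (Km + S) by unweighted
nonlinear least squares, seeded from the Lineweaver-Burk linearization and
guarded by multistarts.  At matched enzyme concentration, relative kcat
between two substrates is the ratio of their fitted Vmax values.  The same
machinery fits one-site (Hill) binding curves, e.g. the brightness of a
calcium indicator versus free calcium, returning the dissociation constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "TitrationData",
    "MMFitResult",
    "RatioResult",
    "BindingFitResult",
    "EmissionSpectrum",
    "twofold_dilution_series",
    "simulate_titration",
    "fit_michaelis_menten",
    "relative_kcat",
    "fit_binding_curve",
    "normalize_emission_spectrum",
]


def twofold_dilution_series(top: float = 15.0, n_levels: int = 8) -> np.ndarray:
    """Final assay concentrations (uM) of a serial twofold dilution.

    The standard design dilutes substrate to twice the top concentration,
    steps down twofold, then mixes 1:1 with enzyme, so the top final
    concentration defaults to 15 uM.
    """
    return top / 2.0 ** np.arange(n_levels)


@dataclass
class TitrationData:
    """One substrate-enzyme titration: concentration vs luminescence."""

    concentrations: np.ndarray   # uM, final
    luminescence: np.ndarray     # instrument units
    replicate_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.luminescence = np.asarray(self.luminescence, dtype=float)
        if self.concentrations.shape != self.luminescence.shape:
            raise ValueError("concentrations and luminescence must match")
        if np.any(self.concentrations < 0) or np.any(self.luminescence < 0):
            raise ValueError("concentrations and luminescence must be >= 0")
        if len(np.unique(self.concentrations)) < 5:
            raise ValueError("need at least 5 distinct concentration levels")
        if self.replicate_id is None:
            self.replicate_id = np.zeros(len(self.concentrations), dtype=int)
        else:
            self.replicate_id = np.asarray(self.replicate_id)

    @classmethod
    def from_csv(cls, path) -> "TitrationData":
        """Read columns concentration_uM, luminescence[, replicate]."""
        df = pd.read_csv(path)
        rep = df["replicate"].to_numpy() if "replicate" in df else None
        return cls(df["concentration_uM"].to_numpy(),
                   df["luminescence"].to_numpy(), rep)

    def to_csv(self, path) -> None:
        pd.DataFrame({"concentration_uM": self.concentrations,
                      "luminescence": self.luminescence,
                      "replicate": self.replicate_id}).to_csv(path,
                                                              index=False)


@dataclass
class MMFitResult:
    """Fitted Vmax/Km with standard errors for one titration."""

    vmax: float                # instrument units
    km: float                  # uM
    vmax_se: float
    km_se: float
    rss: float
    n_points: int

    def predict(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        return self.vmax * s / (self.km + s)


@dataclass
class RatioResult:
    """A ratio of fitted parameters with its propagated standard error."""

    value: float
    se: float


@dataclass
class BindingFitResult:
    """One-site (Hill) binding fit of a response vs ligand concentration."""

    kd: float
    response_apo: float
    response_sat: float
    kd_se: float
    rss: float


def simulate_titration(vmax: float, km: float,
                       concentrations: np.ndarray | None = None,
                       n_replicates: int = 3, noise_cv: float = 0.05,
                       rng: np.random.Generator | None = None) -> TitrationData:
    """Generate a titration from known (Vmax, Km) with multiplicative noise.

    Defaults mimic the standard plate design: an 8-level twofold dilution
    from 15 uM, three technical replicates, 5% multiplicative noise.
    """
    if concentrations is None:
        concentrations = twofold_dilution_series()
    conc = np.tile(np.asarray(concentrations, dtype=float), n_replicates)
    rep = np.repeat(np.arange(n_replicates), len(concentrations))
    v = vmax * conc / (km + conc)
    if noise_cv > 0:
        if rng is None:
            rng = np.random.default_rng()
        v = np.clip(v * (1.0 + noise_cv * rng.standard_normal(v.shape)),
                    0.0, None)
    return TitrationData(conc, v, rep)


def _michaelis_menten(s, vmax, km):
    return vmax * s / (km + s)


def _lineweaver_burk_seed(s, v) -> tuple[float, float]:
    ok = (s > 0) & (v > 0)
    if ok.sum() >= 2:
        slope, intercept = np.polyfit(1.0 / s[ok], 1.0 / v[ok], 1)
        if intercept > 0 and slope > 0:
            vmax0 = 1.0 / intercept
            return vmax0, slope * vmax0
    return float(np.max(v)) if np.max(v) > 0 else 1.0, float(np.median(s[s > 0]))


def fit_michaelis_menten(data: TitrationData) -> MMFitResult:
    """Unweighted least-squares Michaelis-Menten fit of pooled points.

    Deterministic given the data: the Lineweaver-Burk linearization
    provides the seed and five scaled multistarts guard against local
    minima; the lowest-RSS converged fit wins.  Warns when the fitted Km
    falls outside the concentration range spanned by the data.
    """
    s, v = data.concentrations, data.luminescence
    vmax0, km0 = _lineweaver_burk_seed(s, v)
    starts = [(vmax0, km0), (0.3 * vmax0, 3 * km0), (3 * vmax0, 0.3 * km0),
              (0.5 * vmax0, 0.5 * km0), (2 * vmax0, 2 * km0)]
    best = None
    failures = []
    for p0 in starts:
        try:
            popt, pcov = curve_fit(_michaelis_menten, s, v, p0=p0,
                                   bounds=(1e-12, np.inf), maxfev=20000)
        except (RuntimeError, ValueError) as exc:
            failures.append(f"{p0}: {exc}")
            continue
        rss = float(np.sum((v - _michaelis_menten(s, *popt)) ** 2))
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)
    if best is None:
        raise RuntimeError("Michaelis-Menten fit failed to converge from "
                           "all starts: " + "; ".join(failures))
    (vmax, km), pcov, rss = best
    se = np.sqrt(np.diag(pcov))
    positive = s[s > 0]
    if km > positive.max() or km < positive.min():
        warnings.warn(f"fitted Km = {km:.3g} uM lies outside the assayed "
                      f"range [{positive.min():.3g}, {positive.max():.3g}] uM "
                      "and is poorly constrained", stacklevel=2)
    return MMFitResult(float(vmax), float(km), float(se[0]), float(se[1]),
                       rss, len(s))


def relative_kcat(fit_a: MMFitResult, fit_b: MMFitResult,
                  enzyme_conc_equal: bool) -> RatioResult:
    """Relative turnover number of substrate a vs b: Vmax_a / Vmax_b.

    Valid only when both titrations used the same enzyme concentration
    (``enzyme_conc_equal`` asserts this); the standard error is propagated
    from the two Vmax standard errors assuming independence.
    """
    if not enzyme_conc_equal:
        raise ValueError("relative kcat is undefined unless both fits come "
                         "from the same enzyme concentration")
    ratio = fit_a.vmax / fit_b.vmax
    se = abs(ratio) * np.hypot(fit_a.vmax_se / fit_a.vmax,
                               fit_b.vmax_se / fit_b.vmax)
    return RatioResult(float(ratio), float(se))


def fit_binding_curve(concentrations, response,
                      hill_n: float = 1.0) -> BindingFitResult:
    """Least-squares one-site (fixed Hill coefficient) binding fit.

    Model: y = y_apo + (y_sat - y_apo) * c^n / (c^n + Kd^n).  Returns the
    fitted dissociation constant with its standard error.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(response, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")
    if len(c) < 3:
        raise ValueError("need at least 3 points to fit 3 parameters")

    def model(x, y0, y1, kd):
        xn = x ** hill_n
        return y0 + (y1 - y0) * xn / (xn + kd ** hill_n)

    y0_seed, y1_seed = float(y.min()), float(y.max())
    half = 0.5 * (y0_seed + y1_seed)
    order = np.argsort(c)
    kd_seed = float(np.interp(half, y[order], c[order]))
    if not kd_seed > 0:
        kd_seed = float(np.median(c[c > 0]))
    popt, pcov = curve_fit(model, c, y, p0=(y0_seed, y1_seed, kd_seed),
                           bounds=([-np.inf, -np.inf, 1e-12],
                                   [np.inf, np.inf, np.inf]), maxfev=20000)
    rss = float(np.sum((y - model(c, *popt)) ** 2))
    kd_se = float(np.sqrt(pcov[2, 2]))
    return BindingFitResult(float(popt[2]), float(popt[0]), float(popt[1]),
                            kd_se, rss)


@dataclass
class EmissionSpectrum:
    """Wavelength (nm) vs intensity, within the 400-750 nm measurement range."""

    wavelengths: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.shape != self.intensities.shape:
            raise ValueError("wavelengths and intensities must match")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.wavelengths.min() < 400 or self.wavelengths.max() > 750:
            raise ValueError("wavelengths must lie within 400-750 nm")

    @classmethod
    def from_csv(cls, path) -> "EmissionSpectrum":
        df = pd.read_csv(path)
        return cls(df["wavelength_nm"].to_numpy(),
                   df["intensity"].to_numpy())

    @property
    def peak_wavelength(self) -> float:
        return float(self.wavelengths[int(np.argmax(self.intensities))])


def normalize_emission_spectrum(spec: EmissionSpectrum) -> EmissionSpectrum:
    """Divide intensities by the maximum so the peak equals 1."""
    peak = float(np.max(spec.intensities))
    if not peak > 0:
        raise ValueError("spectrum has no positive intensity to normalize by")
    return EmissionSpectrum(spec.wavelengths.copy(),
                            spec.intensities / peak)
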