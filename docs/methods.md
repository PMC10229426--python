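# Methods

`lumipipe` implements the analysis chain used for stimulus-locked,
non-invasive bioluminescence imaging (BLI) of the awake mouse brain, the
statistics that separate a fast calcium-indicator response from the slower
hemodynamic response, and the enzymological models (Michaelis–Menten
kinetics, one-site indicator binding) that characterize the luciferase
substrates and reporters involved.  Because no public recordings of this
kind exist, the package ships a first-class simulator whose every output
component is returned as ground truth; all quantitative claims made by the
test suite are claims about recovery of that ground truth.

## The imaging model

A head-fixed mouse expressing a luciferase (or a calcium-modulated
luciferase indicator) in cortex receives a luciferin substrate injection
and is filmed by an EM-CCD at 5 Hz (200 ms exposure).  The expected photon
count of pixel *(r, c)* in the frame at time *t* is modeled as

    lam(r, c, t) = P(r, c) * S(t) * (1 + h(t) + g(t)) * T_exp

* **P** — a static elliptical head profile with smooth (super-Gaussian)
  edge falloff on a dark field, peak normalized to 1.  The true head mask
  is the ellipse interior (profile >= 0.5).
* **S(t)** — substrate pharmacokinetics: a one-compartment
  absorption/elimination (Bateman) curve
  `A * k_abs/(k_abs − k_elim) * (exp(−k_elim τ) − exp(−k_abs τ))` in time
  since injection τ, with the analytic limit `A k τ exp(−k τ)` when the
  rates coincide.  Defaults `k_abs = 0.45 /min`, `k_elim = 0.11 /min`
  place the brightness peak ≈ 4.1 min after injection, matching the
  reported peak window of roughly 4–5 min for this substrate class;
  `t_offset = 60 s` reflects imaging that begins one minute before the
  stimulation block.  `A = 1500 photons/s/pixel` at the profile peak is a
  plausible low-light EM-CCD operating point; counts are arbitrary camera
  units (no radiometric calibration is attempted).
* **h(t)** — the hemodynamic response: a gamma-variate in delayed time
  with onset delay 2 s, peak 3 s, support [2, 6] s (duration 4 s), shape
  α = 2, peak amplitude 0.10 (fractional dL/L0).  The delay encodes the
  observation that the blood-flow-driven luminescence increase occupies
  2–6 s after the stimulus; without it a gamma-variate peaking at 3 s is
  already at 80% of peak by 2 s and would contaminate the early window.
* **g(t)** — the calcium-indicator response: a difference of exponentials
  (decay/rise time-constant ratio 4) peaking 1 s after the stimulus,
  truncated at 10 s, peak amplitude 0.10.  Both kernels are summed over
  all stimulus onsets (1 s on / 19 s off, 57 cycles by default, first
  onset 60 s into acquisition).

**Camera noise.**  With EM gain *g* and excess noise factor *F* (default
√2, the standard high-gain EM-register limit), simulated counts are

    dark + g * (lam + F * (Poisson(lam) − lam)) + N(0, read_sd)

which is unbiased (mean `dark + g·lam`) with variance
`g²F²·lam + read_sd²`, the textbook EM-CCD behaviour.  Defaults:
`g = 30`, `read_sd = 10` counts, `dark = 100` counts.  The stack is
clipped at zero (a real camera cannot report negative counts), which
rectifies read noise in empty background pixels; the tests account for
this (the background residual after dark subtraction is positive but
below one read-noise SD).

**Calcium indicator.**  Brightness of the indicator is
`1 + (R − 1) · ca^n / (ca^n + Kd^n)` with defaults `Kd = 110 nM`,
`R = 8` (eightfold saturated-to-apo response) and Hill coefficient
`n = 1`: one-site binding is the minimal model consistent with a reported
Kd and fold response.  `ca = ∞` is accepted and returns `R` exactly.

## The analysis chain

1. **Dark subtraction**, clipped at zero.
2. **Head mask**: Otsu's threshold on the temporal-mean image, keeping the
   largest connected component (a fixed-fraction threshold is available).
   One static mask per recording; pixels outside become NaN and are
   excluded from every downstream mean.
3. **Decay correction**: the masked mean intensity per frame is smoothed
   with a zero-phase (forward–backward) Butterworth lowpass filter and
   every frame is divided by the smoothed value.  Defaults: order 4,
   cutoff 0.02 Hz.  The cutoff sits well below the 0.05 Hz stimulus-cycle
   frequency — the effective two-pass gain there is
   `1/(1 + (0.05/0.02)^8) ≈ 6.6e−4` — so the correction tracks substrate
   decay without absorbing stimulus-locked responses, and the zero-phase
   application avoids lag that would leak decay into dL/L0.  Edges are
   padded by odd reflection over `3/cutoff` seconds.
4. **Epoching**: trials cover `[onset − 2 s, onset + 18 s)` (20 s, the
   cycle length), mapped to frames by nearest-frame rounding (0-based,
   half-open windows).  Trials that would overrun the recording are
   dropped and counted.
5. **Normalization**: each pixel of each trial is divided by its own mean
   over the first second of the trial; values are stored as L/L0 ratios,
   and dL/L0 = ratio − 1 is applied only at the statistics/rendering
   boundary (avoiding double-offset bugs).  Pixels with nonpositive
   baselines become NaN with a warning; all-NaN (masked-out) pixels pass
   silently.
6. **Averaging**: pointwise mean of the first 20 trials by default (all
   trials selectable), NaNs ignored.
7. **Rendering**: dL/L0 clamped to [−0.3, 0.3], mapped through a diverging
   lookup table, brightness optionally modulated by normalized luminance;
   missing values render black.

**Response statistics.**  The trial-averaged movie is reduced to a
cortical dL/L0 trace (mean over the mask, time re-zeroed at stimulus
onset).  The trace is then **re-zeroed to its mean over [−1, 0) s**:
ratio normalization against a short noisy baseline is biased upward by
≈ `var(B)/E[B]²` (Jensen's inequality), a constant offset shared by every
frame outside the normalization window.  Frames inside the window sit at
zero by construction, so the offset is estimated from the pre-stimulus
second outside it.  This is the usual dF/F practice of measuring response
areas relative to the pre-stimulus level; without it, one-sample tests on
response areas would reject on normalization bias rather than signal.
Early and late areas are trapezoidal integrals over [0, 2] s and
[2, 6] s (the late right edge is configurable; reports carry both
windows).  Groups are compared with the pooled-variance Student's t-test
(df = n_a + n_b − 2) or the paired t-test, two-tailed; a zero-variance
comparison with equal means returns t = 0, p = 1 by convention.

**Enzymology.**  Titrations (by default an 8-level twofold dilution from
15 µM final, three pooled technical replicates) are fit to
`v = Vmax·S/(Km + S)` by unweighted nonlinear least squares — the
Lineweaver–Burk linearization seeds five multistarts and the lowest-RSS
converged fit wins, making the fit deterministic given the data.  Relative
kcat between substrates at matched enzyme concentration is the Vmax ratio
with independence-propagated standard error.  Emission spectra
(400–750 nm) are normalized to unit peak.

## Numerical behaviour and steady state

The decay-correction filter has a memory of roughly `1/cutoff = 50 s`
(2.5 stimulation cycles).  The rectified stimulus-locked content adds a
small DC component (~2–3% of the mean for the default kernels) to the
masked-mean trace, and the filter's transient response to the onset and
offset of the stimulation block perturbs trials within ~3 cycles of a
block boundary by up to ~1–2% in the recovered waveform.  Steady-state
trials (≥ 3 cycles from block boundaries) recover the injected
`1 + h + g` waveforms to better than 1e−3 on noiseless input, which is the
regime the recovery tests certify; transient-adjacent trials are part of
the averaged output, exactly as in the real procedure.  For the same
reason, simulated sessions used in validation leave a ≥ 60 s recording
tail after the last cycle.

The chain is exactly scale invariant: multiplying the dark-subtracted
stack by any constant cancels in the decay-correction and
trial-normalization divisions (verified to 1e−9 with a shared mask).
The pipeline preserves floating dtype — float32 stacks (the noisy
simulator output) stay float32 for speed; float64 input retains full
precision.

## Problem sizes used in validation

Statistical properties are certified on simulated cohorts run through the
entire chain with the head mask estimated from the data, not taken from
truth.  Null calibration uses 50 cohorts of 3 vs 3 subjects at the full
64×64, 1200-frame (240 s, 9-trial) recording size; the 200-cohort type-I
sweep and the power check use a 16×16 head field, since test calibration
does not depend on the per-subject noise scale.  Early/late separation
uses 20-trial recordings (the default averaging depth) at 64×64.  These
sizes are the package's validation design; all thresholds (binomial 95%
interval for the rejection count, 3×SE for presence/absence of responses,
±0.2 s on the early peak) are stated in the tests themselves.

## What the simulator does not model

No optical PSF or skull/skin scattering, no motion (head-fixed
assumption), no spectral mixing of multiple luciferases, no per-frame mask
adaptation, and no second-scale substrate transients — S(t) is smooth and
slow by assumption.  Passing tests therefore certify the numerical and
statistical behaviour of the chain on data obeying the stated model, not
robustness to motion artifacts or optics-induced spatial blur.

## Known limitations

* The Butterworth comparison against the analytic continuous-time gain
  holds to <1% only below ~0.1 Hz at a 5 Hz frame rate; beyond that the
  bilinear-transform warping of any digital implementation dominates.
* Absolute kcat is out of reach without photon calibration and enzyme
  quantitation; only relative kcat (Vmax ratio) is reported.
* The AUC late-window right edge (default 6 s) is a convention; both
  window bounds are carried in every report so alternative choices
  remain comparable.
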