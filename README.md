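# lumipipe

Stimulus-locked analysis of bioluminescence imaging (BLI) video from the
awake mouse brain, for researchers doing non-invasive luciferase or
bioluminescent-calcium-indicator imaging.  The package provides:

* a **synthetic recording generator** — head-fixed-mouse BLI video with a
  known substrate rise-and-decay, stimulus-locked hemodynamic and calcium
  components, an elliptical head on a dark field, and EM-CCD shot/read
  noise, with every ground-truth component returned alongside the stack;
* the **frame-level analysis chain** — dark subtraction, intensity-based
  head masking, decay correction by division with a zero-phase Butterworth
  lowpass of the masked mean intensity, epoching into stimulus-locked
  trials, per-pixel ΔL/L₀ normalization to the first second of each trial,
  trial averaging, and ±0.3 pseudocolor rendering;
* **response statistics** — cortical ΔL/L₀ traces, early ([0, 2] s,
  calcium) vs late ([2, 6] s, hemodynamic) areas under the curve, and
  two-tailed Student's t-tests between cohorts;
* **enzymology** — Michaelis–Menten fits of substrate titrations
  (v = V·S/(K_m + S)), relative k_cat as a V_max ratio at matched enzyme,
  one-site binding fits (K_d), and emission-spectrum normalization.

The core quantity is the fractional luminescence change

    ΔL/L₀(x, t) = L(x, t) / ⟨L(x, baseline)⟩ − 1

computed per pixel per trial after the slow substrate pharmacokinetics
have been divided out, so that a fast calcium response (peaking ~1 s after
a stimulus) can be separated from the hemodynamic response (2–6 s) by
splitting the post-stimulus area under the curve at 2 s.

## Worked example

Simulate a calcium-indicator subject (20 stimulation cycles, 1 s on /
19 s off, starting 60 s into the recording), run the full chain, and
split the response:

```python
import lumipipe as lp

schedule = lp.make_stimulus_schedule(n_cycles=20, on_duration=1.0,
                                     off_duration=19.0, start_delay=60.0)
kernels = [lp.ResponseKernel.hemodynamic(),   # peak 3 s, support 2-6 s
           lp.ResponseKernel.calcium()]       # peak 1 s
subject = lp.simulate_subject(kernels, seed=1, schedule=schedule,
                              duration=schedule.end_time + 60.0, n_first=20)
print(f"early AUC = {subject.stats.early_auc:.4f}  "
      f"late AUC = {subject.stats.late_auc:.4f}")
```

prints

```
early AUC = 0.1637  late AUC = 0.3320
```

Both areas are positive because this subject carries both response
components: the injected 10%-amplitude calcium kernel dominates the early
window (its trace peaks at ΔL/L₀ ≈ 0.15 at t = 1.0 s) and the
hemodynamic kernel the late window.  A luciferase-only subject (drop
`ResponseKernel.calcium()`) shows a late AUC of similar size but an early
AUC indistinguishable from zero — the separation that identifies a
genuine calcium signal.

Fitting a noisy substrate titration (true V_max = 100, K_m = 5 µM,
twofold dilutions from 15 µM, 3 replicates, 5% noise):

```python
import numpy as np
from lumipipe.enzymology import fit_michaelis_menten, simulate_titration

fit = fit_michaelis_menten(simulate_titration(100.0, 5.0,
                                              rng=np.random.default_rng(7)))
print(f"Vmax = {fit.vmax:.1f} ± {fit.vmax_se:.1f}, "
      f"Km = {fit.km:.2f} ± {fit.km_se:.2f} µM")
# Vmax = 97.4 ± 1.7, Km = 4.99 ± 0.21 µM
```

The same machinery is available from the shell:

```bash
lumipipe simulate --seed 3 --out sim.tif
lumipipe analyze --video sim.tif --ntrials 20 --out results/
lumipipe stats --traces 'results/response_trace*.csv' --out report.json
lumipipe mmfit --in titration.csv --out fit.json
```

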