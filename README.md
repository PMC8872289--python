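# divtrack

Quantitative single-molecule and FRAP analysis of **DivIVA**, the
curvature-sensing polar scaffold protein of Gram-positive bacteria — built
as a reusable, tested pipeline with a synthetic-data generator, so every
estimator is validated by parameter recovery against published values for
*Bacillus subtilis* and *Corynebacterium glutamicum*.

## What it computes

Given single-particle tracking (SPT) tables (TrackMate-compatible CSV) or
simulated trajectories, and FRAP region-of-interest measurements:

- **Ensemble MSD** at lags τ = kΔt, fitted with `MSD(τ) = 4Dτ + b`; the
  free intercept `b` absorbs the localization-error offset 4σ².
- **Jump-distance (SQD) mixture analysis**: the cumulative distribution of
  squared frame-to-frame displacements `u` is fitted with up to three
  diffusive states, `F(u) = 1 − Σᵢ fᵢ·exp(−u / 4DᵢΔt)`, with diffusion
  constants `Dᵢ` **shared across compared conditions** and fractions `fᵢ`
  free per condition (confined / slow / fast by ascending D).
- **Dwell-time survival analysis**: confinement events at a 97 nm radius,
  survival function `S(t)`, constrained biexponential fit
  `S(t) = p₁e^(−t/τ₁) + p₂e^(−t/τ₂)`, `p₁+p₂ = 1`.
- **Confinement heat maps** of confined-track localizations in normalized
  averaged-cell coordinates (rod = 2D spherocylinder, or sphere).
- **FRAP kinetics**: CTCF background correction, focus/whole-cell ratio
  normalization anchored at pre-bleach = 1 and the +20 s frame = 0,
  recovery fit `I(t) = A(1 − e^(−τt))`, half-time `T½ = ln2/τ`, mobile
  fraction `A`, and the Shapiro–Wilk/Bartlett-gated group comparison
  (Dunnett, else rank-sum).

The trajectory simulator (multi-state 2D Brownian motion with fixed state
per molecule, reflecting cell boundaries, localization error, geometric
track lengths) plus the dwell and FRAP generators provide ground truth for
all of it.

## Worked example

```python
from divtrack import (SimConfig, simulate_tracks, filter_tracks,
                      compute_squared_displacements, fit_sqd_mixture_global)

cfg = SimConfig(components=[(0.01, 0.75), (0.1, 0.24), (1.0, 0.01)],
                frame_interval=0.024, n_tracks=3000, loc_error_sd=0.0, seed=2)
ts = filter_tracks(simulate_tracks(cfg), min_frames=5)
sqd = compute_squared_displacements(ts, lag_frames=1)
mix = fit_sqd_mixture_global({"cgb_like": sqd}, n_components=3,
                             frame_interval=0.024)
for lab, D, f in zip(mix.labels, mix.D, mix.fractions["cgb_like"]):
    print(f"{lab:>8}: D = {D:7.4f} um^2/s   fraction = {100*f:5.1f} %")
```

prints

```
confined: D =  0.0100 um^2/s   fraction =  73.5 %
    slow: D =  0.0985 um^2/s   fraction =  25.6 %
    fast: D =  0.9310 um^2/s   fraction =   0.9 %
```

i.e. the fit recovers the simulated C. glutamicum-like population structure
(75/24/1% at D = 0.01/0.1/1 µm²/s) to within ~1.5 percentage points at
this modest track count. With localization error switched on (the 20 nm
default), fitted constants are *apparent* D, inflated by σ²/Δt. The analysis drivers under `analysis/` run the same machinery at
scale: `01` MSD diffusion coefficients (recovering D = 0.142 vs 0.010
µm²/s, a >14× ratio), `02` all published population comparisons, `03` all
published dwell rows, `04` the FRAP group pipeline, `05` confinement maps.

```bash
python analysis/01_msd_diffusion.py 1     # argument = seed
divtrack spt --config configs/demo_spt.yaml --out results/demo
```

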