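# Methods

This note documents the models, estimators and design choices behind
`divtrack`, and what the synthetic-data validation does and does not show.

## The measurement problem

DivIVA is a membrane-binding scaffold protein that accumulates at regions
of strong negative curvature (cell poles, division septa). Its
single-molecule behaviour is heterogeneous: some molecules are locked into
polar assemblies, some exchange slowly, some diffuse freely. SPT movies
(TIRF, 9 or 24 ms effective frame interval) give per-molecule trajectories
in the 2D focal plane; FRAP of polar foci (20 s frame interval) gives
ensemble exchange kinetics. The package quantifies both.

All displacement statistics are planar (2D): TIRF restricts excitation to
a thin layer, and the published convention MSD = 4Dτ is used throughout.

## Trajectory simulator

Tracks are multi-state 2D Brownian walks:

- Each molecule is assigned **one** diffusive state for its whole lifetime,
  with probability equal to the state's population fraction. The mixture
  model being validated assigns fractions to populations, not transitions,
  so the generator matches that assumption; a state-switching generator
  would probe model misspecification, which is out of scope here.
- Per-frame displacements are isotropic Gaussian with variance 2DΔt per
  axis. With a cell geometry, the walk starts uniformly inside the outline
  and is reflected specularly (rods are 2D spherocylinders — the TIRF
  projection; spheres model protoplasts/L-forms).
- Localization error: i.i.d. Gaussian, default σ = 20 nm per axis (typical
  TMR single-molecule precision), added after the walk so boundaries apply
  to true positions.
- Track lengths are geometric (per-frame termination probability, default
  0.05 → mean 20 frames), emulating photobleaching-limited observation.

Consequences used as closed-form oracles: a single-frame squared
displacement is exponential with mean 4DΔt + 4σ², and the ensemble MSD is
4Dτ + 4σ² at every lag.

What the simulator does **not** emulate: blinking/photophysics, detection
and linking errors (false spots, track fusions), static heterogeneity in D
within a state, anomalous diffusion, and within-track state changes.
Passing recovery tests therefore show that the estimators are correct and
well-calibrated for the assumed data-generating process — not that the
published numbers are correct for real movies.

## Track filtering

Tracks need a minimum span of 5 frames ("span" = last − first + 1,
matching linker semantics; localization count is also reported). Gaps of
up to 2 frames are retained inside a track but never contribute
displacement pairs; longer gaps split the track before length filtering.
The final localization of every track is excluded from displacement
statistics to avoid track-ending artifacts.

## MSD analysis

Ensemble MSD at lags kΔt (k = 1..4) pools all eligible pairs. The linear
fit has a free intercept even though a pure Brownian MSD passes through
4σ²·0 = 0 only without localization error: the intercept absorbs 4σ² (and
blur effects in real data), and simulated-D recovery fails without it,
particularly for slow diffusers where 4σ² (0.0016 µm²) is comparable to
4DΔt (0.00096 µm² at D = 0.01). D = slope/4.

## Jump-distance (SQD) mixture

The empirical cumulative distribution of single-frame squared
displacements u is fitted by least squares with

    F(u) = 1 − Σᵢ fᵢ exp(−u / 4DᵢΔt),  i ≤ 3,

with Dᵢ shared across all conditions fitted jointly and fᵢ free per
condition — the "determined simultaneously" design that makes fraction
shifts between conditions directly comparable. Numerical choices:

- ECDF evaluated at Hazen plotting positions (i+0.5)/n, thinned to ≤ 2000
  quantile points per condition (fits are insensitive to this; it bounds
  the cost).
- D parameterized as log₁₀D ∈ [−6, 2]; fractions via stick-breaking, so
  the simplex constraint is exact by construction.
- Multi-start: one deterministic log-spaced start plus 7 jittered
  log-uniform restarts over [10⁻⁴, 10] µm²/s; best residual wins.
  Components are sorted by ascending D afterwards and labeled
  confined/slow/fast. Nearly degenerate constants (ratio < 1.5) raise a
  warning.
- Bootstrap standard errors (resampling steps within condition) are
  optional (`n_boot`), off by default.
- Localization error is **not** explicitly corrected: fitted constants are
  apparent D (inflated by σ²/Δt), matching the published convention.
- Fractions are per-step (each squared displacement counts once), not
  per-track.

Track classification assigns each track the state maximizing the
exponential-step likelihood of its lag-1 squared displacements (sum s over
m steps: log L ∝ −m·ln μᵢ − s/μᵢ + ln fᵢ, μᵢ = 4DᵢΔt), which is what the
confinement maps consume.

## Dwell-time survival analysis

A confinement event grows while each next localization stays within the
confinement radius (97 nm) of the running centroid of the event's
localizations (an anchor-point variant is available behind a switch;
centroid is the default because it is robust to localization noise).
Events need ≥ 3 frames; events truncated by the track end are flagged
censored and included in the survival curve by default ("confined for at
least t" semantics).

The survival curve S(t) is evaluated on the frame grid, and the
two-component model

    S(t) = p₁ e^(−(t−t₀)/τ₁) + (1−p₁) e^(−(t−t₀)/τ₂)

is fitted by least squares with t₀ the first support point, so S(t₀) = 1
and p₁+p₂ = 1 exactly. Referencing at t₀ matters: a duration recorded as k
frames means the underlying dwell exceeded (k−1) frames, and conditioning
an exponential mixture on exceeding a threshold yields another exponential
mixture with the same τ's. The t₀-referenced fit is therefore unbiased for
frame-ceiled durations and for the left truncation from the minimum event
length — verified by recovery at n = 2×10⁵, where the fit returns the
generating parameters to three digits.

Identifiability caveat: with τ₂/τ₁ ≈ 3 (the 9 ms B. subtilis conditions),
the component **fractions** carry a sampling sd of ~4 percentage points at
n = 10⁴ events even though both τ's recover well; fraction comparisons at
that separation need larger event counts.

## FRAP analysis

- CTCF = integrated density − area × mean background (the standard
  background correction).
- The focus CTCF is divided by the whole-cell CTCF, which cancels
  acquisition bleaching exactly (verified for decay rates 0, 10⁻³, 10⁻²
  s⁻¹). The whole-cell CTCF uses an optional `cell_area` column; without
  it the whole-cell signal is taken as already corrected.
- Normalization anchors: mean of all pre-bleach frames ↦ 1; the single
  frame one offset (default 20 s) after the bleach ↦ 0. Fitting starts at
  that anchor frame — the first post-bleach frame is excluded to keep
  fluorophore photoswitching out of the kinetics.
- Recovery fit: I(t) = A(1 − e^(−τt)) by nonlinear least squares, A ∈
  [0, 5] (values > 1 are flagged, not clamped), τ > 0. T½ = ln2/τ; the
  printed form of the half-time relation is implemented in its only
  dimensionally consistent reading.
- Group comparison: Shapiro–Wilk per group and Bartlett across groups at
  α = 0.05 gate the path — Dunnett many-to-one (one-sided, "less") if both
  pass, otherwise continuity-corrected rank-sum tests per treatment. The
  full decision path and all p-values are reported.

### FRAP simulation defaults and precision

The published acquisition fixes only the 20 s frame interval. Defaults for
the generator were chosen once for realism: pre-bleach plateau of 5
frames, 30–60 post-bleach frames, focus/cell CTCF ratio 0.4 dropping to
0.1 at the bleach, Gaussian noise applied on the normalized scale.
Validation kinetics use τ ∈ {0.005, 0.01} s⁻¹ (T½ ≈ 1–2.3 min, typical
scaffold exchange) and A ∈ {0.7, 0.9} over 60-frame series: a Fisher
information (CRLB) analysis shows that faster kinetics (T½ at or below the
frame interval) or short series are τ-information-starved at realistic
noise, and no estimator could recover T½ to a few percent there. At the
chosen grid the fit attains a median |ΔT½|/T½ of 3–4.5% at noise sd 0.05
(200 replicates per grid point), essentially at the CRLB. The single-frame
+20 s anchor of the published normalization adds ~2 points of median error
end to end; it is kept because it is the published procedure.

## Problem sizes

Recovery runs use 5000 tracks (MSD), 40000 steps per condition (SQD
mixtures), 10⁴ durations per dwell row, and 200 replicates per FRAP grid
point. These sizes put simulation noise well inside the published
uncertainty for every recovered quantity (see `results/` tables produced
by the analysis drivers).

## Known limitations

- The exact confinement-event rule of the published analysis software is
  not public; centroid and anchor variants are both implemented, and
  recovered dwell parameters refer to durations generated directly from
  the two-exponential model, not to detector-dependent event definitions.
- The published population-fraction comparisons do not print the shared
  diffusion constants; recovery simulations use (0.01, 0.1, 1.0) µm²/s,
  10×-separated and field-typical. Fraction recovery is insensitive to the
  exact values as long as states remain separated.
- Two of the published shape-comparison fraction sets are incomplete in
  the source; missing entries were completed by closure (sum to 100%) and
  carry-over, and only fully published fractions serve as recovery
  targets.
- Real-cell confinement maps require per-cell outlines as input; the
  package does not segment micrographs.
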