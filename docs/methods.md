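# Methods

`ermech` measures the mechanics and dynamics of endoplasmic-reticulum (ER)
tubules from fluorescence images and tracking data, and ships a synthetic-data
module that generates every input class with known ground truth so the whole
pipeline is testable without microscope data. This note records the models,
the numerical choices, and what the synthetic benchmarks do and do not show.

## Worm-like-chain model and persistence length

A tubule backbone is modelled as a worm-like chain (WLC): tangent vectors
decorrelate exponentially with arc separation, `<t(0)·t(s)> = exp(-s/L_p)`,
where `L_p` is the persistence length. The mean-square end-to-end distance of
a chain of contour length `L_c` is then

    <R²> = 2 L_p (L_c − L_p [1 − exp(−L_c/L_p)]).

`persistence.fit_persistence_length` fits this relation to measured
`(L_c, R)` pairs. The end-to-end route is used rather than direct
tangent-correlation fitting because, for semi-flexible fibres with
`L_p ~ L_c`, most of the bending information sits in the longest-wavelength
modes that also set `R²`, making the estimate robust to pixel-scale tracing
noise. A tangent-correlation estimator is provided as a diagnostic only.

Numerical points:

* `wlc_msre` switches to the series `L_c²(1 − x/3 + x²/12 − x³/60)` for
  `x = L_c/L_p < 1e-4`; the closed form suffers catastrophic cancellation in
  the rigid-rod limit.
* The ensemble fit needs *relative* weights (R² fluctuations scale with their
  mean), and the weights must come from the model, not the data — weighting by
  observed R² correlates weights with noise and biases `L_p` downward by tens
  of percent. The fit therefore iterates nonlinear least squares with
  model-based sigma (IRLS, 3 rounds). Verified unbiased at large n
  (<0.3% at 20 000 chains); at the benchmark size of 1000 chains the sampling
  spread is ~2–3%.
* The per-fibre route (invert `<R²>` for each fibre by bisection, bracket
  `[1e-4, 1e4] ×` the median `L_c`) is exposed because per-fibre distributions
  are scientifically interesting (they are roughly log-normal), but its
  arithmetic mean is biased high by ~30% in the `L_c ~ L_p` regime: per-fibre
  R² has relative sd of order one, and the inversion is convex. Use the
  ensemble methods for the headline number. Straight chains (`R ≥ L_c`) pin
  the inversion at the upper bracket and are flagged.
* 2D chains are generated with Gaussian tangent-angle increments of variance
  `2Δs/L_p`, i.e. the same `exp(-s/L_p)` tangent correlation as the 3D
  convention, so one closed form serves both. (Conventions in which the 2D
  correlation is `exp(-s/2L_p)` would change absolute `L_p` by ~2×; the
  convention here is declared and unit-tested.) 3D steps draw `cos θ` from
  `p ∝ exp(κ cos θ)` with `κ` solved so `<cos θ> = exp(-Δs/L_p)` exactly.
* Projected-3D chains are spline-smoothed before resampling: orthogonal
  projection creates sub-segment zigzags wherever the 3D tangent tilts out of
  plane, which a real traced centerline could not resolve.

## Membrane rigidity of a thin hollow tube

For a solid filament `L_p = κ_pol / k_B T`. ER tubules are hollow with a
3–5 nm wall, far thinner than the ~44 nm outer radius, so the tube is treated
as a thin elastic membrane cylinder, for which

    L_p = 2 κ_mem π R / (k_B T).

`mechanics` converts both ways and reports `κ_mem` in kT and joules
(k_B = 1.380649e-23 J/K exactly; default T = 298 K, consistent with the
kT↔joule pairs the conversions reproduce). At `L_p = 3.03 µm`, `R = 44.1 nm`
this gives `κ_mem = 10.9 kT`; at `L_p = 4.71 µm` (junction-free stretches),
`17.0 kT` — soft but typical for lipid bilayers.

The network-level moduli use the hexagonal-honeycomb scaling for slender
struts of thickness `2r` and branch spacing `L`: `E_in/E = (2r/L)³`,
`G_in/E = 0.25 (2r/L)³`, `E_out/E = (2r/L)`. These are order-of-magnitude
scalings implemented literally; no nonlinear foam mechanics (buckling,
compaction) is attempted.

## Tube radius from cross-sectional profiles

A hollow tube seen in 2D projection has cross-sectional intensity equal to
the line integral through a thin annular shell, `ρ(d) ∝ 1/√(R² − d²)` for
`|d| < R`, convolved with the imaging PSF. `radius.fit_profile_radius` fits
this forward model (radius, amplitude, baseline, small centre shift; radius
bounded `≥ 0`) by least squares. The model is evaluated as an average of
Gaussians centred at `R cos φ` over uniform `φ`, which is the same projection
without the edge singularity. The PSF sigma is a *required input* — the
deconvolution is implicit in the model, not a quadrature subtraction — with
20 nm a sensible default for STORM-class data (divide by 2.355 if given as
FWHM). Profiles are sampled perpendicular to the traced backbone at uniform
arc spacing (bilinear interpolation in image mode; signed-offset histograms
with bin width `max(5 nm, precision/2)` in localization mode) and profiles
within 3 half-widths of a junction are excluded. Averaging drops outliers
beyond 3 scaled MADs and reports the count. Synthetic recovery is better than
1% at R = 30–60 nm with a 20 nm PSF; note the profile is double-peaked (rim
maxima at ±R) once `R ≳ σ_psf`, which is exactly the feature the fit exploits.

## Fibre tracing

The tracer is an open active contour: energy
`E = ∫ (α|c′|² + β|c″|² − w·I(c)) ds` minimised by the standard semi-implicit
update `x ← (I + γ(αK₂ + βK₄))⁻¹ (x + γ w ∇I(x))`, where K₂/K₄ are Gram
matrices of first/second differences (free ends = natural boundary
conditions). Initialisation is the minimum-cost path between two seed points
on an inverted Hessian-ridge (tubeness) map; the path is computed in a
canonical endpoint order so swapping seeds returns the exact reversed trace.
Vertices are resampled to uniform arc spacing every iteration. This
resampling, not a stretching term, regularises the parametrisation:
`α > 0` with free ends makes open snakes slide inward along the ridge and
shortens the trace, so `α` defaults to 0 (it remains exposed). Convergence is
declared when the mean vertex displacement per iteration falls below a
tolerance (default 1 nm); a vertex leaving the image raises an error naming
the iteration.

Accuracy on rendered tubes: RMS centerline error ≲ 0.1 px for noiseless
constant-curvature tubes up to 0.5 µm⁻¹ and ≲ 0.2 px at SNR ~ 5. Tip
positions are only accurate to about half a PSF width (the intensity ramp at
the tube end pulls free tips slightly inward), so the contour length carries
a fixed absolute end bias of ~0.05–0.08 µm per end: below 1% for tubes
≳ 15 µm, but material for very short segments.

Junction detection clusters chain endpoints (single linkage within a
tolerance radius) and counts incident arms — an ending chain contributes one,
a passing chain two; total degree ≥ 3 makes a junction at the arm centroid.
Segmentation between junctions removes vertices within the junction radius
and keeps contiguous runs of at least 3 vertices.

## Transverse dynamics and tension

The transverse displacement of one tubule point (projection of its motion
onto the perpendicular of the nearest backbone segment at t = 0; the
longitudinal/transverse variance ratio is reported rather than silently
assumed small) gives a time-averaged MSD, computed over all overlapping pairs
at each lag up to a fraction (default 1/4) of the track length — identical,
pair for pair, to the naive double-loop definition.

Power-law exponents `msd ∝ τ^α` are fitted in log-log space. Tracks shorter
than 5 s are excluded; the remaining tracks are classified by their exponent
at lags above the 2 s regime break: `α < 1` sub-diffusive (equilibrium
fluctuations under tension), `1 ≤ α < 2` super-diffusive (motor-driven),
`α ≥ 2` excluded as anomalously fast. Both thresholds are configurable.
Ensemble MSDs weight tracks equally by default (pair-count weighting is a
flag). The super-diffusive ensemble gets separate short-lag (≤ 2 s) and
long-lag fits.

### Langevin simulator

A filament of length L pinned at both ends, bending rigidity
`κ_pol = L_p k_B T` and tension `f = σ π R²` (stress times outer
cross-section — the area convention is declared on every output) evolves by
overdamped dynamics of its sine modes `q_n = nπ/L`:
stiffness `k_n = κq⁴ + fq²`, equilibrium variance
`<a_q²> = k_B T / [(L/2) k_n]`, relaxation time `τ_q = ζ/k_n` with
slender-body transverse drag `ζ = 4πη / (ln(L/2R) + 0.84)`. Each mode is
advanced by the exact Ornstein–Uhlenbeck update (AR(1) with
`ρ = exp(-dt/τ_q)`), so the discrete trajectory is statistically exact at any
`dt`; there is no stability limit. Modes faster than the sampling step are
still correctly equilibrated and correctly correlated at all sampled lags —
the code warns (or errors under `strict_dt=True`) only because their
*sub-step* dynamics are unresolved. `active_drift` adds constant-velocity
transport of the midpoint, the minimal model of the motor-driven population
(ballistic at long lags).

Mid-point MSD regimes follow the standard mode-sum picture: with tension the
saturated-mode count grows as `t^{1/2}`, without tension as `t^{3/4}`. The
benchmark conditions were chosen once from the analytic mode sum
(`midpoint_msd_expected`) so that the fit window `[10 dt, duration/10]` sits
inside the relevant regime with margin, then frozen:

* tension-dominated: σ = 200 Pa, L = 50 µm, dt = 1 ms, 5 s, 150 modes,
  12 tracks (tension length `√(κ/f) ≈ 0.1 µm ≪ L`; analytic exponent 0.50);
* tension-free: L = 15 µm, dt = 0.2 ms, 2 s, 60 modes, 32 tracks (analytic
  exponent 0.75);
* equipartition check: L = 2 µm, 3 modes, 10 s (≳ 1000 relaxation times of
  the slowest mode, giving ~3% sampling error on mode variances);
* mixture for the classifier: L = 30 µm, σ = 58.3 Pa, dt = 20 ms, 12 s,
  drift 0.2 µm/s — the super-diffusive ensemble then shows a short-lag
  exponent near 0.6 and a long-lag exponent near 1.5.

### Stress from the fluctuation amplitude

The tensioned-fibre amplitude relation used for stress extraction is

    <Δr⊥²(τ)> = (k_B T/σ)^{3/4} · L_p^{1/4} τ^{1/2} / (2 η^{1/2}),

inverted as `σ = k_B T (L_p^{1/4} / (2 η^{1/2} A))^{4/3}` after fitting
`msd = A τ^{1/2}` (linear LS in √τ; a warning fires if the measured exponent
is outside 0.5 ± 0.1). The viscosity η must be supplied — no default is
asserted as "the" cytosolic value. The estimator also reports the tension
force `f = σπR²`, the tension length `l_t = √(κ_pol/f)` (≈ 0.19 µm at
σ = 58.3 Pa, R = 44.1 nm) and, given a contour length, the validity bound
`σ ≫ k_B T L_p / L²`.

A caveat stated plainly: taken literally with σ in pascals this amplitude
relation is not dimensionally an area, whereas the mode-sum theory for a
tensioned filament gives `msd ∝ k_B T τ^{1/2} f^{-1/2} ζ^{-1/2}` with a
*force* and no `L_p` dependence. The package keeps the two roles separate:
the simulator is the physical model (force-based), and `estimate_stress`
implements the amplitude relation above as the field's estimator, verified by
an exact analytic round trip rather than by cross-calibration against the
simulator. Stress values from real data should be read as defined *by this
estimator*.

## Synthetic data: what it does and does not emulate

The generators reproduce the statistical structure the analyses assume: WLC
geometry with exact tangent-correlation conventions, honeycomb-topology
networks with degree-3 junctions and 1–5 µm edge lengths, annular-shell tube
images with Gaussian PSF and Poisson (or Gaussian/no) noise at both
diffraction-limited (~100 nm px) and STORM-like (10 nm px) sampling,
surface-localization tables with Gaussian precision jitter, and
equilibrium/driven transverse tracks. Deliberately not emulated: fluorophore
photophysics (localization tables are drawn directly, not reconstructed from
blinking movies), sample drift, dense network crossings and out-of-focus
background in real cell images, heterogeneous per-tubule radii or stiffness,
and the interaction of tubules with other organelles. Passing the synthetic
benchmarks therefore demonstrates estimator correctness and noise robustness
at realistic SNR — not segmentation quality on dense, real ER images.

## Benchmark sizes

Chosen once as realistic desk-scale studies: 1000 chains per stiffness for
persistence recovery (sampling spread ~2–3%, so the 5% check is a ~2σ
criterion); ≥ 50 profiles per tube for radius recovery; 12–32 tracks per
dynamics ensemble; a 40-track mixture for the classifier. The analysis
scripts (`analysis/01…05`) regenerate all inputs and results from seeds in
about a minute.
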