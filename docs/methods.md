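# Methods

This note records the models, defaults and numerical choices behind
`lfaquant`, and what the synthetic-data studies do and do not demonstrate.

## Assay model

The package addresses a competitive (binding-inhibition) lateral-flow
format for small analytes: free analyte in the sample occupies the binding
sites of the gold-labelled detection antibody, so only the *uninhibited*
fraction can bind the antigen on the test line. The simulator models that
fraction with the equilibrium Langmuir isotherm

    f(C) = Kd / (Kd + C_molar),

the simplest monotone-decreasing law consistent with a sigmoidal
dose–response on a log axis. `Kd = kd/ka` is taken from the bundled
antibody kinetics (`ka = 2.4·10⁴ M⁻¹s⁻¹`, `kd = 1.3·10⁻³ s⁻¹`, hence
`Kd ≈ 54 nM`); mass concentrations in µg l⁻¹ are converted with the analyte
molar mass (default 277.4 g/mol, amitriptyline). The isotherm only shapes
the *simulated* signal; the analysis chain itself is model-free up to the
4PL calibration.

## Synthetic strips: what is emulated

`simulate.render_strip` emulates an 8-bit RGB photograph of a
laser-structured strip: four 50 px lanes separated by 3 px dark barrier
lines (the fiducials), each lane with a reference zone, a test spot and a
control spot along the flow direction. Red colorant is rendered as
**green-channel depletion** — a red spot absorbs green light, which is what
makes a green-channel analysis informative. Spots are circular
(radius 12 px) with a Gaussian edge shoulder (σ = 1.2 px by default; spot
geometry on real membranes is droplet-dependent and not standardized).

The test-spot depletion depth is `depth_scale · y(C)` with `y` the
configured 4PL (defaults A1 = 1, A2 = 0.1, x0 = 50 µg l⁻¹, p = 1.2, on the
calibration series 0, 1, 10, 30, 100, 300, 1000, 10000 µg l⁻¹); the control
depth is constant by default so that the test/control ratio normalized to
the blank reproduces the configured 4PL *exactly* — this is what makes the
closed-loop identity test meaningful. A mildly analyte-dependent control
line (observed in practice because excess conjugate accumulates there) is
available via `control_slope`, at the price of the ratio curve no longer
being exactly 4PL.

Defaults chosen here, not taken from any instrument: background green
level 210, full-depth test spot 170, control depth 140, additive Gaussian
pixel noise `noise_sd = 2.0` intensity units (a typical low-ISO compact
camera under studio lighting), illumination gradient off. The pixel noise
level of the original camera setup is unknown; 2.0 is a documented choice,
not an inference.

Two rendering regimes exist on purpose:

* **realistic** (default): soft spot edges, rounding quantization. Edge
  pixels enter the Otsu spot class, biasing the *absolute* signal by a few
  percent — but the bias largely cancels in the test/control ratio
  (≤ 0.25% observed), which is precisely why the ratio evaluation is
  preferred.
* **idealized** (`noise_sd = 0`, `gradient_amplitude = 0`,
  `edge_sigma = 0`): hard-edged spots whose interiors are deterministically
  dithered between the two neighbouring 8-bit levels so the zone *mean*
  equals the ground truth to `0.5/n_pixels`. This regime turns the full
  chain into a near-exact identity and is what the closed-loop test uses;
  it verifies the algebra of the pipeline, not the realism of the render.

What the generator does **not** emulate: membrane texture and flow
artifacts, perspective/rotation (the detector recovers translation only),
colour cross-talk, spot asphericity, inter-channel spotting variability,
serum-matrix effects, and long-term drift. Passing tests therefore
demonstrate correctness of the analysis chain under its stated assumptions,
not field performance on real strips.

## Signal evaluation

1. **Zone detection.** The expected barrier-line mask is Pearson-correlated
   with the green plane over integer shifts within ±10 px; the maximizer
   moves all layout boxes. This replaces a learned object detector with a
   deterministic, testable equivalent; a correlation peak below 0.5 raises
   a detection error (e.g. fiducials occluded).
2. **Green plane.** The green channel is used unchanged.
3. **Illumination correction.** A first-order surface `a + b·col + c·row`
   is least-squares fitted to 16 bare-membrane reference points (3×3-pixel
   means) and divided out, rescaled to preserve the mean reference
   intensity. Planar is the minimal model for "local and global" drift; the
   operation is idempotent and exact for a truly planar multiplicative
   field. Correction can be disabled (`correct=False`) to evaluate raw
   intensities.
4. **Segmentation.** Otsu's threshold on the 256-bin histogram *of the zone
   box only*, spot = the low-green class, ties broken toward the lowest
   level. The implementation is closed-form on cumulative moments and is
   tested against an exhaustive scan.
5. **Signal.** `mean(reference zone) − mean(spot pixels)`; negative values
   are allowed but flagged. Per channel the test signal is divided by the
   control signal; per strip the four channel ratios give mean and sample
   SD (n = 4).

## Calibration

Per-strip mean ratios are normalized by the mean blank ratio (the blank
rows average to exactly 1), then fitted with the 4PL on *raw*
concentrations — no log transform, `y(0) = A1` is the `p > 0` limit of the
printed equation. Fitting is unweighted nonlinear least squares (lmfit /
Levenberg–Marquardt) with data-driven starting values; `1/SD²` weights can
be passed explicitly. The parameter covariance is the Jacobian-based
estimate scaled by the residual variance; `df = n − 4`.

**Bands.** Pointwise `ŷ ± t(level, df) · SE(ŷ)` with the delta-method
`SE² = g·Σ·gᵀ` (analytic gradient, the `p`-gradient at x = 0 taken as its
limit 0). A parametric bootstrap band (refit on Gaussian-resampled
responses) is provided as an independent cross-check; the two agree to
within 10% of the half-width in the test suite. `kind="prediction"` adds
the residual variance for single-future-measurement limits; the default
follows the mean-response band.

**Detection limits.** For a decreasing curve, `y_crit` = lower band at 0;
MDC solves `ŷ(x) = y_crit`, RDL solves `upper(x) = y_crit`. Both roots are
bracketed on a 400-point log grid over [10⁻³, 10⁵] µg l⁻¹ and refined by
bisection in log-concentration to relative tolerance 10⁻⁶ — robust and
derivative-free. The solver is verified against a 10⁶-point grid scan of
the same criterion. Other readings of the construction (intersecting the
*lower* band with `y_crit`, or using the band at the curve's zero value)
are geometrically degenerate for a decreasing curve — the crossing either
sits at x = 0 or does not exist — so no alternative-definition flag is
offered; the confidence/prediction `kind` switch is the one genuine degree
of freedom.

## Conjugate characterization

* **Stoichiometry.** Offered antibodies = `V·c/M · N_A`; particles =
  nominal number concentration at OD 1 (20 nm → 7.0·10¹¹ ml⁻¹, 40 nm →
  9.0·10¹⁰ ml⁻¹, supplier-nominal, overridable) × OD × volume; the ratio is
  rounded to the nearest whole antibody. IgG molar mass defaults to
  150 kDa.
* **Monolayer capacity.** `floor(π d² / (14.5 × 8.5) nm²)` with the *bare
  core* diameter — a fractional antibody cannot bind, and using the
  hydrodynamic diameter would overstate the capacity (20 nm → 10,
  40 nm → 40).
* **UV-Vis.** λmax = global maximum (lowest wavelength on ties; edge maxima
  and flat spectra warn); synthesis yield = ratio of final to initial peak
  OD (particle concentration ∝ peak OD at fixed size); FWHM by linear
  interpolation at half maximum, widening = ΔFWHM. Synthetic spectra are
  Lorentzian — adequate for peak-position/height/width bookkeeping, not an
  optical simulation.
* **DLS.** Number-mean diameter over the *main peak* — the connected run of
  bins above 5% of the modal weight carrying the largest total weight —
  so small agglomerate shoulders do not inflate the mean. Layer thickness =
  half the hydrodynamic-diameter growth. Streptavidin-biotin conjugates on
  40 nm cores are deliberately excluded from the stoichiometry golden
  values: their printed antibody/particle ratio reflects preparation losses
  the naive volume arithmetic cannot see.

## Simulation sizes and statistical checks

The stochastic studies use sizes chosen to give stable statistics at
interactive runtimes: 3 batches of 8 concentrations × 4 replicate channels
at σ = 0.03 Gaussian noise on the normalized signal for EC50/MDC/RDL
recovery; 500 Monte-Carlo refits (8 concentrations × 3 replicates) for the
EC50 confidence-interval coverage check (observed ≈93–95%, consistent with
the nominal 95% given moderate curvature nonlinearity); a 4-step noise
ladder σ ∈ {0.01, 0.02, 0.05, 0.1} with 5 replicate calibrations per step
for limit monotonicity. σ = 0.03 is applied in the signal domain: averaging
four ~450-pixel spots suppresses plausible camera pixel noise to well below
that level, so signal-domain noise is the right way to emulate the
strip-to-strip variability that dominates real replicates (spotting,
membrane, flow), which pixel noise alone cannot represent.

## Known limitations

* Translation-only registration; rotated or perspective-distorted
  photographs are out of scope.
* The 4PL is fitted homoscedastically; no 5PL or variance-function
  modelling.
* Detection limits inherit the delta-method approximation; strongly
  nonlinear, poorly conditioned fits (flat curves, weak signals) widen
  bands and can push the RDL beyond the calibrated range, which is
  reported as an error rather than extrapolated.
* The simulator's noise is Gaussian and independent per pixel; structured
  noise (JPEG artifacts, vignetting beyond first order) is not modelled.
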