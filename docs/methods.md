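# Methods

This note records the model, conventions and numerical choices behind
`phagedls`, in the order data flows through the package.

## Spectra and grids

A DLS size-intensity spectrum is a histogram of relative scattered-light
intensity (%) over hydrodynamic-diameter bins. Instruments report
log-spaced bins; the package default emulates a benchtop Zetasizer
reporting range with **70 geometric bins over 0.4–10,000 nm**
(constant edge ratio; centers are geometric means of edges). The bin
layout of any particular instrument export is not standardized, so
imported grids may be irregular; they are reconstructed from reported
centers with geometric-midpoint edges and carry a flag marking whether
they are log-uniform.

Spectra are normalized to total area 100. On import, sums within 10⁻³ of
100 are accepted as normalized; deviations up to 0.1 are kept as-is
(flagged un-normalized); larger deviations are renormalized with a
logged warning, on the view that an export that should sum to 100 but
does not has been truncated or mangled and is better repaired loudly
than rejected.

**Resampling.** AUCΔ needs both spectra on one grid. Intensities are
interpreted as densities per unit log₁₀(diameter) — the natural reading
of a log-binned percentage export — linearly interpolated in log-size
onto the target centers, multiplied by target bin log-widths, and
renormalized to area 100. Bins outside the source support are
zero-filled (the instrument reported no mass there); a target grid with
no overlap at all is an error. Resampling onto the spectrum's own grid
is exact, and a round trip through a ≥64-bin grid reproduces a smooth
spectrum to well under 1% L1.

**Replicates.** Replicate spectra (typically n = 3) are normalized,
aligned to a common grid, and averaged bin-wise before any divergence is
computed; the comparison of a sample against the *averaged* baseline is
the package's default convention. The spread of individual
replicate-vs-baseline divergences is reported alongside the point value.

**Stokes–Einstein.** D_H = k_B·T / (3πη·D), with k_B the exact SI
Boltzmann constant, T in kelvin, η in Pa·s (default: water at 25 °C,
8.872 × 10⁻⁴ Pa·s) and D in m²/s; returned in nm.

## The AUCΔ divergence

AUCΔ(a, b) = Σᵢ |aᵢ − bᵢ| over a shared grid, after normalization (and
resampling when grids differ; the default common grid is the 70-bin log
grid spanning the union of both supports). The statistic is symmetric,
bounded in [0, 200] because each spectrum has area 100, zero iff the
co-gridded spectra are identical, and an L1 metric on any fixed grid.
Values fractionally above 200 from floating point are clamped. For
smooth spectra the statistic is stable to the binning: 70 vs 280 bins
changes it by well under 2%.

## Linear calibration

Titer loss (log₁₀ PFU/mL; **positive = loss** throughout the package) is
regressed on AUCΔ by ordinary least squares. Inference is the two-tailed
t-test on the Pearson correlation; the residual SD uses n − 2 degrees of
freedom. Prediction for a new AUCΔ value x uses the standard
single-observation prediction interval, half-width
t₁₋α/2,n−2 · s · √(1 + 1/n + (x − x̄)²/Sxx); queries outside the fitted
AUCΔ range are flagged as extrapolated rather than refused. Censored
pairs — samples whose plaque assay bottomed out at its detection limit —
are included in linear fits by default (their recorded loss is baseline
minus limit) with a switch to exclude them.

**Runs test.** Departure from linearity is checked with a two-sided
Wald–Wolfowitz runs test on the signs of residuals ordered by AUCΔ.
The exact null distribution of the run count is used for n ≤ 30
(doubling the smaller tail, capped at 1); above that, the normal
approximation without continuity correction. Zero residuals (within
10⁻¹² of the residual scale) are dropped; an exact fit returns p = 1
with a note.

## Threshold logistic classifiers

For each loss threshold L, the outcome is y = 1 iff loss **strictly
exceeds** L, and a single-predictor logistic model is fit by iteratively
reweighted least squares (deviance tolerance 10⁻¹⁰, ≤ 100 iterations).
The slope is reported as the percent change in odds per AUCΔ unit,
100·(e^β₁ − 1), with a Wald 95% CI transformed to the same scale (CI
bounds whose exponential overflows are reported as +∞). Fit quality is
summarized by Tjur's pseudo-R² (mean fitted probability among positives
minus mean among negatives) and the ROC-AUC computed from the
Mann–Whitney rank statistic on fitted probabilities, with ties given
half credit; ROC curve points group tied scores, so the trapezoidal area
equals the rank statistic exactly.

**Separation.** Perfectly separated data have no finite MLE. The fit
flags separation instead of diverging or raising, using two guards: a
slope magnitude above 50 (on the AUCΔ scale a slope of 50 is already
astronomically steep), *or* a final deviance below 10⁻⁶. The second
guard is needed because with a wide gap between classes the IRLS
deviance converges while the slope is still numerically small — the
probabilities are already 0/1 and the likelihood is flat. Flagged
results still report coefficients (the values at the stopping point) so
downstream summaries never silently contain divergent numbers.

A threshold sweep over {0.5, 1, 1.5, 2, 2.5, 3} log₁₀ fits one
classifier per feasible threshold; thresholds that leave one outcome
class empty are reported as skipped.

## The decay simulator

The simulator generates the statistical structure the calibrations
assume, not aggregation physics (no Smoluchowski kinetics, no Mie
weighting). Species are lognormal intensity peaks — Gaussian in
log₁₀-diameter with SD log₁₀(gsd). Defaults: intact virions at 100 nm
(gsd 1.25), fragments at 90 nm (gsd 1.25), aggregates centered at
2,000 nm (gsd 2.0, spanning roughly 500–8,000 nm). Peak widths are
implementation constants: real spectra show peaks of this width but no
standard parameterization exists. The canonical fixtures put virion
peaks at 100 nm (fresh), 200 nm (the surviving archival phage), 60 nm
(predicted fresh baselines), and 120/150 nm for two further
clinical-trial phages — the latter two are implementation constants
chosen inside the observed virion range.

Each component is renormalized to area 100 *within the grid* before
mixing, so mixture weights are exact area fractions and the decay path
s(λ) = (1 − λ)·intact + λ·damaged is exactly affine in the damage
parameter λ. Consequently the noise-free AUCΔ against baseline is
exactly c·λ (c the intact-vs-fully-damaged divergence) — which is what
makes the linear calibration exactly recoverable and gives the
simulator a well-defined ground-truth slope titer_slope / c.

Per sample: λ is drawn uniformly on [0, 1] (or follows an explicit
schedule), damaged intensity splits a_frac = 0.8 to aggregates and the
rest to fragments (aggregation dominates observed decay), true loss is
titer_slope·λ + N(0, noise_sd_titer), and each of the (default 3)
replicates receives multiplicative lognormal per-bin jitter before
renormalization. Defaults: titer_slope 6 log₁₀ (a heavily damaged
preparation loses several logs), noise_sd_titer 0.3 log₁₀ (typical
plaque-assay spread), noise_sd_intensity 0.05, baseline titer 10⁹
PFU/mL. All randomness flows from one integer seed; identical configs
give bit-identical output.

**What the simulator does not emulate.** Real spectra have
instrument-specific smoothing from the autocorrelation inversion,
intensity weighting that over-represents large particles relative to
number concentration, occasional sedimentation artifacts, and decay
modes (e.g. ghost particles of near-intact size) that barely move the
spectrum. Tests passing on synthetic data therefore establish the
correctness of the statistics, not the biological fidelity of any
particular calibration — standard curves must still be built per phage
and condition from real paired measurements.

## Verification choices

Parameter-recovery checks run the simulator with replicate-intensity
jitter off and titer noise 0.3, so that the predictor is measured
without error and the OLS slope has a well-defined truth
(titer_slope/c); with predictor jitter on, ordinary least squares is
attenuated toward zero as in any errors-in-variables setting, which is a
property of OLS rather than a defect of the calibration. Recovery is
measured over 200 seeded simulations at n = 100 samples each; the
logistic-ladder trend uses 100 seeds at n = 100 — sizes chosen to make
Monte-Carlo error small relative to the 5%/coverage bands being checked.

## Known limitations

* Calibrations are per phage and per perturbation type; a slope fitted
  for oxidation of one phage does not transfer.
* AUCΔ is blind to damage that does not change particle size (genomic
  damage, ghost particles); spectra identical to baseline do not imply
  preserved activity under such stressors.
* The linear model extrapolates poorly outside the sampled AUCΔ range;
  predictions there are flagged but still only as good as the nearest
  training data.
* Intensity-weighted spectra saturate: once aggregates dominate
  scattering, further titer loss moves AUCΔ little, compressing the
  upper end of the calibration.
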