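# Methods

## Forward model

Tissue activity follows the two-tissue irreversible leucine model. For a
kinetically homogeneous volume,

    CT*(t) = (1−V_b)·K₁k₄/β · ∫₀ᵗ C_p*(τ)dτ
           + (1−V_b)·K₁(k₂+k₃)/β · ∫₀ᵗ C_p*(τ)e^{−β(t−τ)}dτ
           + V_b·[C_b*(t) − V_D·C_c*(t)] + V_D·C_c*(t),        β = k₂+k₃+k₄.

A heterogeneous volume is a weighted mixture of n such subregions sharing
one blood term; its tissue part is a spectrum with trapping amplitude
θ₀ = (1−V_b)Σ wᵢK₁ᵢk₄ᵢ/βᵢ and equilibrating amplitudes
θᵢ = (1−V_b)wᵢK₁ᵢ(k₂ᵢ+k₃ᵢ)/βᵢ at rates βᵢ. Macro parameters are recovered
from a spectrum as K₁ = (θ₀+Σθᵢ)/(1−V_b), λ = Σθᵢ/(θ₀+Σθᵢ) and
rCPS = K₁(1−λ)/λ·C_p; this assumes λ is common across subregions, which the
synthetic heterogeneous construction enforces. Labeled protein breakdown is
neglected (k₅P* ≈ 0) and brain ¹¹CO₂ is omitted in simulation mode
(C_c* ≡ 0); the full blood term with V_D = 0.41 is implemented for
completeness.

All internal times are minutes and rates are per minute; file readers
convert from seconds. The ¹¹C decay constant defaults to
γ = ln2/20.34 min⁻¹ (configurable); all activities are decay-corrected.

## Numerical evaluation

Model curves are evaluated on a 1-s fine grid. The exponential convolution
uses the piecewise-analytic recurrence that is exact for piecewise-linear
inputs (stable for stiff β up to the 1.33 min⁻¹ grid top; implemented as an
IIR filter on uniform grids). Frame values are within-frame means obtained
from the cumulative trapezoidal integral, because the noise model defines a
frame value as the frame mean. Halving the fine-grid step changes frame
values by <0.05%.

## Estimators

Both estimators share one precomputed dictionary (`BasisSet`): the trapping
column ∫C_p*, one frame-averaged convolution column per rate in a 100-point
logarithmic β grid over [0.0037, 1.33] min⁻¹, and the blood column.

**BFM** solves, for each grid β, a weighted 3-parameter linear least squares
problem in (trap, equilibrating, blood) amplitudes via batched normal
equations; any negative coefficient triggers a non-negative refit for that
grid point, and the β with minimal weighted residual sum of squares wins
(the unconstrained WRSS is used as a pruning lower bound, which is exact).
Estimates are therefore always non-negative. Recovery:
K₁ = (c₁+c₂)/(1−V̂_b), λ = c₂/(c₁+c₂), k₄ = β̂c₁/(c₁+c₂).

**SAIF** restricts equilibrating rates to a bandpass [0.02, 0.3] min⁻¹
(separating blood and trapped tracer below the band and noise-driven fast
components above it) and solves one weighted non-negative least squares
problem over trap + in-band + blood columns. The equilibrating component
count merges adjacent active grid points into one component — noise splits
a single physical component across neighbours — and clusters separated by
at least one inactive grid point are distinct. Clusters carrying <0.1% of
the total equilibrating amplitude are solver residue and are not counted;
relative amplitudes below 1e−9 of the spectral total are treated as exact
zeros in the macro-parameter algebra. The block-alternating
(out-of-band / in-band) formulation of this filter converges to the same
optimum because the problem is convex; the joint solve is used.

Degenerate cases: a fit with no equilibrating mass cannot separate
transport from incorporation; it is flagged, λ is reported as 0 and rCPS
falls back to the net-uptake form θ₀/(1−V_b)·C_p. Estimates with
K₁ > 1 mL/g/min, V_b > 1 or rCPS > 10 nmol/g/min are flagged
non-physiological (outliers).

**Weights.** Fit weights are proportional to the inverse of the frame error
variance. For measured-like data the variance is evaluated on the observed
TAC with a positivity floor of 1% of the TAC maximum
(`weights_from_variance`). In the Monte Carlo study the generating variance
is known exactly, and the weights use it (`weights_from_noise_model`);
observed-TAC weights at realistic noise up-weight the noisiest early frames
and corrupt both estimators.

**Tracer delay** between the arterial sampling site and brain is estimated
by shifting the input set over a 1-s grid of candidate delays (0–20 s),
refitting the whole-brain TAC with SAIF and keeping the delay with minimal
WRSS (ties to the smaller delay).

**Bootstrap heterogeneity classifier.** Residuals of an initial SAIF fit
are normalized by the count-statistics scale sᵢ = √(exp(γtᵢ)CTᵢ/Δtᵢ)
evaluated on the fitted curve, resampled with replacement (default N = 50),
rescaled, added back to the fitted curve and refit; a voxel is flagged
heterogeneous when the fraction of replicates with ≥2 components reaches
the threshold (default 0.80).

## Synthetic study inputs

**Arterial input.** A 2-min infusion: C_p* ramps linearly to its peak at
the end of infusion, then decays tri-exponentially (half-times 1.5, 8,
45 min; amplitude fractions 0.6/0.3/0.1, so the curve is continuous).
Whole-blood activity is 0.8×plasma; C_c* = 0 in simulation mode. The
unlabeled plasma leucine concentration defaults to C_p = 120 nmol/mL,
placing rCPS in the physiological gray-matter range (e.g. 2.4 nmol/g/min
for K₁ = 0.05, k₂+k₃ = 0.10, k₄ = 0.04). The synthetic input emulates the
shape class of measured curves, not any specific subject; in particular its
relatively heavy 45-min tail keeps the running integral ∫C_p* growing late
in the scan, which reduces the late-time contrast between the trapping
term and slow equilibrating components (see Limitations).

**Reference library.** 19 parameter sets spanning K₁ ∈ [0.025, 0.062]
mL/g/min, k₂+k₃ ∈ [0.054, 0.157] min⁻¹, k₄ ∈ [0.027, 0.053] min⁻¹ (all
endpoints attained), V_b = 0.05 throughout. The layout is deterministic
stratified interpolation, decorrelated across the three rates by fixed
multiplicative permutations (i·7 mod 19, i·11 mod 19) so the rates are not
co-monotone.

**Heterogeneous construction.** Each library entry generates a
two-subregion mixture with equal weights, equal λ, preserved weighted K₁,
βₐ = 5β_b, and K₁ₐ(k₂+k₃)ₐ = 25·K₁_b(k₂+k₃)_b. These constraints fix
K₁ₐ = 5K₁/3 and K₁_b = K₁/3 but leave the absolute β scale free; the
anchor chosen sets the weighted mean β of the subregions equal to the
homogeneous β (βₐ = 5β/3, β_b = β/3), preserving the mixture's mean
turnover. The construction preserves weighted rCPS exactly (to 1e−12).

**Noise.** Frame-wise, zero-mean Gaussian with variance
α·exp(γtᵢ)·CTᵢ/Δtᵢ evaluated on the noise-free TAC. The two calibration
levels fix α so the relative SD at the peak frame of the mid-library TAC is
7% ("voxel") or 1.2% ("ROI"). These anchors were calibrated once so that
the Monte Carlo estimator dispersion (RMSE% of K₁, λ, rCPS in the
noise-dominated regime: SAIF at ROI level, the homogeneous scenario at
voxel level) reproduces the dispersion reported for voxel-level and
ROI-level leucine PET data; the calibration used dispersion only, so bias,
outlier and classification statistics remain genuine predictions of the
simulation.

**Phantom.** A 48×48×24 grid of 1.2-mm voxels: ellipsoidal gray-matter
shell around a white-matter core, zero-activity background. Classes sit at
the library range extremes (gray = fast endpoints, rCPS 2.51; white = slow
endpoints, rCPS 1.50), maximizing gray/white kinetic contrast. Every
in-brain voxel is kinetically homogeneous by construction; optional
frame-wise noise.

## Experiments

The Monte Carlo driver generates each scenario's 19 reference TACs, adds
200 seeded noise realizations each, fits every realization with both
estimators, and reports per-set bias% (mean relative difference, outliers
excluded), RMSE% (root mean squared error relative to truth, outliers
excluded; outlier fractions are reported separately), and the SAIF
component-count classification. ROI-level noise is only used with the
heterogeneous scenario: a region large enough for ROI-level statistics
would not be kinetically homogeneous.

The resolution experiment smooths the phantom frame-wise with a 3D Gaussian
(default FWHM 7.1 mm, σ = FWHM/2.3548 per axis) and refits voxelwise before
and after. Smoothing mixes class TACs across borders, so the SAIF
heterogeneity fraction (voxels with ≥2 components) rises and the regional
(SAIF−BFM)/BFM rCPS difference flips from ≈0 on the homogeneous unsmoothed
phantom to negative (BFM's mismatch overestimation) after smoothing. The
default experiment is noise-free: it isolates the resolution/partial-volume
effect. With voxel-level noise added first (available via the API), SAIF's
noise-driven spectral overfitting depresses its rCPS by ~8% even on
homogeneous voxels and dominates the unsmoothed difference; that
noise-coupled behaviour is quantified separately by the Monte Carlo study.

## Problem sizes

The shipped study sizes are 19 sets × 200 realizations per scenario/noise
combination (11 400 fits per method over the three combinations) and the
48×48×24 phantom (~17 000 brain voxels, fit twice per method). The full
acceptance run completes in seconds on one CPU because the dictionary is
precomputed once and the BFM grid search is solved with batched normal
equations.

## Known limitations

* The synthetic input function and reference kinetics stand in for measured
  quantities that are not publicly deposited; quantities that depend on
  their fine structure (notably the exact component-count classification
  rates and the sign of the small SAIF rCPS bias under heavy noise) should
  be read as properties of these synthetic conditions. Under them, the slow
  subregion component (β_b ∈ [0.027, 0.07] min⁻¹) is weakly identifiable at
  voxel-level noise and collapses into the trapping term in roughly a fifth
  of realizations; with a measured input function with a faster-decaying
  tail this collapse is expected to be rarer.
* Passing tests on the phantom demonstrate the partial-volume mechanism and
  the direction of its effects, not scanner-specific magnitudes: there is
  no attenuation, scatter, reconstruction correlation, or motion; noise is
  applied in TAC space.
* The bootstrap classifier resamples residuals globally across frames; it
  assumes the normalized residuals are exchangeable.
* The component count is grid-based: physical components closer than one
  grid step (≈6%) merge, and a component falling outside the bandpass piles
  up at the band edge.
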