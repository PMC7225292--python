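# Methods

## Signal model and estimation

The package models magnitude DWI as `S(b) = S0·exp(−b·ADC) + ν` with
additive homoscedastic noise `ν ~ N(0, σ_ν)` in the signal domain.  After
log-linearisation, first-order error propagation makes the log-domain noise
heteroscedastic with SD `σ_ν / (S0·e^{−b·ADC})`, which motivates weighted
linear least squares.  The design-matrix convention is fixed once: rows of
**B** are `(b_i, 1)`, so the fitted slope is −ADC and the intercept is
ln S0; ADC is reported as the negated slope and σ_ADC as the square root of
the (1,1) element of the parameter covariance.  This convention is the
single source of truth throughout the package.

Assumptions: isotropic diffusion (orthogonal diffusion-encoding directions
are treated as independent repeats of the same decay), monoexponential decay
over the acquired b-range, and Gaussian noise in the log domain — a good
approximation of Rician magnitude noise when the minimum SNR over b-values
exceeds about 5.

### DWLS

Requires M ≥ 3 excitations per b-value.  The weight at each b-value is the
inverse empirical variance (divisor M − 1) of the repeated log-signals,
shared by all rows at that b-value; the covariance is `(BᵀWB)⁻¹` with no
residual-variance factor, because the weights are already absolute inverse
variances.  Degenerate repeats (empirical variance exactly zero) would give
an infinite weight; the weight is replaced by the voxel's largest finite
weight times 10⁶, which preserves the exact-interpolation limit without NaN
propagation, and unit weights are used if every b-value is degenerate
(noise-free data).

### IWLS

Starts from the unweighted least-squares solution, then alternates
`W = diag(exp{2Bα̂})` (the squared model-predicted signal — the inverse
log-domain noise variance up to the global σ_ν²) with a re-solve, stopping
when `max|α̂_t − α̂_{t−1}| < ε` or after N_t iterations.  Defaults
N_t = 100, ε = 10⁻⁵; the tolerance is applied jointly to both parameters in
their native units (mm²/s and log-signal).  The residual variance
`σ̂_ν² = (Y − Bα̂)ᵀW(Y − Bα̂)/(NM − 2)` then scales `(BᵀWB)⁻¹` to give the
covariance.  On well-posed data convergence is fast (the test suite asserts
≥ 97% of voxels within 5 iterations at SNR ≥ 20); non-converged voxels
return the last iterate with a convergence flag.

### SIWLS

IWLS, then the σ̂_ν² field is convolved with a normalised box kernel of odd
width Ω before the covariance is formed.  Smoothing is 2D per axial slice by
default (3D optional).  Averaging k-dof chi-square variates over Ω² voxels
multiplies the effective degrees of freedom by Ω² (Ω³ in 3D); this is an
approximation — neighbouring fits share no data, but the smoothed field is
treated as if it were a single χ²_{kΩ²} variate, which overstates the
information content near tissue boundaries where σ̂_ν² is not locally
homogeneous.  Boundary handling: the kernel mass is renormalised over the
in-mask support (NaN/background voxels carry zero mass), so no dark rim is
created by zero padding; the halo seen at very large Ω comes from genuine
mixing of unlike regions, not from padding.  Ω = 1 reproduces IWLS
bit-exactly.

### Per-voxel validity

A log-transform of a non-positive magnitude is flagged invalid and that row
is dropped from the voxel's regression (no clipping floor, which would bias
the weights); a voxel with fewer than 3 valid rows is unfittable and returns
NaN.  The σ̂_ν² divisor uses the voxel's own valid row count minus 2.

## Chi-distribution theory

With Gaussian log-domain noise, `k·σ̂_ν²/σ_ν² ~ χ²_k` and hence
`ẑ = σ̂_ADC√k/(σ_ν√A₁₁) ~ χ_k`, where A₁₁ is the (1,1) element of
`(BᵀWB)⁻¹` at the true weights `(S0·e^{−b·ADC})²` (the σ_ν² factor is
carried separately, so A₁₁ scales as 1/S0²).  Moments:

* `E(σ̂_ADC) = c(k)·√A₁₁·σ_ν`, `E(σ̂²_ADC) = A₁₁σ_ν²` (k-free),
* `Var(σ̂_ADC) = (1 − c(k)²)·A₁₁σ_ν²`, `Var(σ̂²_ADC) = (2/k)·A₁₁²σ_ν⁴`,

with `c(k) = √(2/k)·Γ((k+1)/2)/Γ(k/2)`, computed by log-gamma differencing
so it remains finite for the large effective k produced by smoothing
(k = 25·Ω² reaches 10⁴ at Ω = 20); non-integer k is accepted.  The
`2/k` form of the fourth moment is the one consistent with
`Var(ẑ²) = 2k` under the stated scaling and with the averaged-vs-full
variance ratio `(MN−2)/(N−2)`.

Averaging M excitations per b-value before fitting leaves `E(σ̂²_ADC)`
unchanged (σ_ν² shrinks by M while A₁₁ grows by M) but collapses the
degrees of freedom from MN − 2 to N − 2.  For the reference protocol
(N = 3, M = 9) the variance penalty is
`(1 − c(1)²)/(1 − c(25)²) = 18.36`.  Note the vendor-averaged k is
N − 2 = 1 — the value required by these ratios — not the row count 3.
The unbiased estimator is `σ̂′_ADC = σ̂_ADC/c(k)` with
`Var(σ̂′_ADC) = (1/c(k)² − 1)·A₁₁σ_ν²`.

## Computed images

`S_nc(a_c, b_c) = e^{−a_c·σ_ADC}·e^{−b_c·ADC}` with a_c, b_c ≥ 0; a_c = 0
recovers eDWI, and a_c = b_c = 0 gives the unit image (the closed endpoint
of (0, 1] is permitted).  Unfittable voxels render as 0 and are excluded
from MIP rays; anisotropic volumes are nearest-neighbour resampled to an
isotropic grid before projection.  a_c and b_c are unconstrained
non-negative reals; the CNR sweep defaults (a_c to 50 000, b_c to 5 000)
are conventions, not limits.

## Synthetic data

No external data is needed; three generators emulate the relevant regimes.
All take explicit seeds and are bit-for-bit reproducible.

**Monte Carlo grid** — per condition (SNR, ADC): M = 9 Rician magnitudes
(μ = e^{−b·ADC}, σ = 1/SNR, S0 = 1) at each b ∈ {50, 600, 900} s/mm².
The desk-scale default grid is 20 × 20 conditions over SNR 1→300 and
ADC 0→4 × 10⁻³ mm²/s with Ns = 2000 replications per cell; acceptance
checks use Ns = 2000–10 000 at selected conditions and quote Monte Carlo
standard errors accordingly.  Replicates are fitted as a batch through the
same vectorised code path as image data.

**Phantom** — five cylinders (radius 6 voxels, 64 × 64 × 4 grid at
2 × 2 × 5 mm) in an ice-water bath (ADC 1.1 × 10⁻³ mm²/s at 0 °C, the
standard QA reference).  Vial ADCs are evenly spaced over
0.7–1.1 × 10⁻³ mm²/s and vial T2s log-spaced over 75–1408 ms — the
tumour-mimicking range — so vial S0 = e^{−TE/T2} at TE = 93 ms varies
strongly between vials.  That S0 spread is what differentiates σ_ADC
between vials and lets the a_c weighting add contrast; with uniform S0 the
uncertainty map is flat and niceDWI degenerates to eDWI.  SNR defaults to
50 in proton-density units.  CNR between vials 2–5 and vial 1 uses two
independent repeat experiments: the per-ROI noise SD is
SD(image₁ − image₂)/√2 (the √2 because a difference of two i.i.d. images
doubles the variance), and CNR = |mean ROI − mean reference| / noise SD.
Zero contrast reports CNR 0; nonzero contrast at zero noise reports +inf.

**Body-like volume** — an elliptical-cylinder torso (default 64 × 64 × 24
at 3.4 × 3.4 × 5 mm) of uniform soft tissue (ADC 1.6 × 10⁻³ mm²/s) with
6 ellipsoidal low-ADC lesions (0.7 × 10⁻³ mm²/s, radii 3–5 voxels), a
smooth in-plane Gaussian coil-sensitivity field (30% amplitude) and
per-station receive gains drawn from 0.8–1.2 over 3 stations.  Gain and
bias multiply the reconstructed magnitudes — noise included — so the true
σ_ν field varies in-plane and jumps between stations while the true σ_ADC
field does not (the gain cancels between σ_ν and S0).  This is precisely
the regime that penalises over-smoothing in SIWLS: smoothing σ̂_ν² across
a gain gradient no longer cancels against the voxel-wise Â₁₁, so the RMSE
against the full-data IWLS gold standard falls with Ω while replicate noise
dominates and rises again once the window spans the gain structure, giving
an interior optimum.  Both maps are bias-corrected before comparison so
their expectations coincide despite very different k.

What the generators do **not** emulate: T1 relaxation and TR effects,
eddy-current and motion artefacts, parallel-imaging (GRAPPA) noise
correlations, partial-volume edges, anisotropic diffusion, and the Rician
noise floor's full effect below SNR_min ≈ 5.  Passing tests therefore
demonstrate the estimator and theory under the stated noise model, not
robustness to acquisition artefacts on real scanners.

## Numerical choices

* 2 × 2 weighted normal equations are solved in closed form per voxel,
  vectorised over voxels; singular systems (rank-deficient designs,
  all-weights-zero voxels) yield NaN rather than raising.
* The IWLS weight update uses the previous iterate's prediction; voxels are
  dropped from the active set as they converge.
* The Kolmogorov–Smirnov and moment checks evaluate the *uncorrected* or
  *corrected* estimator as the corresponding formula dictates; the scaled
  statistic uses the true A₁₁ and σ_ν of the generating condition.
* Seeds: every stochastic routine accepts a seed or Generator; grid studies
  spawn independent child streams per cell so cell results do not depend on
  grid traversal order.

## Limitations

* The chi-distribution theory assumes Gaussian log-domain noise; at
  SNR_min < 5 Rician effects bias ADC downward and the moment formulas
  degrade (probed empirically by the Monte Carlo study, not corrected for).
* The effective-k rescaling under SIWLS is an upper bound on information
  content; bias correction with k·Ω² slightly under-corrects near
  boundaries.
* DWLS's σ_ADC is systematically low (its empirical weights are noisy and
  correlated with the residuals); it is retained for comparison but IWLS is
  the recommended fitter.
* MIP resampling is nearest-neighbour; for strongly anisotropic data a
  higher-order interpolant would render smoother projections.
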