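# nicedwi

Joint voxel-wise estimation of the apparent diffusion coefficient (ADC) and
its statistical uncertainty (σ_ADC) from multi-b-value diffusion-weighted
MRI, and synthesis of **n**oise-corrected **e**xponentially weighted
computed images (niceDWI) from the two maps.

Whole-body DWI reads out tumour burden "at a glance", but conventional
computed high-b images inherit S0 contrast — coil-sensitivity bias fields,
T1/T2 weighting, and gain jumps between acquisition stations — which
confounds comparison across stations, scanners and visits.  `nicedwi`
replaces S0 by a per-voxel confidence weight derived from the ADC fit
itself, giving a purely quantitative image signal.  Intended users:
quantitative-MRI researchers and imaging scientists post-processing
(whole-body) DWI.

## Model

Magnitude DWI signals follow the monoexponential decay

```
S(b) = S0 · exp(−b · ADC) + ν,          ν ~ N(0, σ_ν)
```

Log-transforming gives the linear model `y = ln S0 − b·ADC + ε` with
heteroscedastic noise `ε ~ N(0, σ_ν / (S0 e^{−b·ADC}))`, fitted per voxel by
weighted linear least squares.  With design matrix **B** (rows `(b_i, 1)`),
weights **W** and log-signals **Y**:

```
α̂ = (BᵀWB)⁻¹ BᵀWY,        ADĈ = −α̂₁,        σ̂_ADC = √(Σ̂_α)₁₁
```

Three weighting schemes are provided:

* **DWLS** — weights are the inverse empirical variance of M ≥ 3 repeated
  log-signals per b-value; `Σ̂_α = (BᵀWB)⁻¹`.
* **IWLS** — weights are iteratively re-derived from the model itself,
  `W = diag(exp{2Bα̂})`; `Σ̂_α = (BᵀŴB)⁻¹ σ̂_ν²` with the weighted residual
  variance σ̂_ν² on k = NM − 2 degrees of freedom.  Needs only NM ≥ 3 rows.
* **SIWLS** — IWLS with the σ̂_ν² field box-smoothed over width Ω before
  forming Σ̂_α; the effective k becomes k·Ω².  This rescues precise σ_ADC
  maps when only vendor-averaged data (one volume per b-value, k = N − 2)
  are available.

For Gaussian log-domain noise, `σ̂_ADC·√k / (σ_ν√A₁₁) ~ χ(k)` where
`A₁₁ = [(BᵀWB)⁻¹]₁₁` at the true weights.  The package implements the
resulting closed-form moments, the chi-distribution bias factor
`c(k) = √(2/k)·Γ((k+1)/2)/Γ(k/2)`, the unbiased estimator
`σ̂′_ADC = σ̂_ADC / c(k)`, and the moment ratios between vendor-averaged and
per-excitation acquisitions — notably the 18.36× noise-power penalty in
σ_ADC for discarding individual excitations of a 3-b-value, 9-excitation
protocol.

Computed images:

```
niceDWI:  S_nc(a_c, b_c) = exp(−a_c·σ_ADC) · exp(−b_c·ADC)   ∈ (0, 1]
cDWI:     S0 · exp(−b_c·ADC)
eDWI:     exp(−b_c·ADC)          (= niceDWI with a_c = 0)
```

## Worked example

Fit a synthetic five-vial ice-water phantom (tumour-like ADCs
0.7–1.1 × 10⁻³ mm²/s, T2s 75–1408 ms, SNR 50) with IWLS and apply the bias
correction:

```python
import numpy as np
import nicedwi as nd

spec = nd.PhantomSpec()
series = nd.synth_phantom(spec, seed=0)       # 27 volumes: 3 b × 9 excitations
res = nd.ADCModel(series).fit("iwls").correct_bias()
print(res.summary())
```

```
Voxel-wise ADC fit
================================================
method:             IWLS
degrees of freedom: 25
bias corrected:     True
voxels fitted:      11312
voxels unfittable:  0
median ADC:         0.001092 mm^2/s
median sigma_ADC:   3.058e-05 mm^2/s
converged:          100.0%
median iterations:  3
```

Median ADC ≈ 1.09 × 10⁻³ mm²/s is dominated by the ice-water bath
(1.1 × 10⁻³ mm²/s at 0 °C); a typical voxel's ADC standard error is
≈ 3 × 10⁻⁵ mm²/s, i.e. ~3% relative.  Per vial:

```python
labels = nd.phantom_rois(spec)
for lab, t in zip(range(1, 6), spec.vial_adcs):
    sel = labels == lab
    print(lab, t, np.median(res.adc_map[sel]), np.median(res.sigma_adc_map[sel]))
```

```
vial 1: true ADC 7.00e-04  fitted median 6.979e-04  median sigma 5.16e-05
vial 2: true ADC 8.00e-04  fitted median 7.984e-04  median sigma 2.84e-05
vial 3: true ADC 9.00e-04  fitted median 9.003e-04  median sigma 2.24e-05
vial 4: true ADC 1.00e-03  fitted median 9.985e-04  median sigma 2.01e-05
vial 5: true ADC 1.10e-03  fitted median 1.102e-03  median sigma 1.99e-05
```

Each vial's median ADC lands within 0.2% of truth; σ_ADC grows as vial S0
(short T2) falls — the confidence signal that niceDWI turns into contrast:

```python
img = nd.nicedwi_image(res.adc_map, res.sigma_adc_map, a_c=20_000, b_c=900)
proj = nd.mip(img, axis="coronal", invert=True)
```

The closed-form averaging penalty (why per-excitation data are worth
keeping):

```python
>>> nd.averaging_relations(N=3, M=9)["var_sigma_ratio"]
18.356144063293193
```

A command-line interface mirrors the library:
`nicedwi fit`, `synth`, `theory`, `simulate`, `phantom`, `omega-study`
(see `nicedwi --help`).

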