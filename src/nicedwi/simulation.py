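"""Synthetic data generation and the three validation studies.

* A Monte Carlo study of the estimator properties of DWLS / IWLS /
  IWLS-on-averaged-data under Rician magnitude noise, over a grid of true
  SNR and ADC values.
* A synthetic multi-vial ice-water phantom for contrast-to-noise (CNR)
  analysis of computed images.
* A synthetic body-like volume (torso with low-ADC lesions, coil-sensitivity
  bias field and per-station gain jumps) for choosing the smoothing width
  Omega of the SIWLS fitter by RMSE against the full-data IWLS gold
  standard.

Everything is generated programmatically; no external data is required.
All stochastic operations take an explicit seed and are bit-for-bit
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .data import AcquisitionDesign, DWISeries, vendor_average
from .model import ADCModel, apply_bias_correction
from .noise import a11 as a11_of, bias_factor_c, corrected_variance, sigma_moments
from .synthesis import ComputedImage, nicedwi_image

__all__ = [
    "SimulationGrid",
    "SimulationResult",
    "PhantomSpec",
    "sample_rician",
    "simulate_cell",
    "run_monte_carlo",
    "synth_phantom",
    "phantom_rois",
    "cnr",
    "cnr_surface",
    "synth_body",
    "omega_rmse_study",
]


# ---------------------------------------------------------------------------
# Rician sampling and the Monte Carlo estimator study
# ---------------------------------------------------------------------------

def sample_rician(mu, sigma: float, n: int | tuple = 1, seed=None) -> np.ndarray:
    """Draw Rician magnitudes |(mu + X) + iY|, X,Y ~ N(0, sigma).

    ``mu`` may be an array; the output broadcasts ``mu`` against shape ``n``
    (``n`` trailing dimensions of independent draws per element of mu when n
    is an int is not used -- pass the full output shape instead).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    mu = np.asarray(mu, dtype=float)
    if np.any(mu < 0):
        raise ValueError("mu must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    shape = (n,) if np.isscalar(n) else tuple(n)
    re = mu + rng.normal(0.0, sigma, size=np.broadcast_shapes(shape, mu.shape))
    im = rng.normal(0.0, sigma, size=re.shape)
    return np.hypot(re, im)


@dataclass
class SimulationGrid:
    """Grid of true (SNR, ADC) conditions for the Monte Carlo study.

    Defaults are a desk-scale 20 x 20 grid with 2000 replications per cell;
    the acquisition layout mirrors a whole-body protocol: b in {50, 600, 900}
    s/mm^2 with M = 9 excitations per b-value.
    """

    snr_values: np.ndarray = dc_field(
        default_factory=lambda: np.linspace(1.0, 300.0, 20))
    adc_values: np.ndarray = dc_field(
        default_factory=lambda: np.linspace(0.0, 4e-3, 20))
    bvalues: tuple = (50.0, 600.0, 900.0)
    M: int = 9
    Ns: int = 2000
    seed: int = 0

    def __post_init__(self):
        self.snr_values = np.atleast_1d(np.asarray(self.snr_values, float))
        self.adc_values = np.atleast_1d(np.asarray(self.adc_values, float))
        if np.any(self.snr_values <= 0):
            raise ValueError("all SNR values must be positive")
        if np.any(self.adc_values < 0):
            raise ValueError("ADC values must be non-negative")
        if self.Ns < 2:
            raise ValueError("Ns must be >= 2")


@dataclass
class SimulationResult:
    """Per-cell estimator statistics from the Monte Carlo study."""

    table: pd.DataFrame
    grid: SimulationGrid
    methods: tuple

    def cell(self, snr: float, adc: float, method: str) -> pd.Series:
        t = self.table
        row = t[(t.method == method)
                & np.isclose(t.snr, snr) & np.isclose(t.adc, adc)]
        if row.empty:
            raise KeyError(f"no cell ({snr}, {adc}, {method})")
        return row.iloc[0]


def _replicates_as_series(signals: np.ndarray, bvalues: np.ndarray) -> DWISeries:
    """View Ns x R replicate signals as an (Ns, 1, 1, R) series for the
    vectorised fitters."""
    return DWISeries(signal=signals[:, None, None, :], bvalues=bvalues)


def simulate_cell(
    snr: float,
    adc: float,
    bvalues,
    M: int,
    Ns: int,
    methods=("dwls", "iwls", "iwls_avg"),
    seed=None,
) -> list[dict]:
    """Monte Carlo statistics of each estimator at one (SNR, ADC) condition.

    Draws ``Ns`` independent acquisitions of M Rician magnitudes per b-value
    (mu = exp(-b*ADC), sigma = 1/SNR, S0 = 1), fits each method, and
    accumulates: the mean fitted ADC, the empirical SD of the fitted ADC
    (the ground-truth sigma_ADC), the mean raw and bias-corrected
    sigma_hat_ADC, their empirical variances, and the chi-theory predictions.
    ``iwls_avg`` arithmetic-averages the M magnitudes per b-value first
    (the vendor-data scenario; k = N - 2).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    b = np.asarray(bvalues, float)
    sigma_nu = 1.0 / snr
    mu = np.exp(-b * adc)
    full_b = np.repeat(b, M)
    signals = sample_rician(np.repeat(mu, M), sigma_nu, (Ns, full_b.size), rng)
    rows = []
    for method in methods:
        if method == "iwls_avg":
            data = signals.reshape(Ns, b.size, M).mean(axis=2)
            series = _replicates_as_series(data, b)
            des = AcquisitionDesign.from_bvalues(b)
            fit = ADCModel(series, des).fit("iwls")
            A11 = a11_of(des, adc)
            s_nu = sigma_nu / np.sqrt(M)
        else:
            series = _replicates_as_series(signals, full_b)
            des = AcquisitionDesign.from_bvalues(full_b)
            fit = ADCModel(series, des).fit(method if method != "iwls" else "iwls")
            A11 = a11_of(des, adc)
            s_nu = sigma_nu
        k = fit.k
        corr = apply_bias_correction(fit)
        adc_hat = fit.adc_map.ravel()
        sig_hat = fit.sigma_adc_map.ravel()
        sigp_hat = corr.sigma_adc_map.ravel()
        good = np.isfinite(adc_hat) & np.isfinite(sig_hat)
        n = int(good.sum())
        adc_hat, sig_hat, sigp_hat = adc_hat[good], sig_hat[good], sigp_hat[good]
        adc_mean = adc_hat.mean()
        adc_sd = adc_hat.std(ddof=1)  # ground-truth sigma_ADC
        sigp_mean = sigp_hat.mean()
        sigp_var = sigp_hat.var(ddof=1)
        ck = bias_factor_c(k)
        theory = {
            "e_sigma_theory": ck * np.sqrt(A11) * s_nu,
            "e_sigma_corr_theory": np.sqrt(A11) * s_nu,
            "var_sigma_theory": (1 - ck**2) * A11 * s_nu**2,
            "var_corr_theory": corrected_variance(k, A11, s_nu),
        }
        rows.append({
            "snr": snr, "adc": adc, "method": method, "k": k,
            "n_fitted": n, "n_dropped": Ns - n,
            "adc_mean": adc_mean,
            "adc_sd": adc_sd,
            "sigma_mean": sig_hat.mean(),
            "sigma_var": sig_hat.var(ddof=1),
            "sigma_corr_mean": sigp_mean,
            "sigma_corr_var": sigp_var,
            # Monte Carlo standard errors
            "se_adc_mean": adc_sd / np.sqrt(n),
            "se_adc_sd": adc_sd / np.sqrt(2.0 * (n - 1)),
            "se_sigma_mean": sig_hat.std(ddof=1) / np.sqrt(n),
            "se_sigma_corr_mean": sigp_hat.std(ddof=1) / np.sqrt(n),
            "se_sigma_corr_var":
                np.std((sigp_hat - sigp_mean) ** 2, ddof=1) / np.sqrt(n),
            "se_sigma_var":
                np.std((sig_hat - sig_hat.mean()) ** 2, ddof=1) / np.sqrt(n),
            "a11_theory": A11,
            **theory,
        })
    return rows


def run_monte_carlo(
    grid: SimulationGrid, methods=("dwls", "iwls", "iwls_avg")
) -> SimulationResult:
    """Run the estimator-property study over the full (SNR, ADC) grid."""
    ss = np.random.SeedSequence(grid.seed)
    children = ss.spawn(grid.snr_values.size * grid.adc_values.size)
    rows = []
    i = 0
    for snr in grid.snr_values:
        for adc in grid.adc_values:
            rng = np.random.default_rng(children[i]); i += 1
            rows.extend(simulate_cell(
                snr, adc, grid.bvalues, grid.M, grid.Ns, methods, rng))
    return SimulationResult(table=pd.DataFrame(rows), grid=grid, methods=tuple(methods))


# ---------------------------------------------------------------------------
# Synthetic multi-vial phantom and CNR analysis
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """A synthetic multi-vial diffusion phantom.

    Five cylinders (along z) with tumour-like ADCs and T2s, bathed in
    ice-water; vial 1 (the first entry) is the CNR reference.  Geometry is
    in voxels; ``voxel_spacing`` carries the physical scale.  Defaults:
    64 x 64 x 4 grid, vial ADCs evenly spaced over 0.7-1.1e-3 mm^2/s, vial
    T2s log-spaced over 75-1408 ms (so vial S0 = exp(-TE/T2) varies
    strongly at TE = 93 ms, as in tumour-mimicking MnCl2/sucrose
    solutions), ice-water bath at 1.1e-3 mm^2/s, SNR 50 (noise SD = 1/SNR
    in proton-density units).
    """

    shape: tuple = (64, 64, 4)
    voxel_spacing: tuple = (2.0, 2.0, 5.0)
    vial_centers: tuple = ((32, 32), (15, 32), (49, 32), (32, 15), (32, 49))
    vial_radius: float = 6.0
    vial_adcs: np.ndarray = dc_field(
        default_factory=lambda: np.linspace(0.7e-3, 1.1e-3, 5))
    vial_t2s: np.ndarray = dc_field(
        default_factory=lambda: np.geomspace(75.0, 1408.0, 5))
    echo_time: float = 93.0  # ms
    bath_adc: float = 1.1e-3  # ice-water at 0 C
    bath_s0: float = 0.6
    bath_radius: float = 30.0
    snr: float = 50.0

    @property
    def vial_s0(self) -> np.ndarray:
        """Per-vial b=0 signal: T2 decay of unit proton density at TE."""
        return np.exp(-self.echo_time / np.asarray(self.vial_t2s, float))

    def __post_init__(self):
        self.vial_adcs = np.asarray(self.vial_adcs, float)
        t2 = np.atleast_1d(np.asarray(self.vial_t2s, float))
        if t2.size != self.vial_adcs.size:
            # re-spread the T2 range over however many vials were requested
            t2 = (np.geomspace(t2.min(), t2.max(), self.vial_adcs.size)
                  if t2.size > 1 else np.full(self.vial_adcs.size, t2[0]))
        self.vial_t2s = t2
        if len(self.vial_centers) != self.vial_adcs.size:
            raise ValueError("one ADC per vial required")
        if np.any(self.vial_adcs <= 0) or np.any(self.vial_adcs > 4e-3):
            raise ValueError("vial ADCs must lie in (0, 4e-3] mm^2/s")
        centers = np.asarray(self.vial_centers, float)
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                if np.hypot(*(centers[i] - centers[j])) < 2 * self.vial_radius:
                    raise ValueError(f"vials {i} and {j} overlap")

    def render(self):
        """Rasterise true (S0, ADC) volumes, the object mask and ROI labels."""
        nx, ny, nz = self.shape
        xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        s0 = np.zeros((nx, ny), float)
        adc = np.zeros((nx, ny), float)
        labels = np.zeros((nx, ny), int)
        cx, cy = nx / 2 - 0.5, ny / 2 - 0.5
        bath = np.hypot(xx - cx, yy - cy) <= self.bath_radius
        s0[bath] = self.bath_s0
        adc[bath] = self.bath_adc
        obj = bath.copy()
        vial_s0 = self.vial_s0
        for i, ((vx, vy), a) in enumerate(zip(self.vial_centers, self.vial_adcs), 1):
            inside = np.hypot(xx - vx, yy - vy) <= self.vial_radius
            s0[inside] = vial_s0[i - 1]
            adc[inside] = a
            labels[inside] = i
            obj |= inside
        rep = lambda f: np.repeat(f[:, :, None], nz, axis=2)
        return rep(s0), rep(adc), rep(obj), rep(labels)


def synth_phantom(
    spec: PhantomSpec,
    bvalues=(50.0, 600.0, 900.0),
    n_directions: int = 3,
    n_repeats: int = 3,
    seed=None,
) -> DWISeries:
    """Per-excitation noisy series for the phantom.

    One Rician-noised volume per (b-value, direction, repeat); diffusion is
    isotropic so directions are independent repeats of the same decay.
    Different seeds give the independent repeat experiments needed for the
    CNR noise estimate.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    s0, adc, mask, _ = spec.render()
    b = np.asarray(bvalues, float)
    n_exc = n_directions * n_repeats
    full_b = np.repeat(b, n_exc)
    sigma = 1.0 / spec.snr
    mu = s0[..., None] * np.exp(-full_b * adc[..., None])
    noisy = sample_rician(mu, sigma, mu.shape, rng)
    return DWISeries(signal=noisy, bvalues=full_b,
                     voxel_spacing=spec.voxel_spacing, mask=mask)


def phantom_rois(spec: PhantomSpec) -> np.ndarray:
    """Labelled ROI volume (vial i -> label i, elsewhere 0)."""
    return spec.render()[3]


def cnr(image1: ComputedImage, image2: ComputedImage,
        rois: np.ndarray, reference_label: int = 1) -> dict[int, float]:
    """Contrast-to-noise ratio of each ROI against the reference ROI.

    Noise SD per ROI is estimated from two repeat experiments as
    SD(image1 - image2)/sqrt(2) within the ROI; CNR is
    |mean(roi) - mean(reference)| / noise_SD using the two-experiment
    average image.  Zero contrast gives CNR 0; nonzero contrast at zero
    noise gives +inf.
    """
    v1, v2 = image1.values, image2.values
    labels = [int(l) for l in np.unique(rois) if l != 0]
    if reference_label not in labels:
        raise ValueError(f"reference label {reference_label} not present")
    means, noise = {}, {}
    for l in labels:
        m = rois == l
        if not m.any():
            raise ValueError(f"ROI {l} is empty")
        means[l] = 0.5 * (v1[m].mean() + v2[m].mean())
        noise[l] = (v1[m] - v2[m]).std(ddof=1) / np.sqrt(2.0)
    out = {}
    for l in labels:
        if l == reference_label:
            continue
        contrast = abs(means[l] - means[reference_label])
        out[l] = 0.0 if contrast == 0 else (np.inf if noise[l] == 0 else contrast / noise[l])
    return out


def cnr_surface(
    fit1, fit2,
    rois: np.ndarray,
    reference_label: int = 1,
    ac_values=np.arange(0.0, 50001.0, 5000.0),
    bc_values=np.arange(0.0, 5001.0, 500.0),
) -> pd.DataFrame:
    """CNR of every ROI over a grid of niceDWI weighting parameters.

    ``fit1``/``fit2`` are ADCFitResults from two independent repeat
    experiments on identical geometry.  Returns one row per
    (roi, a_c, b_c).
    """
    rows = []
    for ac in np.asarray(ac_values, float):
        for bc in np.asarray(bc_values, float):
            img1 = nicedwi_image(fit1.adc_map, fit1.sigma_adc_map, ac, bc)
            img2 = nicedwi_image(fit2.adc_map, fit2.sigma_adc_map, ac, bc)
            for roi, val in cnr(img1, img2, rois, reference_label).items():
                rows.append({"roi": roi, "a_c": ac, "b_c": bc, "cnr": val})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Body-like volume and the Omega (SIWLS smoothing width) study
# ---------------------------------------------------------------------------

def synth_body(
    shape=(64, 64, 24),
    voxel_spacing=(3.4, 3.4, 5.0),
    bvalues=(50.0, 600.0, 900.0),
    n_directions: int = 3,
    n_repeats: int = 3,
    snr: float = 40.0,
    tissue_adc: float = 1.6e-3,
    lesion_adc: float = 0.7e-3,
    n_lesions: int = 6,
    lesion_radius: tuple = (3.0, 5.0),
    n_stations: int = 3,
    station_gain_range: tuple = (0.8, 1.2),
    bias_amplitude: float = 0.3,
    seed=None,
):
    """Synthetic torso volume with the artefacts whole-body DWI suffers from.

    An elliptical-cylinder torso of uniform soft tissue with randomly placed
    low-ADC ellipsoidal lesions; S0 carries a smooth in-plane multiplicative
    coil-sensitivity bias field, and the volume is split into axial
    acquisition stations each with its own receive gain.  Gain and bias are
    applied to the reconstructed magnitudes, so the effective noise SD (and
    hence the true sigma_nu field) varies smoothly in-plane and jumps at
    station boundaries -- the regime in which a single best smoothing width
    exists for SIWLS.

    Returns (series, lesion_mask).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    nx, ny, nz = shape
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    cx, cy = nx / 2 - 0.5, ny / 2 - 0.5
    torso2d = ((xx - cx) / (0.42 * nx)) ** 2 + ((yy - cy) / (0.34 * ny)) ** 2 <= 1.0
    torso = np.repeat(torso2d[:, :, None], nz, axis=2)

    adc = np.where(torso, tissue_adc, 0.0)
    lesion_mask = np.zeros(shape, bool)
    zz = np.arange(nz)
    placed = 0
    while placed < n_lesions:
        r = rng.uniform(*lesion_radius)
        lx = rng.uniform(cx - 0.3 * nx, cx + 0.3 * nx)
        ly = rng.uniform(cy - 0.22 * ny, cy + 0.22 * ny)
        rz = r * voxel_spacing[0] / voxel_spacing[2]  # z half-extent in slices
        lz = rng.uniform(rz, nz - rz) if nz > 2 * rz else nz / 2.0
        ell = ((xx[:, :, None] - lx) ** 2 + (yy[:, :, None] - ly) ** 2
               + ((zz[None, None, :] - lz) * voxel_spacing[2] / voxel_spacing[0]) ** 2
               ) <= r**2
        if not (ell & ~torso).any():
            lesion_mask |= ell
            placed += 1
    adc[lesion_mask] = lesion_adc

    s0 = np.where(torso, 1.0, 0.0)
    # smooth in-plane coil-sensitivity bias field
    bx, by = rng.uniform(0.2, 0.8, 2)
    bias2d = 1.0 + bias_amplitude * np.exp(
        -(((xx / nx - bx) ** 2) + ((yy / ny - by) ** 2)) / 0.15)
    gain_field = np.repeat(bias2d[:, :, None], nz, axis=2)
    # per-station receive gain jumps
    edges = np.linspace(0, nz, n_stations + 1).astype(int)
    for s in range(n_stations):
        g = rng.uniform(*station_gain_range)
        gain_field[:, :, edges[s]:edges[s + 1]] *= g

    b = np.asarray(bvalues, float)
    full_b = np.repeat(b, n_directions * n_repeats)
    sigma = 1.0 / snr
    mu = s0[..., None] * np.exp(-full_b * adc[..., None])
    noisy = sample_rician(mu, sigma, mu.shape, rng) * gain_field[..., None]
    series = DWISeries(signal=noisy, bvalues=full_b,
                       voxel_spacing=voxel_spacing, mask=torso)
    return series, lesion_mask


def omega_rmse_study(
    body_series: DWISeries,
    omegas,
    lesion_mask: np.ndarray | None = None,
    directions_per_repeat: int = 3,
) -> pd.DataFrame:
    """RMSE of SIWLS-on-averaged-data sigma_ADC maps against the IWLS gold
    standard, per smoothing width Omega.

    The gold standard retains every excitation (IWLS, k = N*M - 2); the
    candidate pipeline vendor-averages first, then runs SIWLS with each
    Omega.  Both maps are bias-corrected so their expectations coincide.
    Returns a table of (omega, rmse_whole, rmse_lesion).
    """
    omegas = [int(o) for o in np.atleast_1d(omegas)]
    if not omegas:
        raise ValueError("omega list must not be empty")
    gold = apply_bias_correction(ADCModel(body_series).fit("iwls"))
    averaged = vendor_average(body_series, directions_per_repeat)
    model = ADCModel(averaged)
    rows = []
    for om in omegas:
        fit = apply_bias_correction(model.fit("siwls", omega=om))
        diff = fit.sigma_adc_map - gold.sigma_adc_map
        ok = np.isfinite(diff)
        rmse = float(np.sqrt(np.mean(diff[ok] ** 2)))
        row = {"omega": om, "rmse_whole": rmse}
        if lesion_mask is not None:
            sel = ok & lesion_mask
            row["rmse_lesion"] = float(np.sqrt(np.mean(diff[sel] ** 2)))
        rows.append(row)
    return pd.DataFrame(rows)
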