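"""Voxel-wise weighted least-squares estimation of ADC and its uncertainty.

Three fitters for the log-linearised monoexponential model
y = ln S0 - b*ADC + eps, eps ~ N(0, sigma_nu / (S0 exp(-b*ADC))):

DWLS
    Direct weighted least squares.  Requires >= 3 excitations per b-value;
    the weight at each b-value is the inverse empirical variance of the
    repeated log-signals, and the parameter covariance is (B^T W B)^(-1)
    directly (the weights are absolute inverse variances).

IWLS
    Iterative weighted least squares.  Starts from the unweighted solution
    and alternates weight update W = diag(exp(2*B*alpha)) -- the squared
    model-predicted signal, i.e. the inverse of the log-domain noise variance
    up to the global sigma_nu^2 -- with a re-solve, until the parameter
    change falls below a tolerance.  The covariance is
    (B^T W B)^(-1) * sigma_nu_hat^2 with the weighted residual variance
    sigma_nu_hat^2 = r^T W r / (rows - 2).

SIWLS
    IWLS followed by spatial box-smoothing of the sigma_nu_hat^2 field
    before the covariance is formed.  A box kernel of odd width Omega
    multiplies the effective chi-square degrees of freedom by Omega^2
    (per-slice smoothing) or Omega^3 (volumetric).

All fitters share the design-matrix convention: rows of B are (b_i, 1), the
fitted slope equals -ADC, and sigma_ADC is the square root of the first
diagonal element of the parameter covariance.

The implementation is vectorised over voxels; maps for a whole-body volume
fit in seconds.  Log-transform of a non-positive magnitude is flagged
invalid and that row is dropped from the voxel's regression; a voxel with
fewer than 3 valid rows is unfittable and returns NaN.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.ndimage import uniform_filter

from .data import AcquisitionDesign, DWISeries
from .noise import bias_factor_c

__all__ = [
    "ADCModel",
    "ADCFitResults",
    "dwls_fit",
    "iwls_fit",
    "siwls_fit",
    "apply_bias_correction",
]

Method = Literal["dwls", "iwls", "siwls"]

# factor applied to the largest finite weight when an empirical variance is
# exactly zero (identical repeats): keeps the exact-interpolation limit
# without propagating infinities
_ZERO_VAR_WEIGHT_BOOST = 1e6


def _solve_wls(B: np.ndarray, Y: np.ndarray, w: np.ndarray):
    """Solve the weighted normal equations per voxel.

    B : (R, 2); Y, w : (V, R).  Returns alpha (V, 2) and the inverse normal
    matrix A = (B^T W B)^(-1), shape (V, 2, 2); singular voxels give NaN.
    """
    # normal matrix elements, vectorised: S_pq = sum_r w_r * B[r,p] * B[r,q]
    wb0 = w * B[:, 0]
    s00 = wb0 @ B[:, 0]
    s01 = wb0 @ B[:, 1]
    s11 = w @ (B[:, 1] ** 2)
    t0 = (w * Y) @ B[:, 0]
    t1 = (w * Y) @ B[:, 1]
    det = s00 * s11 - s01 * s01
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_det = np.where(det > 0, 1.0 / det, np.nan)
    a00 = s11 * inv_det
    a01 = -s01 * inv_det
    a11_ = s00 * inv_det
    alpha = np.stack([a00 * t0 + a01 * t1, a01 * t0 + a11_ * t1], axis=-1)
    A = np.stack(
        [np.stack([a00, a01], axis=-1), np.stack([a01, a11_], axis=-1)], axis=-2
    )
    return alpha, A


@dataclass
class ADCFitResults:
    """Maps and diagnostics from a voxel-wise weighted least-squares fit.

    Attributes
    ----------
    adc_map : ndarray (x, y, z)
        Apparent diffusion coefficient, mm^2/s (negated fitted slope).
    ln_s0_map : ndarray
        Fitted log-signal at b=0.
    sigma_adc_map : ndarray
        Standard error of the ADC estimate, mm^2/s.
    sigma_nu_sq_map : ndarray
        Weighted residual variance per voxel (signal-noise variance estimate
        for IWLS/SIWLS; dimensionless for DWLS whose weights are absolute).
    k : float
        Nominal residual degrees of freedom (rows - 2, times the kernel area
        for SIWLS); governs the chi-distribution bias factor c(k).
    iterations_map, converged_map : ndarray
        Iteration count and convergence flag (IWLS/SIWLS; DWLS reports 1/True).
    """

    adc_map: np.ndarray
    ln_s0_map: np.ndarray
    sigma_adc_map: np.ndarray
    sigma_nu_sq_map: np.ndarray
    k: float
    iterations_map: np.ndarray
    converged_map: np.ndarray
    method: str
    bias_corrected: bool = False
    n_unfittable: int = 0
    params: dict = field(default_factory=dict)
    affine: np.ndarray | None = field(default=None, repr=False)

    @property
    def fitted_mask(self) -> np.ndarray:
        return np.isfinite(self.adc_map)

    @property
    def s0_map(self) -> np.ndarray:
        return np.exp(self.ln_s0_map)

    def correct_bias(self) -> "ADCFitResults":
        """Return a copy with sigma_ADC divided by the chi bias factor c(k)."""
        if self.bias_corrected:
            raise RuntimeError("bias correction already applied")
        out = copy.deepcopy(self)
        out.sigma_adc_map = self.sigma_adc_map / bias_factor_c(self.k)
        out.bias_corrected = True
        return out

    def summary(self) -> str:
        fitted = self.fitted_mask
        n_fit = int(fitted.sum())
        lines = [
            "Voxel-wise ADC fit",
            "=" * 48,
            f"method:             {self.method.upper()}",
            f"degrees of freedom: {self.k:g}",
            f"bias corrected:     {self.bias_corrected}",
            f"voxels fitted:      {n_fit}",
            f"voxels unfittable:  {self.n_unfittable}",
        ]
        if n_fit:
            adc = self.adc_map[fitted]
            sig = self.sigma_adc_map[fitted]
            conv = self.converged_map[fitted]
            lines += [
                f"median ADC:         {np.median(adc):.4g} mm^2/s",
                f"median sigma_ADC:   {np.median(sig):.4g} mm^2/s",
                f"converged:          {100.0 * conv.mean():.1f}%",
                f"median iterations:  {np.median(self.iterations_map[fitted]):g}",
            ]
        if self.params:
            lines.append(f"parameters:         {self.params}")
        return "\n".join(lines)


class ADCModel:
    """Monoexponential decay model for a diffusion-weighted series.

    Parameters
    ----------
    series : DWISeries
        Per-excitation (or vendor-averaged) magnitude data.
    design : AcquisitionDesign, optional
        Defaults to the design implied by ``series.bvalues``.

    Examples
    --------
    >>> model = ADCModel(series)
    >>> res = model.fit(method="iwls")
    >>> print(res.summary())
    """

    def __init__(self, series: DWISeries, design: AcquisitionDesign | None = None):
        self.series = series
        self.design = design if design is not None else series.design()
        if self.design.total_rows != series.n_volumes:
            raise ValueError("design rows must match series volumes")
        shape = series.shape
        if series.mask is not None:
            self._vox_idx = np.flatnonzero(series.mask.ravel())
        else:
            self._vox_idx = np.arange(int(np.prod(shape)))
        sig = series.signal.reshape(-1, series.n_volumes)[self._vox_idx]
        self._valid = sig > 0
        with np.errstate(divide="ignore"):
            self._Y = np.where(self._valid, np.log(np.where(self._valid, sig, 1.0)), 0.0)
        self._n_valid = self._valid.sum(axis=1)

    # -- internal helpers ---------------------------------------------------

    def _to_map(self, flat: np.ndarray, fill=np.nan) -> np.ndarray:
        out = np.full(int(np.prod(self.series.shape)), fill, dtype=flat.dtype)
        out[self._vox_idx] = flat
        return out.reshape(self.series.shape)

    def _fittable(self) -> np.ndarray:
        return self._n_valid >= 3

    # -- public API ---------------------------------------------------------

    def fit(self, method: Method = "iwls", **kwargs) -> ADCFitResults:
        """Fit the model with the chosen weighting scheme.

        Keyword arguments are passed to the per-method fitters:
        ``n_iter``/``tol`` for IWLS, plus ``omega``/``kernel``/``dims``
        for SIWLS.
        """
        method = method.lower()
        if method == "dwls":
            return self._fit_dwls(**kwargs)
        if method == "iwls":
            return self._fit_iwls(**kwargs)
        if method == "siwls":
            return self._fit_siwls(**kwargs)
        raise ValueError(f"unknown method {method!r}")

    # -- DWLS ---------------------------------------------------------------

    def _fit_dwls(self) -> ADCFitResults:
        des = self.design
        if des.repeats_per_b.min() < 3:
            raise ValueError(
                "DWLS requires at least 3 excitations at every b-value; "
                f"got repeats {des.repeats_per_b.tolist()}"
            )
        B = des.design_matrix
        V = self._Y.shape[0]
        w = np.zeros((V, B.shape[0]))
        # per-b inverse empirical variance of the log-signals, shared by all
        # rows at that b-value
        for b in des.unique_bvalues:
            cols = np.flatnonzero(des.bvalues == b)
            yb = self._Y[:, cols]
            vb = self._valid[:, cols]
            nb = vb.sum(axis=1)
            mean = np.where(nb > 0, (yb * vb).sum(axis=1) / np.maximum(nb, 1), 0.0)
            ss = ((yb - mean[:, None]) ** 2 * vb).sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                var = np.where(nb >= 2, ss / np.maximum(nb - 1, 1), np.nan)
                wb = np.where(var > 0, 1.0 / var, np.inf)
            wb = np.where(nb >= 2, wb, 0.0)  # too few repeats: row excluded
            w[:, cols] = wb[:, None]
        w *= self._valid
        # zero-variance b-values (identical repeats): weight would be infinite.
        # Replace with the largest finite weight at that voxel, boosted; if no
        # finite weight exists anywhere (noise-free voxel), use unit weights.
        inf_w = np.isinf(w)
        if inf_w.any():
            finite_w = np.where(inf_w, 0.0, w)
            wmax = finite_w.max(axis=1)
            all_inf = wmax == 0
            repl = np.where(all_inf, 1.0, wmax * _ZERO_VAR_WEIGHT_BOOST)
            w = np.where(inf_w, repl[:, None] * self._valid, w)
        fittable = self._fittable() & ((w > 0).sum(axis=1) >= 3)
        alpha, A = _solve_wls(B, self._Y, np.where(fittable[:, None], w, 0.0))
        adc = -alpha[:, 0]
        sigma_adc = np.sqrt(A[:, 0, 0])
        # weighted residual variance (informational for DWLS)
        resid = self._Y - alpha @ B.T
        dof = np.maximum(self._n_valid - 2, 1)
        sig_nu_sq = (w * resid**2).sum(axis=1) / dof
        bad = ~fittable | ~np.isfinite(adc)
        for arr in (adc, sigma_adc, sig_nu_sq):
            arr[bad] = np.nan
        alpha[bad] = np.nan
        k = des.dof
        return ADCFitResults(
            adc_map=self._to_map(adc),
            ln_s0_map=self._to_map(alpha[:, 1]),
            sigma_adc_map=self._to_map(sigma_adc),
            sigma_nu_sq_map=self._to_map(sig_nu_sq),
            k=float(k),
            iterations_map=self._to_map(np.where(bad, 0, 1).astype(float)),
            converged_map=self._to_map((~bad).astype(float)).astype(bool),
            method="dwls",
            n_unfittable=int(bad.sum()),
            affine=self.series.affine,
        )

    # -- IWLS ---------------------------------------------------------------

    def _iwls_core(self, n_iter: int, tol: float):
        """Run the iterative reweighting on all fittable voxels.

        Returns flat arrays: alpha (V,2), A (V,2,2), sigma_nu_sq, iterations,
        converged, fittable.
        """
        des = self.design
        if des.total_rows < 3:
            raise ValueError("IWLS needs at least 3 rows in total")
        B = des.design_matrix
        fittable = self._fittable()
        Y = self._Y
        vmask = self._valid.astype(float)
        vmask[~fittable] = 0.0
        # unweighted start (valid rows only)
        alpha, _ = _solve_wls(B, Y, vmask)
        alpha = np.nan_to_num(alpha)
        iterations = np.zeros(Y.shape[0], dtype=int)
        converged = np.zeros(Y.shape[0], dtype=bool)
        active = fittable.copy()
        w = vmask.copy()
        for t in range(1, n_iter + 1):
            if not active.any():
                break
            ypred = alpha[active] @ B.T
            w_act = np.exp(2.0 * ypred) * vmask[active]
            new_alpha, _ = _solve_wls(B, Y[active], w_act)
            delta = np.max(np.abs(new_alpha - alpha[active]), axis=1)
            ok = np.isfinite(delta)
            newly = (delta < tol) & ok
            idx = np.flatnonzero(active)
            alpha[idx[ok]] = new_alpha[ok]
            iterations[idx] = t
            converged[idx[newly]] = True
            w[idx] = w_act
            still = ~newly & ok
            active[:] = False
            active[idx[still]] = True
        # final weights/covariance at the last iterate
        ypred = alpha @ B.T
        w = np.exp(2.0 * ypred) * vmask
        _, A = _solve_wls(B, Y, w)  # covariance at the last iterate's weights
        resid = Y - alpha @ B.T
        dof = np.maximum(self._n_valid - 2, 1)
        sigma_nu_sq = (w * resid**2).sum(axis=1) / dof
        bad = ~fittable | ~np.isfinite(alpha).all(axis=1) | ~np.isfinite(A[:, 0, 0])
        return alpha, A, sigma_nu_sq, iterations, converged, ~bad

    def _fit_iwls(self, n_iter: int = 100, tol: float = 1e-5) -> ADCFitResults:
        alpha, A, sig_nu_sq, iters, conv, good = self._iwls_core(n_iter, tol)
        adc = -alpha[:, 0]
        sigma_adc = np.sqrt(A[:, 0, 0] * sig_nu_sq)
        for arr in (adc, sigma_adc, sig_nu_sq):
            arr[~good] = np.nan
        alpha[~good] = np.nan
        return ADCFitResults(
            adc_map=self._to_map(adc),
            ln_s0_map=self._to_map(alpha[:, 1]),
            sigma_adc_map=self._to_map(sigma_adc),
            sigma_nu_sq_map=self._to_map(sig_nu_sq),
            k=float(self.design.dof),
            iterations_map=self._to_map(iters.astype(float)),
            converged_map=self._to_map(conv.astype(float)).astype(bool),
            method="iwls",
            n_unfittable=int((~good).sum()),
            params={"n_iter": n_iter, "tol": tol},
            affine=self.series.affine,
        )

    # -- SIWLS --------------------------------------------------------------

    def _fit_siwls(
        self,
        omega: int = 20,
        kernel: str = "box",
        dims: Literal["2D", "3D"] = "2D",
        n_iter: int = 100,
        tol: float = 1e-5,
    ) -> ADCFitResults:
        if kernel != "box":
            raise ValueError(f"unsupported kernel {kernel!r}")
        omega = int(omega)
        if omega < 1 or omega % 2 == 0:
            raise ValueError(f"omega must be an odd positive integer, got {omega}")
        alpha, A, sig_nu_sq, iters, conv, good = self._iwls_core(n_iter, tol)
        sig_map = self._to_map(np.where(good, sig_nu_sq, np.nan))
        smoothed = _box_smooth_nan(sig_map, omega, dims)
        sm_flat = smoothed.reshape(-1)[self._vox_idx]
        adc = -alpha[:, 0]
        sigma_adc = np.sqrt(A[:, 0, 0] * sm_flat)
        for arr in (adc, sigma_adc, sm_flat):
            arr[~good] = np.nan
        alpha[~good] = np.nan
        k_eff = self.design.dof * (omega**2 if dims == "2D" else omega**3)
        return ADCFitResults(
            adc_map=self._to_map(adc),
            ln_s0_map=self._to_map(alpha[:, 1]),
            sigma_adc_map=self._to_map(sigma_adc),
            sigma_nu_sq_map=self._to_map(sm_flat),
            k=float(k_eff),
            iterations_map=self._to_map(iters.astype(float)),
            converged_map=self._to_map(conv.astype(float)).astype(bool),
            method="siwls",
            n_unfittable=int((~good).sum()),
            params={"omega": omega, "kernel": kernel, "dims": dims,
                    "n_iter": n_iter, "tol": tol},
            affine=self.series.affine,
        )


def _box_smooth_nan(field: np.ndarray, omega: int, dims: str) -> np.ndarray:
    """Box-average a 3D field, renormalising the kernel over valid voxels.

    NaN (unfitted/background) voxels carry zero kernel mass, so the average
    near edges is taken over the in-support neighbourhood only -- no dark rim
    from zero padding.
    """
    if omega == 1:
        return field.copy()
    valid = np.isfinite(field)
    filled = np.where(valid, field, 0.0)
    size = (omega, omega, 1) if dims == "2D" else (omega, omega, omega)
    num = uniform_filter(filled, size=size, mode="constant", cval=0.0)
    den = uniform_filter(valid.astype(float), size=size, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(valid & (den > 0), num / den, np.nan)
    return out


# -- functional wrappers ----------------------------------------------------

def dwls_fit(series: DWISeries, design: AcquisitionDesign | None = None) -> ADCFitResults:
    """Direct weighted least-squares fit (empirical repeat-variance weights)."""
    return ADCModel(series, design).fit(method="dwls")


def iwls_fit(
    series: DWISeries,
    design: AcquisitionDesign | None = None,
    N_t: int = 100,
    eps: float = 1e-5,
) -> ADCFitResults:
    """Iterative weighted least-squares fit with model-derived weights."""
    return ADCModel(series, design).fit(method="iwls", n_iter=N_t, tol=eps)


def siwls_fit(
    series: DWISeries,
    design: AcquisitionDesign | None = None,
    omega: int = 20,
    kernel: str = "box",
    dims: Literal["2D", "3D"] = "2D",
    N_t: int = 100,
    eps: float = 1e-5,
) -> ADCFitResults:
    """IWLS with spatially smoothed residual variance (box kernel, width omega)."""
    return ADCModel(series, design).fit(
        method="siwls", omega=omega, kernel=kernel, dims=dims, n_iter=N_t, tol=eps
    )


def apply_bias_correction(fit: ADCFitResults) -> ADCFitResults:
    """Divide the sigma_ADC map by the chi bias factor c(k) (unbiased estimator)."""
    return fit.correct_bias()
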