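"""Computed diffusion-weighted image synthesis.

Three flavours of synthetic contrast from fitted parameter maps:

cDWI
    S0 * exp(-b_c * ADC): monoexponential extrapolation to a computed
    b-value b_c, retaining the scanner's S0 contrast (and hence its coil
    sensitivity, T1/T2 weighting and station gain).

eDWI
    exp(-b_c * ADC): S0 replaced by a constant, leaving pure ADC contrast.

niceDWI
    exp(-a_c * sigma_ADC) * exp(-b_c * ADC): eDWI additionally down-weighted
    where the ADC estimate is uncertain.  Values lie in (0, 1]; a_c (units
    conjugate to sigma_ADC) and b_c (s/mm^2) trade off uncertainty vs ADC
    weighting and can be swept cheaply for display.

Plus maximum-intensity projections for whole-body display (optionally on the
inverse grayscale convention where low-ADC/low-uncertainty disease is dark
on white).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ComputedImage", "nicedwi_image", "cdwi_image", "edwi_image", "mip"]

_AXES = {"sagittal": 0, "coronal": 1, "axial": 2}


@dataclass
class ComputedImage:
    """A synthesised volume with the weighting parameters that produced it."""

    values: np.ndarray
    kind: str  # {"niceDWI", "cDWI", "eDWI"}
    a_c: float = 0.0
    b_c: float = 0.0
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = field(default=None, repr=False)


def _check_weights(a_c: float, b_c: float) -> None:
    if a_c < 0 or b_c < 0:
        raise ValueError(f"computed weights must be non-negative, got a_c={a_c}, b_c={b_c}")


def nicedwi_image(
    adc_map: np.ndarray,
    sigma_adc_map: np.ndarray,
    a_c: float,
    b_c: float,
    fill_background: bool = True,
    **meta,
) -> ComputedImage:
    """Noise-corrected exponentially weighted image exp(-a_c*sigma_ADC - b_c*ADC).

    Purely quantitative: independent of S0 and hence of coil-sensitivity bias
    fields and inter-station gain.  NaN in either input map propagates; with
    ``fill_background`` unfitted voxels render as 0 (background-dark).
    """
    _check_weights(a_c, b_c)
    vals = np.exp(-a_c * np.asarray(sigma_adc_map, float)) * np.exp(
        -b_c * np.asarray(adc_map, float)
    )
    if fill_background:
        vals = np.where(np.isnan(vals), 0.0, vals)
    return ComputedImage(values=vals, kind="niceDWI", a_c=a_c, b_c=b_c, **meta)


def edwi_image(adc_map: np.ndarray, b_c: float, fill_background: bool = True, **meta) -> ComputedImage:
    """Exponentially weighted image exp(-b_c*ADC); niceDWI with a_c = 0."""
    out = nicedwi_image(adc_map, np.zeros_like(np.asarray(adc_map, float)), 0.0,
                        b_c, fill_background=fill_background, **meta)
    out.kind = "eDWI"
    return out


def cdwi_image(s0_map: np.ndarray, adc_map: np.ndarray, b_c: float, **meta) -> ComputedImage:
    """Computed DWI S0*exp(-b_c*ADC) in scanner units."""
    _check_weights(0.0, b_c)
    vals = np.asarray(s0_map, float) * np.exp(-b_c * np.asarray(adc_map, float))
    return ComputedImage(values=vals, kind="cDWI", b_c=b_c, **meta)


def mip(image: ComputedImage, axis: str = "coronal", invert: bool = False) -> np.ndarray:
    """Maximum-intensity projection of a computed volume along an anatomical axis.

    NaN voxels are excluded from each ray.  With anisotropic voxel spacing the
    volume is first resampled (nearest neighbour) to an isotropic grid so the
    projection is not geometrically distorted.  ``invert`` maps v -> 1 - v for
    the inverse-grayscale whole-body display convention.
    """
    vol = np.asarray(image.values, float)
    if vol.ndim != 3:
        raise ValueError(f"MIP requires a 3D volume, got ndim={vol.ndim}")
    try:
        ax = _AXES[axis]
    except KeyError:
        raise ValueError(f"axis must be one of {sorted(_AXES)}, got {axis!r}") from None
    sp = np.asarray(image.voxel_spacing, float)
    if not np.allclose(sp, sp[0]):
        iso = sp.min()
        idx = [np.clip(np.round(np.arange(0, n * s / iso) * iso / s).astype(int), 0, n - 1)
               for n, s in zip(vol.shape, sp)]
        vol = vol[np.ix_(idx[0], idx[1], idx[2])]
    finite = np.isfinite(vol)
    proj = np.where(finite, vol, -np.inf).max(axis=ax)
    proj = np.where(np.isneginf(proj), np.nan, proj)  # all-NaN rays
    return 1.0 - proj if invert else proj
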