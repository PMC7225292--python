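"""Diffusion-weighted image series, acquisition design and the monoexponential
signal model.

The data model assumes magnitude DWI volumes acquired at a set of diffusion
weightings (b-values, s/mm^2), possibly with several excitations (orthogonal
encoding directions x repeat acquisitions) per b-value.  Under the isotropy
assumption every excitation at a given b-value is an independent repeat of the
same monoexponential decay

    S(b) = S0 * exp(-b * ADC) + noise .

Log-transforming linearises the model, y = ln S0 - b*ADC, at the cost of
heteroscedastic noise whose standard deviation grows as the inverse of the
decayed signal -- the reason weighted least squares is used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DWISeries",
    "AcquisitionDesign",
    "LogSignal",
    "forward_signal",
    "log_transform",
    "log_noise_sd",
    "vendor_average",
]


@dataclass
class DWISeries:
    """A 4D stack of per-excitation magnitude volumes with per-volume b-values.

    Parameters
    ----------
    signal : ndarray, shape (x, y, z, n_volumes)
        Non-negative magnitude data in arbitrary scanner units.
    bvalues : ndarray, shape (n_volumes,)
        Diffusion weighting of each volume, s/mm^2.
    voxel_spacing : tuple of float
        Voxel size in mm, (dx, dy, dz).
    mask : ndarray of bool, shape (x, y, z), optional
        Voxels to fit; everything outside is left as NaN in output maps.
    affine : ndarray (4, 4), optional
        NIfTI affine, carried through for round-trip I/O.
    """

    signal: np.ndarray
    bvalues: np.ndarray
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    mask: np.ndarray | None = None
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.bvalues = np.atleast_1d(np.asarray(self.bvalues, dtype=float))
        if self.signal.ndim != 4:
            raise ValueError(
                f"signal must be 4D (x, y, z, volume); got ndim={self.signal.ndim}"
            )
        if self.signal.shape[-1] != self.bvalues.size:
            raise ValueError(
                f"{self.signal.shape[-1]} volumes but {self.bvalues.size} b-values"
            )
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")
        if np.any(self.signal < 0):
            raise ValueError("signal contains negative values; magnitude data expected")
        if np.any(self.bvalues < 0) or not np.all(np.isfinite(self.bvalues)):
            raise ValueError("b-values must be finite and non-negative")
        if np.unique(self.bvalues).size < 2:
            raise ValueError("at least 2 distinct b-values are required")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.signal.shape[:3]:
                raise ValueError("mask shape must match the spatial grid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.signal.shape[-1]

    @property
    def unique_bvalues(self) -> np.ndarray:
        return np.unique(self.bvalues)

    def design(self) -> "AcquisitionDesign":
        """Acquisition design implied by the per-volume b-values."""
        return AcquisitionDesign.from_bvalues(self.bvalues)


@dataclass
class AcquisitionDesign:
    """b-value layout and the stacked regression design matrix.

    ``design_matrix`` has one row (b_i, 1) per acquired volume; the fitted
    slope of the log-signal regression equals -ADC (see :mod:`nicedwi.model`).
    """

    unique_bvalues: np.ndarray
    repeats_per_b: np.ndarray
    bvalues: np.ndarray  # per-row b, in acquisition order

    @classmethod
    def from_bvalues(cls, bvalues: Sequence[float]) -> "AcquisitionDesign":
        bvalues = np.atleast_1d(np.asarray(bvalues, dtype=float))
        uniq, counts = np.unique(bvalues, return_counts=True)
        if uniq.size < 2:
            raise ValueError("design needs at least 2 distinct b-values")
        return cls(unique_bvalues=uniq, repeats_per_b=counts, bvalues=bvalues)

    @property
    def design_matrix(self) -> np.ndarray:
        """The (N*M, 2) matrix B with rows (b_i, 1)."""
        return np.column_stack([self.bvalues, np.ones_like(self.bvalues)])

    @property
    def total_rows(self) -> int:
        return int(self.bvalues.size)

    @property
    def n_unique(self) -> int:
        return int(self.unique_bvalues.size)

    @property
    def dof(self) -> int:
        """Residual degrees of freedom of the two-parameter fit, N*M - 2."""
        return self.total_rows - 2

    def averaged(self) -> "AcquisitionDesign":
        """Design after vendor averaging: one row per unique b-value."""
        return AcquisitionDesign.from_bvalues(self.unique_bvalues)


@dataclass
class LogSignal:
    """Log-transformed signals with per-entry validity flags.

    Entries where the raw magnitude was <= 0 are flagged invalid rather than
    clipped; downstream fitters exclude them from the regression.
    """

    y: np.ndarray
    valid: np.ndarray


def forward_signal(
    S0: float, ADC: float, bvalues: Sequence[float]
) -> np.ndarray:
    """Noise-free monoexponential signal S0*exp(-b*ADC) at each b-value.

    Parameters are scalar: S0 > 0 (scanner units), ADC >= 0 (mm^2/s),
    bvalues in s/mm^2.
    """
    if S0 <= 0:
        raise ValueError(f"S0 must be positive, got {S0}")
    if ADC < 0:
        raise ValueError(f"ADC must be non-negative, got {ADC}")
    b = np.asarray(bvalues, dtype=float)
    return S0 * np.exp(-b * ADC)


def log_transform(series: DWISeries) -> LogSignal:
    """Natural log of the signal; non-positive entries flagged invalid."""
    valid = series.signal > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        y = np.where(valid, np.log(np.where(valid, series.signal, 1.0)), np.nan)
    return LogSignal(y=y, valid=valid)


def log_noise_sd(S0: float, ADC: float, b: float, sigma_nu: float) -> float:
    """Log-domain noise SD under additive signal noise of SD ``sigma_nu``.

    By first-order error propagation the log-signal noise is
    sigma_nu / (S0*exp(-b*ADC)): heteroscedastic, growing with b for ADC > 0.
    """
    if S0 <= 0 or sigma_nu <= 0:
        raise ValueError("S0 and sigma_nu must be positive")
    return float(sigma_nu / (S0 * np.exp(-b * ADC)))


def vendor_average(series: DWISeries, directions_per_repeat: int) -> DWISeries:
    """Collapse per-excitation data to one trace-weighted volume per b-value.

    Emulates the averaged product a scanner vendor returns: for each unique
    b-value, the geometric mean over the diffusion-encoding directions within
    each repeat (the trace-weighted image), then the arithmetic mean over
    repeats.

    Parameters
    ----------
    series : DWISeries
        Per-excitation data.  Within each unique b-value the volumes are taken
        in acquisition order as ``repeats`` consecutive groups of
        ``directions_per_repeat`` volumes.
    directions_per_repeat : int
        Number of orthogonal encoding directions per repeat (3 for a
        trace-weighted protocol, 1 if volumes are already trace-weighted).

    Returns
    -------
    DWISeries with one volume per unique b-value.
    """
    if directions_per_repeat < 1:
        raise ValueError("directions_per_repeat must be >= 1")
    out = []
    for b in series.unique_bvalues:
        idx = np.flatnonzero(series.bvalues == b)
        if idx.size % directions_per_repeat:
            raise ValueError(
                f"{idx.size} volumes at b={b} not divisible into groups of "
                f"{directions_per_repeat} directions"
            )
        n_rep = idx.size // directions_per_repeat
        vols = series.signal[..., idx]
        grouped = vols.reshape(series.shape + (n_rep, directions_per_repeat))
        # geometric mean over directions; zeros stay zero
        with np.errstate(divide="ignore"):
            logv = np.where(grouped > 0, np.log(np.where(grouped > 0, grouped, 1.0)), -np.inf)
        trace = np.exp(logv.mean(axis=-1))
        out.append(trace.mean(axis=-1))
    avg = np.stack(out, axis=-1)
    return DWISeries(
        signal=avg,
        bvalues=series.unique_bvalues,
        voxel_spacing=series.voxel_spacing,
        mask=series.mask,
        affine=series.affine,
    )
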