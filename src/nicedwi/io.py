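"""Reading and writing DWI series and fitted parameter maps.

NIfTI-1 (.nii / .nii.gz) 4D volumes with an FSL-style plain-text ``.bval``
sidecar (one whitespace-separated row, one entry per volume).  Per-volume
b-value repetition encodes the excitation layout; no separate repeats file
is needed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from . import __version__
from .data import DWISeries
from .model import ADCFitResults

__all__ = ["RunConfig", "read_bvals", "read_dwi", "write_dwi", "write_maps"]


@dataclass
class RunConfig:
    """A reproducible fitting-run configuration (YAML-serialisable).

    Defaults follow the recommended protocol: IWLS with N_t = 100,
    eps = 1e-5; SIWLS box kernel of width omega = 20.
    """

    input: str | None = None
    bval: str | None = None
    mask: str | None = None
    out: str = "nicedwi_out"
    method: str = "iwls"
    n_iter: int = 100
    eps: float = 1.0e-5
    omega: int = 20
    kernel: str = "box"
    a_c: float = 20_000.0
    b_c: float = 900.0
    seed: int = 0
    log_level: str = "info"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in ("dwls", "iwls", "siwls"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.n_iter < 1 or self.eps <= 0:
            raise ValueError("n_iter must be >= 1 and eps > 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        extra = dict(raw.pop("extra", {}))
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra.update({k: v for k, v in raw.items() if k not in known})
        return cls(**kwargs, extra=extra)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def read_bvals(bval_path) -> np.ndarray:
    """Read an FSL-dialect .bval file (or a JSON list)."""
    path = Path(bval_path)
    text = path.read_text().strip()
    if not text:
        raise ValueError(f"{path}: empty b-value file")
    if text.lstrip().startswith("["):
        vals = np.asarray(json.loads(text), dtype=float)
    else:
        try:
            vals = np.asarray(text.split(), dtype=float)
        except ValueError as err:
            raise ValueError(f"{path}: could not parse b-values") from err
    if np.any(vals < 0):
        raise ValueError(f"{path}: negative b-values")
    return vals


def read_dwi(nifti_path, bval_path) -> DWISeries:
    """Load a 4D NIfTI volume plus its b-value sidecar as a DWISeries."""
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{nifti_path}: expected a 4D volume, got ndim={data.ndim}")
    bvals = read_bvals(bval_path)
    if bvals.size != data.shape[-1]:
        raise ValueError(
            f"{bval_path}: {bvals.size} b-values for {data.shape[-1]} volumes "
            f"in {nifti_path}"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DWISeries(signal=data, bvalues=bvals, voxel_spacing=spacing,
                     affine=img.affine)


def write_dwi(series: DWISeries, nifti_path, bval_path=None) -> None:
    """Write a DWISeries as NIfTI + .bval (for round-tripping synthetic data)."""
    affine = series.affine
    if affine is None:
        affine = np.diag(list(series.voxel_spacing) + [1.0])
    img = nib.Nifti1Image(series.signal.astype(np.float32), affine)
    img.header.set_zooms(tuple(series.voxel_spacing) + (1.0,))
    nib.save(img, str(nifti_path))
    if bval_path is not None:
        Path(bval_path).write_text(
            " ".join(f"{b:g}" for b in series.bvalues) + "\n")


def write_maps(fit: ADCFitResults, out_dir, prefix: str = "") -> dict[str, Path]:
    """Write the fitted maps as NIfTI volumes plus a JSON metadata sidecar.

    One file per map (adc, sigma_adc, ln_s0, sigma_nu_sq, iterations,
    converged), mirroring the input geometry; the sidecar records the
    method, degrees of freedom, fit parameters and package version.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = fit.affine if fit.affine is not None else np.eye(4)
    maps = {
        "adc": fit.adc_map,
        "sigma_adc": fit.sigma_adc_map,
        "ln_s0": fit.ln_s0_map,
        "sigma_nu_sq": fit.sigma_nu_sq_map,
        "iterations": fit.iterations_map,
        "converged": fit.converged_map.astype(np.uint8),
    }
    written = {}
    for name, vol in maps.items():
        path = out_dir / f"{prefix}{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float32), affine), str(path))
        written[name] = path
    meta = {
        "method": fit.method,
        "k": fit.k,
        "bias_corrected": fit.bias_corrected,
        "n_unfittable": fit.n_unfittable,
        "params": {k: (v if not isinstance(v, np.generic) else v.item())
                   for k, v in fit.params.items()},
        "version": __version__,
    }
    sidecar = out_dir / f"{prefix}fit.json"
    sidecar.write_text(json.dumps(meta, indent=2) + "\n")
    written["sidecar"] = sidecar
    return written
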