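"""NIfTI + bval/bvec I/O and voxel-wise reconstruction.

Volumes are 4-D NIfTI-1 images (x, y, z, acquisition) accompanied by
FSL-dialect gradient tables: a ``.bval`` file with one whitespace-separated
row of b-values and a ``.bvec`` file with three rows holding the x, y and z
components of the gradient directions.  b-values below 50 s/mm^2 are
treated as zero-weighted baselines.  Directions are re-normalized on load
and treated as antipodally symmetric; bvecs are not reoriented by the image
affine (documented limitation).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from . import peak_analysis as pk
from .signal_sim import DWSignal, GradientScheme
from .sphere_math import n_sh_coeffs, real_sh_basis, tessellate_icosahedron

__all__ = [
    "DWIVolume",
    "B0_THRESHOLD",
    "load_dwi",
    "save_dwi",
    "signals_to_volume",
    "voxelwise_reconstruct",
]

B0_THRESHOLD = 50.0  # s/mm^2


@dataclass
class DWIVolume:
    """4-D diffusion-weighted dataset with its gradient table."""

    data: np.ndarray  # (x, y, z, n_acq)
    affine: np.ndarray
    bvals: np.ndarray  # (n_acq,)
    bvecs: np.ndarray  # (n_acq, 3)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("DWI data must be 4-D (x, y, z, acquisition)")
        n = self.data.shape[3]
        if len(self.bvals) != n or self.bvecs.shape != (n, 3):
            raise ValueError(
                f"gradient table length mismatch: {n} volumes, "
                f"{len(self.bvals)} b-values, {self.bvecs.shape[0]} directions"
            )

    @property
    def b0_index(self) -> np.ndarray:
        return np.flatnonzero(self.bvals < B0_THRESHOLD)

    @property
    def dw_index(self) -> np.ndarray:
        return np.flatnonzero(self.bvals >= B0_THRESHOLD)

    def scheme(self) -> GradientScheme:
        dw = self.dw_index
        return GradientScheme(
            directions=self.bvecs[dw],
            b=float(np.median(self.bvals[dw])),
            n_b0=len(self.b0_index),
        )


def _read_table(path: Path, expected_rows: int | None = None) -> np.ndarray:
    rows = [
        np.array(line.split(), dtype=float)
        for line in Path(path).read_text().splitlines()
        if line.strip()
    ]
    table = np.vstack(rows)
    if expected_rows is not None and table.shape[0] != expected_rows:
        raise ValueError(
            f"{path}: expected {expected_rows} rows (FSL dialect), "
            f"got {table.shape[0]}"
        )
    if not np.all(np.isfinite(table)):
        raise ValueError(f"{path}: non-finite entries")
    return table


def load_dwi(image_path, bval_path, bvec_path, mask_path=None) -> DWIVolume:
    """Load a NIfTI volume with FSL-dialect bval/bvec gradient tables."""
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{image_path}: expected a 4-D image, got {data.ndim}-D")
    bvals = _read_table(Path(bval_path)).ravel()
    bvecs = _read_table(Path(bvec_path), expected_rows=3).T
    if len(bvals) != data.shape[3] or bvecs.shape[0] != data.shape[3]:
        raise ValueError(
            f"gradient table length ({len(bvals)} bvals, {bvecs.shape[0]} "
            f"bvecs) does not match {data.shape[3]} volumes"
        )
    dw = bvals >= B0_THRESHOLD
    if not dw.any():
        raise ValueError("no diffusion-weighted volumes (all b < 50 s/mm^2)")
    norms = np.linalg.norm(bvecs, axis=1)
    if np.any(norms[dw] == 0):
        raise ValueError("zero-length direction for a diffusion-weighted volume")
    bvecs = bvecs.copy()
    bvecs[dw] /= norms[dw, None]
    mask = None
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    return DWIVolume(
        data=data, affine=img.affine, bvals=bvals, bvecs=bvecs, mask=mask
    )


def save_dwi(volume: DWIVolume, image_path, bval_path, bvec_path) -> None:
    """Write a NIfTI image and FSL-dialect bval/bvec text tables."""
    nib.Nifti1Image(volume.data.astype(np.float32), volume.affine).to_filename(
        str(image_path)
    )
    Path(bval_path).write_text(
        " ".join(f"{b:g}" for b in volume.bvals) + "\n"
    )
    lines = [
        " ".join(f"{c:.17g}" for c in volume.bvecs[:, axis])
        for axis in range(3)
    ]
    Path(bvec_path).write_text("\n".join(lines) + "\n")


def signals_to_volume(
    signals: np.ndarray,
    scheme: GradientScheme,
    b: float,
    b0_values: np.ndarray | None = None,
    affine: np.ndarray | None = None,
) -> DWIVolume:
    """Assemble simulated voxel signals into a 4-D dataset.

    ``signals`` has shape (x, y, z, NG) holding measured DW intensities;
    ``b0_values`` shape (x, y, z, n_b0) holds zero-weighted intensities
    (default: ones).  The b0 volumes are interleaved first, mirroring the
    acquisition bookkeeping.
    """
    signals = np.asarray(signals, dtype=float)
    n_b0 = scheme.n_b0 or 1
    if b0_values is None:
        b0_values = np.ones(signals.shape[:3] + (n_b0,))
    data = np.concatenate([b0_values, signals], axis=3)
    bvals = np.concatenate(
        [np.zeros(b0_values.shape[3]), np.full(scheme.n_gradients, b)]
    )
    bvecs = np.vstack(
        [np.zeros((b0_values.shape[3], 3)), scheme.directions]
    )
    return DWIVolume(
        data=data,
        affine=np.eye(4) if affine is None else affine,
        bvals=bvals,
        bvecs=bvecs,
    )


def save_coefficient_map(coeff_map: np.ndarray, affine: np.ndarray, path) -> None:
    """Write a voxel-wise SH coefficient map as 4-D NIfTI (one volume per
    coefficient)."""
    nib.Nifti1Image(np.asarray(coeff_map, dtype=np.float32), affine).to_filename(
        str(path)
    )


def voxelwise_reconstruct(
    volume: DWIVolume,
    method: str = "qball",
    lmax: int = 6,
    t_ms: float | None = None,
    mesh_order: int = 5,
    rel_threshold: float = 0.5,
    max_peaks: int = 3,
):
    """Per-voxel reconstruction + peak extraction over a masked volume.

    Normalizes each voxel by the mean of its b0 volumes, reconstructs with
    the chosen method, and extracts up to ``max_peaks`` mesh maxima.
    Returns ``(coeff_map, peak_map, flags)`` where ``coeff_map`` is
    (x, y, z, R), ``peak_map`` is (x, y, z, max_peaks, 3) and ``flags``
    marks voxels skipped for non-positive S0 or masked out.
    """
    from .experiments import _reconstruct

    scheme = volume.scheme()
    b = scheme.b
    if t_ms is None and method != "qball":
        raise ValueError("DOT methods require the diffusion time t_ms")
    shape = volume.data.shape[:3]
    n_coeff = n_sh_coeffs(lmax)
    coeff_map = np.zeros(shape + (n_coeff,))
    peak_map = np.zeros(shape + (max_peaks, 3))
    flags = np.zeros(shape, dtype=np.uint8)  # 1 = skipped
    mesh = tessellate_icosahedron(mesh_order)
    basis = real_sh_basis(mesh.vertices, lmax)
    b0 = volume.data[..., volume.b0_index]
    dw = volume.data[..., volume.dw_index]
    for idx in np.ndindex(shape):
        if volume.mask is not None and not volume.mask[idx]:
            flags[idx] = 1
            continue
        s0 = float(b0[idx].mean())
        if s0 <= 0:
            flags[idx] = 1
            continue
        att = dw[idx] / s0
        signal = DWSignal(attenuations=att, s0=s0, b0_values=b0[idx] / s0)
        odf = _reconstruct(method, signal, scheme, b, t_ms, lmax)
        coeff_map[idx] = odf.sh.coeffs
        values = basis @ odf.sh.coeffs
        try:
            peaks = pk.find_maxima(values, mesh, rel_threshold)
        except ValueError:
            flags[idx] = 1
            continue
        k = min(max_peaks, len(peaks))
        peak_map[idx][:k] = peaks.directions[:k]
    return coeff_map, peak_map, flags
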