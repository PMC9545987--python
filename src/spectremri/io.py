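"""File formats: the HDF5 raw-data container, FSL bval/bvec text files and
NIfTI image output.

The container stores everything a reconstruction needs: undersampled k-space
with its mask and parity labels, full-FOV coil sensitivities, noise-only
calibration samples, the diffusion protocol, and (for simulated data) the
ground-truth bundle used by the evaluation module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .simulate import DiffusionProtocol, GroundTruthBundle, MultiCoilKSpace

__all__ = [
    "RawDataContainer",
    "write_raw",
    "read_raw",
    "read_bvals_bvecs",
    "write_bvals_bvecs",
    "save_nifti",
]

FORMAT_VERSION = "spectremri-raw-1"

_TRUTH_FIELDS = ("images", "phase_maps", "psi_true", "md", "fa", "object_mask")


@dataclass
class RawDataContainer:
    kspace: MultiCoilKSpace
    sens: np.ndarray  # [coil, x, y, z]
    noise_samples: np.ndarray  # [coil, N]
    protocol: DiffusionProtocol
    truth: GroundTruthBundle | None = None
    seed: int = 0
    version: str = FORMAT_VERSION


def write_raw(path: str | Path, container: RawDataContainer) -> None:
    """Write a container to HDF5 (lossless round trip of arrays and attrs)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=container.kspace.data)
        f.create_dataset("mask", data=container.kspace.mask)
        f.create_dataset("parity", data=container.kspace.parity)
        f.create_dataset("sens", data=container.sens)
        f.create_dataset("noise_samples", data=container.noise_samples)
        f.create_dataset("protocol/bvals", data=container.protocol.bvals)
        f.create_dataset("protocol/bvecs", data=container.protocol.bvecs)
        if container.truth is not None:
            for name in _TRUTH_FIELDS:
                f.create_dataset(f"truth/{name}", data=getattr(container.truth, name))
            f["truth"].attrs["noise_rows"] = container.truth.noise_rows
        f.attrs["R"] = container.kspace.R
        f.attrs["seed"] = container.seed
        f.attrs["version"] = container.version
        f.attrs["grid"] = container.kspace.data.shape[1:4]


def read_raw(path: str | Path) -> RawDataContainer:
    """Read a container, raising KeyError naming any absent dataset."""
    with h5py.File(path, "r") as f:
        for key in ("kspace", "mask", "parity", "sens", "noise_samples",
                    "protocol/bvals", "protocol/bvecs"):
            if key not in f:
                raise KeyError(f"container is missing required dataset '/{key}'")
        version = f.attrs.get("version", "")
        if version != FORMAT_VERSION:
            warnings.warn(
                f"container version {version!r} differs from expected {FORMAT_VERSION!r}",
                stacklevel=2,
            )
        ks = MultiCoilKSpace(
            data=f["kspace"][()],
            mask=f["mask"][()],
            parity=f["parity"][()],
            R=int(f.attrs["R"]),
        )
        protocol = DiffusionProtocol(f["protocol/bvals"][()], f["protocol/bvecs"][()])
        truth = None
        if "truth" in f:
            truth = GroundTruthBundle(
                **{name: f[f"truth/{name}"][()] for name in _TRUTH_FIELDS},
                noise_rows=int(f["truth"].attrs.get("noise_rows", 8)),
            )
            truth.object_mask = truth.object_mask.astype(bool)
        return RawDataContainer(
            kspace=ks,
            sens=f["sens"][()],
            noise_samples=f["noise_samples"][()],
            protocol=protocol,
            truth=truth,
            seed=int(f.attrs.get("seed", 0)),
            version=str(version),
        )


def read_bvals_bvecs(bvals_path: str | Path, bvecs_path: str | Path) -> DiffusionProtocol:
    """Read an FSL-style protocol: bvals one whitespace row, bvecs three."""
    bvals = np.loadtxt(bvals_path).ravel()
    bvecs = np.loadtxt(bvecs_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    return DiffusionProtocol(bvals, bvecs)


def write_bvals_bvecs(
    protocol: DiffusionProtocol, bvals_path: str | Path, bvecs_path: str | Path
) -> None:
    np.savetxt(bvals_path, protocol.bvals[None, :], fmt="%.6g")
    np.savetxt(bvecs_path, protocol.bvecs.T, fmt="%.9g")


def save_nifti(
    path: str | Path, data: np.ndarray, voxel_size: float = 2.0
) -> None:
    """Save an image array as NIfTI-1 (RAS, y = phase-encode).

    Complex data are stored as two stacked real volumes (real, imaginary)
    along a trailing axis.
    """
    if np.iscomplexobj(data):
        data = np.stack([data.real, data.imag], axis=-1)
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    img.header.set_qform(affine, code=1)
    img.header.set_sform(affine, code=1)
    nib.save(img, str(path))
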