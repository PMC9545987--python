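"""SENSE unfolding of uniformly undersampled multi-coil data.

The aliased coil images are the (scaled) zero-filled inverse FFT of the
undersampled k-space, truncated to the reduced FOV.  For stride ``s`` and
acquired-line offset ``off`` the exact folding model is

    a_k(x, j) = sum_r  u^r / sqrt(s) * C_k(x, j + r*delta) * rho(x, j + r*delta)

with ``delta = ny/s`` and the unit-modulus constant ``u`` from
:func:`spectremri.fourier.alias_weight`.  Unfolding solves this per-voxel
least-squares system (unweighted — inputs are assumed prewhitened so channel
noise is i.i.d. unit variance); the geometry factor at folded position j is
``g_j = sqrt([ (E^H E)^-1 ]_jj * [E^H E]_jj)``.

The sqrt(s) scaling is chosen so that the noise variance per aliased-image
voxel equals the k-space channel covariance, which makes the replica noise
law std = g * sqrt(R) * sigma / rss(C) hold exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .fourier import alias_weight, ifft2c
from .simulate import MultiCoilKSpace

__all__ = ["AliasedCoilImages", "ReconSeries", "ifft_to_aliased", "sense_unfold", "magnitude"]

log = logging.getLogger(__name__)

#: voxels whose unfolding system has a condition number above this are zeroed
COND_LIMIT = 1e8


@dataclass
class AliasedCoilImages:
    """Reduced-FOV complex coil images ``[coil, x, y_reduced, z, volume]``
    together with the sampling geometry needed to unfold them."""

    data: np.ndarray
    R: int  # undersampling stride relative to the full ky grid
    offset: int  # first acquired ky line
    ny_full: int

    @property
    def n_coils(self) -> int:
        return self.data.shape[0]


@dataclass
class ReconSeries:
    """Unfolded complex image series with its g-factor map.

    ``gfactor`` is NaN where no coil has sensitivity (background) and >= 1
    wherever defined.  ``flagged`` counts voxels zeroed because their
    unfolding system was ill-conditioned.
    """

    data: np.ndarray  # complex [x, y, z, volume]
    gfactor: np.ndarray  # [x, y, z]
    tag: str = ""
    flagged: int = 0
    phase_maps: np.ndarray | None = None  # PEC-SENSE diagnostic
    extras: dict = field(default_factory=dict)


def ifft_to_aliased(kspace: MultiCoilKSpace) -> AliasedCoilImages:
    """Transform undersampled k-space to reduced-FOV aliased coil images.

    Orthonormal centered 2D inverse FFT of the zero-filled k-space, scaled
    by sqrt(R) and truncated to the first ny/R block (the discarded blocks
    repeat it up to a global phase).
    """
    kspace.validate()
    ny = kspace.data.shape[2]
    r = kspace.R
    img = ifft2c(kspace.data, axes=(1, 2)) * np.sqrt(r)
    return AliasedCoilImages(
        data=np.ascontiguousarray(img[:, :, : ny // r]),
        R=r,
        offset=kspace.offset,
        ny_full=ny,
    )


def aliased_to_kspace(aliased: AliasedCoilImages, template: MultiCoilKSpace) -> MultiCoilKSpace:
    """Inverse of :func:`ifft_to_aliased`: rebuild undersampled k-space from
    (possibly processed, e.g. channel-denoised) aliased coil images.

    The discarded FOV blocks repeat the stored one up to the known global
    phase u^-r, so the full zero-filled image — and hence the acquired
    k-space lines — is recovered exactly.  ``template`` supplies the mask,
    parity labels and grid.
    """
    from .fourier import fft2c

    ny = aliased.ny_full
    s = aliased.R
    delta = ny // s
    u = alias_weight(s, aliased.offset, ny)
    nc, nx, _, nz, nv = aliased.data.shape
    full = np.empty((nc, nx, ny, nz, nv), dtype=complex)
    for r in range(s):
        full[:, :, r * delta : (r + 1) * delta] = aliased.data * (u ** -r / np.sqrt(s))
    k = fft2c(full, axes=(1, 2))
    k[:, :, ~template.mask] = 0.0
    return MultiCoilKSpace(data=k, mask=template.mask.copy(), parity=template.parity.copy(), R=template.R)


def _fold_positions(ny: int, stride: int) -> np.ndarray:
    """Full-FOV y indices folded onto each reduced row: [y_reduced, stride]."""
    delta = ny // stride
    return np.arange(delta)[:, None] + delta * np.arange(stride)[None, :]


def _solve_fold_systems(
    e: np.ndarray, d: np.ndarray, cond_limit: float = COND_LIMIT
) -> tuple[np.ndarray, np.ndarray, int]:
    """Solve batched per-voxel least-squares systems.

    ``e`` is [..., rows, s] encoding matrices, ``d`` [..., rows, vol] data.
    Background fold positions (all-zero column) are decoupled and set to 0.
    Returns (rho [..., s, vol], gfactor [..., s] with NaN background,
    flagged-voxel count).
    """
    ehe = e.conj().swapaxes(-1, -2) @ e
    rhs = e.conj().swapaxes(-1, -2) @ d
    s = e.shape[-1]
    colnorm = np.linalg.norm(e, axis=-2)
    bg = colnorm <= 1e-12 * max(colnorm.max(), 1e-300)
    if bg.any():
        # zero columns: decouple by putting 1 on the diagonal (solution 0)
        idx = np.nonzero(bg)
        diag = idx[:-1] + (idx[-1], idx[-1])
        ehe[diag] = 1.0
        rhs[bg] = 0.0
    evs = np.linalg.eigvalsh(ehe)
    cond = evs[..., -1] / np.maximum(evs[..., 0], 1e-300)
    ill = cond > cond_limit
    if ill.any():
        ehe = ehe.copy()
        ehe[ill] = np.eye(s)
        rhs[ill] = 0.0
        log.warning("%d unfolding systems ill-conditioned; voxels zeroed", int(ill.sum()))
    rho = np.linalg.solve(ehe, rhs)
    inv_diag = np.diagonal(np.linalg.inv(ehe), axis1=-2, axis2=-1)
    g = np.sqrt(np.abs(inv_diag.real * np.diagonal(ehe, axis1=-2, axis2=-1).real))
    g[bg] = np.nan
    if ill.any():
        g[ill] = np.nan
        rho[ill] = 0.0
    flagged = int(ill.sum()) * s
    return rho, g, flagged


def sense_unfold(
    aliased: AliasedCoilImages,
    sensitivities: np.ndarray,
    R: int | None = None,
    tag: str = "sense",
    cond_limit: float = COND_LIMIT,
) -> ReconSeries:
    """Unfold aliased coil images with (prewhitened) sensitivity maps.

    ``sensitivities`` is ``[coil, x, y_full, z]``; ``R`` defaults to the
    stride carried by ``aliased``.
    """
    s = R if R is not None else aliased.R
    if s != aliased.R:
        raise ValueError("requested R disagrees with the aliased-image geometry")
    nc, nx, nred, nz, nv = aliased.data.shape
    ny = aliased.ny_full
    if sensitivities.shape != (nc, nx, ny, nz):
        raise ValueError(
            f"sensitivity shape {sensitivities.shape} does not match "
            f"[{nc}, {nx}, {ny}, {nz}]"
        )
    u = alias_weight(s, aliased.offset, ny)
    folds = _fold_positions(ny, s)  # [nred, s]
    weights = u ** np.arange(s) / np.sqrt(s)
    # E: [x, nred, z, coil, s]
    e = sensitivities[:, :, folds, :].transpose(1, 2, 4, 0, 3) * weights
    d = aliased.data.transpose(1, 2, 3, 0, 4)  # [x, nred, z, coil, vol]
    rho, g, flagged = _solve_fold_systems(e, d, cond_limit)

    out = np.zeros((nx, ny, nz, nv), dtype=complex)
    gmap = np.full((nx, ny, nz), np.nan)
    for r in range(s):
        out[:, folds[:, r], :, :] = rho[:, :, :, r, :].transpose(0, 1, 2, 3)
        gmap[:, folds[:, r], :] = g[:, :, :, r]
    return ReconSeries(data=out, gfactor=gmap, tag=tag, flagged=flagged)


def magnitude(recon: ReconSeries | np.ndarray) -> np.ndarray:
    """Voxelwise modulus of a reconstruction (phase discarded)."""
    data = recon.data if isinstance(recon, ReconSeries) else recon
    return np.abs(data)
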