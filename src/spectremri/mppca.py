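"""Marcenko-Pastur PCA denoising of image series.

A sliding 3D kernel extracts, at each position, the Casorati matrix X
(kernel voxels x volumes).  The eigenvalues of its Gram matrix are compared
against the Marcenko-Pastur law for pure-noise matrices: the smallest p is
found such that the remaining eigenvalues are MP-consistent, which
simultaneously yields the local noise level sigma^2 (mean of the noise
eigenvalues) and the number of signal components to retain.  The center
voxel's row of the rank-p reconstruction is written back.

Eigen-analysis operates on the complex Casorati matrix directly (no
real/imaginary stacking) and without mean-centering; sigma^2 is the total
per-element variance (real + imaginary for complex data).  When the kernel
volume is smaller than the number of volumes the analysis transposes X so
the MP fit always uses the smaller dimension as the eigenvalue count.  At
array edges the kernel is shifted to stay in bounds and the edge voxel
keeps its own row of the shifted-kernel reconstruction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["DenoiseResult", "mp_threshold", "denoise_series", "denoise_channels"]

#: Width of the MP eigenvalue bulk used by the consistency test: for a pure
#: noise matrix the spread of the eigenvalues of (1/M) X^H X approaches
#: 4*sqrt(gamma)*sigma^2 with gamma = N/M (the edge-to-edge width of the
#: Marcenko-Pastur distribution), following the reference formulation of
#: the estimator.
MP_BULK_FACTOR = 4.0


@dataclass
class DenoiseResult:
    denoised: np.ndarray
    sigma_map: np.ndarray  # per-voxel noise sigma (total per-element std)
    rank_map: np.ndarray  # per-voxel retained signal components


def _mp_threshold_batch(evals: np.ndarray, big_dim: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized MP consistency scan.

    ``evals`` is [batch, Q] ascending eigenvalues of the (1/big_dim)-scaled
    Gram matrix, Q being the smaller Casorati dimension.  Returns per-batch
    (sigma^2, p) where p is the smallest signal count whose remaining Q - p
    eigenvalues fit under the MP bulk.
    """
    evals = np.maximum(evals, 0.0)  # eigh can return tiny negatives
    # numerically-zero eigenvalues of exactly low-rank data are treated as zero
    evals = np.where(evals < 1e-12 * evals[:, -1:], 0.0, evals)
    batch, q = evals.shape
    n_noise = q - np.arange(q)  # noise-set size for p = 0 .. Q-1
    means = np.cumsum(evals, axis=1)[:, ::-1] / n_noise  # [batch, Q]
    spread = evals[:, ::-1] - evals[:, :1]  # lambda_{Q-p} - lambda_1
    gamma = n_noise / big_dim
    ok = spread <= MP_BULK_FACTOR * np.sqrt(gamma) * means
    p = np.argmax(ok, axis=1)  # p = Q-1 (single noise eigenvalue) always passes
    sigma2 = means[np.arange(batch), p]
    return sigma2, p


def mp_threshold(eigenvalues: Sequence[float], m: int) -> tuple[float, int]:
    """Noise level and signal count from Gram eigenvalues.

    Parameters
    ----------
    eigenvalues:
        Ascending eigenvalues of ``(1/m) X^H X`` for a Casorati matrix X
        with ``m`` rows.
    m:
        Number of rows of X (the larger Casorati dimension).

    Returns
    -------
    (sigma2, p_signal):
        Estimated noise variance (total per-element) and the number of
        signal components.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.size == 0:
        raise ValueError("empty eigenvalue list")
    if np.any(np.diff(ev) < -1e-12 * max(ev.max(), 1.0)):
        raise ValueError("eigenvalues must be sorted ascending")
    sigma2, p = _mp_threshold_batch(ev[None, :], m)
    return float(sigma2[0]), int(p[0])


def _clip_kernel(kernel: Sequence[int], shape: Sequence[int]) -> tuple[int, ...]:
    out = []
    for k, n in zip(kernel, shape):
        if k < 1 or k % 2 == 0:
            raise ValueError("kernel must be odd-sized in every dimension")
        if k > n:
            k = n if n % 2 else n - 1
            k = max(k, 1)
        out.append(k)
    if tuple(out) != tuple(kernel):
        warnings.warn(
            f"kernel {tuple(kernel)} larger than the array; shrunk to {tuple(out)}",
            stacklevel=3,
        )
    return tuple(out)


def denoise_series(
    series: np.ndarray, kernel: Sequence[int] = (5, 5, 5)
) -> DenoiseResult:
    """MPPCA-denoise a (complex or real) image series ``[x, y, z, volume]``."""
    series = np.asarray(series)
    if series.ndim != 4:
        raise ValueError("series must be [x, y, z, volume]")
    nx, ny, nz, nv = series.shape
    if nv < 2:
        raise ValueError("need at least 2 volumes to denoise")
    kx, ky, kz = _clip_kernel(kernel, (nx, ny, nz))
    m = kx * ky * kz
    is_complex = np.iscomplexobj(series)
    out = np.empty_like(series, dtype=complex if is_complex else float)
    sigma_map = np.empty((nx, ny, nz))
    rank_map = np.empty((nx, ny, nz), dtype=np.int32)

    # window start of the (possibly edge-shifted) kernel for every voxel
    sx = np.clip(np.arange(nx) - kx // 2, 0, nx - kx)
    sy = np.clip(np.arange(ny) - ky // 2, 0, ny - ky)
    sz = np.clip(np.arange(nz) - kz // 2, 0, nz - kz)
    wy, wz = ny - ky + 1, nz - kz + 1

    view = np.lib.stride_tricks.sliding_window_view(series, (kx, ky, kz), axis=(0, 1, 2))
    # view: [wx, wy, wz, nv, kx, ky, kz]

    row_z = np.arange(nz) - sz

    # chunk along the x window axis to bound memory
    step = max(1, int(2**24 / max(wy * wz * m * nv, 1)))
    for x0 in range(0, nx - kx + 1, step):
        x1 = min(x0 + step, nx - kx + 1)
        ncw = (x1 - x0) * wy * wz
        xr = view[x0:x1].reshape(ncw, nv, m)  # Casorati transpose per window
        if nv <= m:
            g = xr.conj() @ xr.transpose(0, 2, 1) / m  # (1/M) X^H X
            evals, v = np.linalg.eigh(g)
            sigma2, p = _mp_threshold_batch(evals, m)
            keep = np.arange(nv)[None, :] >= (nv - p)[:, None]
            vm = v * keep[:, None, :]
            proj = vm @ vm.conj().transpose(0, 2, 1)  # [w, nv, nv]
        else:
            g = xr.transpose(0, 2, 1) @ xr.conj() / nv  # (1/N) X X^H
            evals, u = np.linalg.eigh(g)
            sigma2, p = _mp_threshold_batch(evals, nv)
            keep = np.arange(m)[None, :] >= (m - p)[:, None]
            um = u * keep[:, None, :]
            proj = um @ um.conj().transpose(0, 2, 1)  # [w, m, m]

        # voxels served by windows in this chunk
        xi = np.flatnonzero((sx >= x0) & (sx < x1))
        wid = ((sx[xi, None, None] - x0) * wy + sy[None, :, None]) * wz + sz[None, None, :]
        # row index of the voxel inside its window: ((dx*ky) + dy)*kz + dz
        dx = (np.arange(nx)[xi] - sx[xi])[:, None, None]
        dy = (np.arange(ny) - sy)[None, :, None]
        dz = row_z[None, None, :]
        row = (dx * ky + dy) * kz + dz
        wl = wid.ravel()
        rl = row.ravel()
        if nv <= m:
            vals = np.einsum("sn,snm->sm", xr[wl, :, rl], proj[wl])
        else:
            vals = np.einsum("sm,snm->sn", proj[wl, rl, :], xr[wl])
        shape3 = (xi.size, ny, nz)
        out[xi] = vals.reshape(shape3 + (nv,)) if is_complex else vals.real.reshape(shape3 + (nv,))
        sigma_map[xi] = np.sqrt(sigma2[wl]).reshape(shape3)
        rank_map[xi] = p[wl].reshape(shape3).astype(np.int32)

    return DenoiseResult(denoised=out, sigma_map=sigma_map, rank_map=rank_map)


def denoise_channels(
    channel_series: np.ndarray, kernel: Sequence[int] = (5, 5, 5)
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Denoise each coil of ``[coil, x, y, z, volume]`` data independently.

    Returns (denoised channels, per-coil sigma maps, per-coil rank maps).
    """
    channel_series = np.asarray(channel_series)
    if channel_series.ndim != 5:
        raise ValueError("channel series must be [coil, x, y, z, volume]")
    outs, sigmas, ranks = [], [], []
    for c in range(channel_series.shape[0]):
        res = denoise_series(channel_series[c], kernel)
        outs.append(res.denoised)
        sigmas.append(res.sigma_map)
        ranks.append(res.rank_map)
    return np.stack(outs), np.stack(sigmas), np.stack(ranks)
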