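"""Coil noise covariance estimation and prewhitening.

The coil covariance Psi is estimated from noise-only samples and its inverse
lower Cholesky factor D = L^-1 (Psi = L L^H) decorrelates channel data and
sensitivities: Sw = D S, Cw = D C.  After whitening, channel noise is i.i.d.
with unit (total complex) variance, so downstream SENSE unfolding can use
unweighted least squares.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.linalg

__all__ = [
    "estimate_noise_covariance",
    "decorrelation_matrix",
    "apply_prewhitening",
]


def estimate_noise_covariance(noise_samples: np.ndarray) -> np.ndarray:
    """Sample covariance Psi = (1/N) sum_n x_n x_n^H of noise-only coil
    vectors (``noise_samples`` is [coil, samples]; mean assumed zero)."""
    x = np.asarray(noise_samples)
    if x.ndim != 2:
        raise ValueError("noise samples must be a [coil x samples] matrix")
    nc, n = x.shape
    if n < 2 * nc:
        raise ValueError(f"need at least {2 * nc} noise samples, got {n}")
    psi = (x @ x.conj().T) / n
    psi = 0.5 * (psi + psi.conj().T)  # Hermitian by construction, enforce exactly
    ev = np.linalg.eigvalsh(psi)
    if ev.min() <= 1e-12 * ev.max():
        raise ValueError(
            "noise covariance is (near) rank-deficient; enlarge the noise-only "
            "region or check for duplicated channels"
        )
    return psi


def decorrelation_matrix(psi: np.ndarray) -> np.ndarray:
    """Inverse lower Cholesky factor of Psi; satisfies D Psi D^H = I."""
    psi = np.asarray(psi)
    if not np.allclose(psi, psi.conj().T):
        raise ValueError("covariance must be Hermitian")
    try:
        L = np.linalg.cholesky(psi)
    except np.linalg.LinAlgError:
        # near-singular: tiny Tikhonov jitter, retried once
        jitter = 1e-12 * np.real(np.trace(psi))
        if jitter <= 0:
            raise ValueError("covariance is not positive-definite") from None
        warnings.warn(
            "covariance is near-singular; adding 1e-12*trace jitter before Cholesky",
            stacklevel=2,
        )
        try:
            L = np.linalg.cholesky(psi + jitter * np.eye(psi.shape[0]))
        except np.linalg.LinAlgError:
            raise ValueError("covariance is not positive-definite") from None
    return scipy.linalg.solve_triangular(L, np.eye(L.shape[0]), lower=True)


def apply_prewhitening(
    channel_data: np.ndarray, sensitivities: np.ndarray, D: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Left-multiply the coil vector at every sample by D (coil axis first):
    Sw = D S and Cw = D C.  Shapes are unchanged."""
    D = np.asarray(D)
    nc = D.shape[0]
    for name, arr in (("channel data", channel_data), ("sensitivities", sensitivities)):
        if arr.shape[0] != nc:
            raise ValueError(
                f"{name} coil axis has size {arr.shape[0]}, expected {nc} "
                f"(axis 0 must be the coil axis)"
            )
    Sw = np.einsum("ij,j...->i...", D, channel_data)
    Cw = np.einsum("ij,j...->i...", D, sensitivities)
    return Sw, Cw
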