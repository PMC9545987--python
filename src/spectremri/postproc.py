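"""Post-reconstruction denoising strategies.

Two alternatives to channel-wise denoising are provided for comparison:

* magnitude-domain MPPCA followed by a method-of-moments correction of the
  Rician bias, using the sigma map MPPCA itself estimates;
* complex-domain MPPCA after removal of the smooth background phase (a
  low-pass phase-flattening step standing in for decorrelated phase
  filtering, so slowly varying phase structure does not masquerade as extra
  signal components).

Both return magnitude data ready for diffusion-model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .mppca import denoise_series
from .sense import ReconSeries

__all__ = [
    "RicianCorrectedSeries",
    "method_of_moments",
    "remove_background_phase",
    "denoise_after_recon",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class RicianCorrectedSeries:
    data: np.ndarray  # nonnegative magnitude series
    clamp_mask: np.ndarray  # where M^2 < 2 sigma^2 forced the estimate to 0


def method_of_moments(
    magnitude_series: np.ndarray, sigma_map: np.ndarray
) -> RicianCorrectedSeries:
    """Second-moment Rician bias correction A = sqrt(max(M^2 - 2 sigma^2, 0)).

    ``sigma_map`` is the per-component Gaussian noise sigma (broadcastable to
    the series; a 3D map applies to every volume).  Uses E[M^2] = A^2 +
    2 sigma^2 for Rician magnitudes.
    """
    m = np.asarray(magnitude_series)
    sigma = np.asarray(sigma_map, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("sigma must be nonnegative")
    if sigma.ndim == m.ndim - 1:
        sigma = sigma[..., None]
    sq = m**2 - 2.0 * sigma**2
    clamp = sq < 0
    return RicianCorrectedSeries(data=np.sqrt(np.clip(sq, 0, None)), clamp_mask=clamp)


def remove_background_phase(
    complex_series: np.ndarray, fwhm: float = 8.0
) -> np.ndarray:
    """Conjugate-multiply out a smooth background phase estimate.

    The background phase of each volume is the argument of a 3D
    Gaussian-filtered copy (FWHM in voxels); the output keeps the input
    magnitude exactly and retains only phase structure sharper than the
    filter scale.
    """
    x = np.asarray(complex_series, dtype=complex)
    sigma = fwhm * _FWHM_TO_SIGMA
    sigmas = (sigma, sigma, sigma, 0)
    sm = gaussian_filter(x.real, sigmas) + 1j * gaussian_filter(x.imag, sigmas)
    phase = np.angle(sm)
    return np.abs(x) * np.exp(1j * (np.angle(x) - phase))


def denoise_after_recon(
    recon: ReconSeries | np.ndarray,
    mode: str,
    kernel: Sequence[int] = (5, 5, 5),
    bg_phase_fwhm: float = 8.0,
) -> np.ndarray:
    """Denoise a reconstructed complex series, returning magnitude data.

    ``mode='magnitude'``: MPPCA on the modulus, then method-of-moments with
    the MPPCA sigma map.  ``mode='complex'``: background-phase removal, then
    MPPCA on the complex data, then modulus.
    """
    data = recon.data if isinstance(recon, ReconSeries) else np.asarray(recon)
    if mode == "magnitude":
        res = denoise_series(np.abs(data), kernel)
        # real-valued input: the MPPCA sigma is the per-component sigma
        return method_of_moments(res.denoised, res.sigma_map).data
    if mode == "complex":
        flat = remove_background_phase(data, fwhm=bg_phase_fwhm)
        res = denoise_series(flat, kernel)
        return np.abs(res.denoised)
    raise ValueError(f"unknown denoising mode {mode!r} (use 'magnitude' or 'complex')")
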