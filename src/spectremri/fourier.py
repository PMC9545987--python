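"""Centered orthonormal FFT helpers.

One convention is used everywhere in the package: the DC sample sits at
index ``n // 2`` of each transformed axis (even grids), and transforms are
orthonormal (``norm="ortho"``), so white noise keeps its variance between
k-space and image space.  ``ky`` is always the phase-encode axis.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fftc", "ifftc", "fft2c", "ifft2c", "alias_weight"]


def fftc(x: np.ndarray, axes) -> np.ndarray:
    """Centered orthonormal forward FFT over ``axes``."""
    axes = tuple(np.atleast_1d(axes))
    return np.fft.fftshift(
        np.fft.fftn(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"), axes=axes
    )


def ifftc(x: np.ndarray, axes) -> np.ndarray:
    """Centered orthonormal inverse FFT over ``axes``."""
    axes = tuple(np.atleast_1d(axes))
    return np.fft.fftshift(
        np.fft.ifftn(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"), axes=axes
    )


def fft2c(x: np.ndarray, axes=(1, 2)) -> np.ndarray:
    return fftc(x, axes)


def ifft2c(x: np.ndarray, axes=(1, 2)) -> np.ndarray:
    return ifftc(x, axes)


def alias_weight(stride: int, offset: int, n: int) -> complex:
    """Replica weight generator for uniform undersampling.

    With the centered orthonormal convention, the zero-filled inverse FFT of
    k-space sampled at indices ``offset + m*stride`` on an ``n``-point grid is

        I_zf[y] = (1/stride) * sum_r u**r * I[(y + r*delta) mod n],

    where ``delta = n // stride`` and ``u`` is the unit-modulus constant
    returned here.  This is the exact folding model SENSE unfolding inverts.
    """
    if n % stride:
        raise ValueError(f"grid size {n} not divisible by undersampling stride {stride}")
    delta = n // stride
    return (-1.0) ** delta * np.exp(-2j * np.pi * offset / stride)
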