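"""Reconstruction pipeline dispatch.

Eight pipelines combine two reconstructions (SENSE, PEC-SENSE) with four
denoising strategies (none; magnitude-domain after image formation;
complex-domain after image formation; channel-wise before image formation):

======== =============================================================
name      stages
======== =============================================================
sense       prewhiten -> SENSE
sense_m     prewhiten -> SENSE -> magnitude MPPCA + method of moments
sense_c     prewhiten -> SENSE -> phase removal + complex MPPCA
sense_ch    prewhiten -> channel MPPCA -> SENSE
pecsense    prewhiten -> PEC-SENSE
pecsense_m  prewhiten -> PEC-SENSE -> magnitude MPPCA + MoM
pecsense_c  prewhiten -> PEC-SENSE -> phase removal + complex MPPCA
spectre     prewhiten -> channel MPPCA -> PEC-SENSE
======== =============================================================

The coil covariance is estimated from the noise-only top rows of the
aliased coil images; channel data and sensitivities are decorrelated before
any further processing, so all unfolding uses unweighted least squares.
"""

from __future__ import annotations

import logging
import time
from typing import Mapping

import numpy as np

from .mppca import denoise_channels
from .pecsense import pec_sense_recon
from .postproc import denoise_after_recon
from .prewhiten import apply_prewhitening, decorrelation_matrix, estimate_noise_covariance
from .sense import AliasedCoilImages, aliased_to_kspace, ifft_to_aliased, magnitude, sense_unfold
from .simulate import sample_noise_region

__all__ = ["PIPELINES", "run_pipeline"]

log = logging.getLogger(__name__)

PIPELINES = (
    "sense",
    "sense_m",
    "sense_c",
    "sense_ch",
    "pecsense",
    "pecsense_m",
    "pecsense_c",
    "spectre",
)


def _prewhitened(raw, cfg: Mapping, cache: dict):
    """Whitened k-space + sensitivities (computed once per dataset)."""
    if "ks_w" not in cache:
        t0 = time.perf_counter()
        aliased = ifft_to_aliased(raw.kspace)
        noise_rows = raw.truth.noise_rows if raw.truth is not None else cfg.get("noise_rows", 8)
        samples = sample_noise_region(aliased.data, n_rows=noise_rows)
        psi = estimate_noise_covariance(samples)
        d = decorrelation_matrix(psi)
        sw, cw = apply_prewhitening(raw.kspace.data, raw.sens, d)
        ks_w = type(raw.kspace)(
            data=sw, mask=raw.kspace.mask.copy(), parity=raw.kspace.parity.copy(), R=raw.kspace.R
        )
        cache.update(psi=psi, D=d, ks_w=ks_w, sens_w=cw)
        log.info("prewhitening: %.2fs", time.perf_counter() - t0)
    return cache["ks_w"], cache["sens_w"]


def _channel_denoised(raw, cfg: Mapping, cache: dict):
    """Whitened k-space after channel-wise complex MPPCA (cached)."""
    if "ks_w_denoised" not in cache:
        ks_w, _ = _prewhitened(raw, cfg, cache)
        t0 = time.perf_counter()
        aliased = ifft_to_aliased(ks_w)
        den, sig, rank = denoise_channels(aliased.data, cfg.get("kernel", (5, 5, 5)))
        al_d = AliasedCoilImages(
            data=den, R=aliased.R, offset=aliased.offset, ny_full=aliased.ny_full
        )
        cache["ks_w_denoised"] = aliased_to_kspace(al_d, ks_w)
        cache["channel_sigma"] = sig
        cache["channel_rank"] = rank
        log.info("channel MPPCA (%d coils): %.2fs", den.shape[0], time.perf_counter() - t0)
    return cache["ks_w_denoised"], cache["sens_w"]


def run_pipeline(raw, name: str, config: Mapping | None = None, _cache: dict | None = None) -> dict:
    """Run one named pipeline on a RawDataContainer.

    Returns a dict with the complex ``recon`` (ReconSeries, g-factor map
    attached), the ``magnitude`` series ready for model fitting, and
    diagnostics (coil covariance, channel sigma maps where applicable).
    Pass a shared ``_cache`` dict to reuse the prewhitening and channel
    denoising across pipelines run on the same dataset.
    """
    if name not in PIPELINES:
        raise ValueError(f"unknown pipeline {name!r}; valid names: {sorted(PIPELINES)}")
    cfg = dict(config or {})
    cache = _cache if _cache is not None else {}
    kernel = cfg.get("kernel", (5, 5, 5))
    fwhm = cfg.get("phase_fwhm", 5.0)
    cond = cfg.get("cond_limit", 1e8)
    noise_rows = raw.truth.noise_rows if raw.truth is not None else cfg.get("noise_rows", 8)

    t0 = time.perf_counter()
    if name in ("sense_ch", "spectre"):
        ks, sens = _channel_denoised(raw, cfg, cache)
    else:
        ks, sens = _prewhitened(raw, cfg, cache)

    if name in ("sense", "sense_m", "sense_c", "sense_ch"):
        recon = sense_unfold(ifft_to_aliased(ks), sens, tag=name, cond_limit=cond)
    else:
        recon = pec_sense_recon(
            ks, sens, fwhm=fwhm, noise_rows=noise_rows, tag=name, cond_limit=cond
        )

    if name.endswith("_m"):
        mag = denoise_after_recon(recon, "magnitude", kernel)
    elif name.endswith("_c"):
        mag = denoise_after_recon(
            recon, "complex", kernel, bg_phase_fwhm=cfg.get("bg_phase_fwhm", 8.0)
        )
    else:
        mag = magnitude(recon)
    log.info(
        "pipeline %s: recon %s -> magnitude %s in %.2fs",
        name,
        recon.data.shape,
        mag.shape,
        time.perf_counter() - t0,
    )
    return {
        "recon": recon,
        "magnitude": mag,
        "psi": cache.get("psi"),
        "channel_sigma": cache.get("channel_sigma") if name in ("sense_ch", "spectre") else None,
    }
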