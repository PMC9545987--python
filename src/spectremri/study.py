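"""Dataset factory: turn a simulation configuration into a raw container.

This is the single place where the study conditions (phantom, coils,
protocol, phase error, noise) are assembled into the HDF5-ready
RawDataContainer consumed by the pipelines and the evaluation module.
"""

from __future__ import annotations

import numpy as np

from .config import SimulationConfig
from .io import RawDataContainer
from .simulate import (
    PhaseErrorSpec,
    build_phantom,
    default_noise_covariance,
    default_phantom,
    default_protocol,
    encode_epi,
    simulate_coil_sensitivities,
    simulate_dwi_series,
)

__all__ = ["make_dataset"]


def make_dataset(
    config: SimulationConfig | None = None,
    seed: int | None = None,
    phantom=None,
    protocol=None,
) -> RawDataContainer:
    """Simulate a complete ghosted, noisy, undersampled DW-EPI acquisition.

    ``seed`` overrides the config seed; independent sub-seeds are derived
    for the coil geometry and the noise stream.
    """
    cfg = config or SimulationConfig()
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    coil_seed, noise_seed = rng.integers(0, 2**31 - 1, size=2)

    ph = phantom if phantom is not None else default_phantom(cfg.grid)
    prot = protocol if protocol is not None else default_protocol(cfg.shells, cfg.n_dirs, cfg.n_b0)
    images = simulate_dwi_series(ph, prot)
    coils = simulate_coil_sensitivities(cfg.n_coils, cfg.grid, seed=int(coil_seed))
    pe = cfg.phase_error
    spec = PhaseErrorSpec(
        constant=pe.constant,
        linear_x=pe.linear_x,
        linear_y=pe.linear_y,
        quad_x=pe.quad_x,
        quad_y=pe.quad_y,
        cross=pe.cross,
        jitter=pe.jitter,
    )
    psi = (
        default_noise_covariance(cfg.n_coils, cfg.noise_sigma, cfg.coil_rho)
        if cfg.noise_sigma > 0
        else None
    )
    ks, truth, noise_samples = encode_epi(
        images,
        coils,
        spec,
        cfg.R,
        psi,
        seed=int(noise_seed),
        ground_truth={"md": ph.md_map(), "fa": ph.fa_map(), "object_mask": ph.support},
        noise_rows=cfg.noise_rows,
    )
    return RawDataContainer(
        kspace=ks, sens=coils, noise_samples=noise_samples, protocol=prot, truth=truth, seed=seed
    )
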