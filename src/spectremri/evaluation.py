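"""Quantitative benchmarks: replica SNR, accuracy, precision, ghost level.

Accuracy is the mean voxel-wise error relative to the ground-truth value
(sign convention: positive = underestimation); precision is the coefficient
of variation across voxels (population SD).  SNR uses the multiple replicas
of the b=0 data: per-voxel mean over replicas divided by SD over replicas,
averaged over an ROI.  The ghost-to-signal ratio quantifies the residual
half-FOV Nyquist ghost against the known object mask.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion

__all__ = [
    "snr_from_replicas",
    "accuracy_mean_relative_error",
    "cov_across_voxels",
    "ghost_to_signal_ratio",
    "compare_pipelines",
]

log = logging.getLogger(__name__)


def snr_from_replicas(b0_replicas: np.ndarray, roi_mask: np.ndarray) -> float:
    """Mean over the ROI of (per-voxel replica mean / replica SD).

    ``b0_replicas`` is ``[x, y, z, replica]`` magnitude data with >= 3
    replicas.  Zero-SD voxels are excluded (their count logged); if none
    remain the data carry no noise and an error is raised.
    """
    reps = np.asarray(b0_replicas, dtype=float)
    if reps.shape[-1] < 3:
        raise ValueError("need at least 3 b=0 replicas")
    mean = reps.mean(axis=-1)
    sd = reps.std(axis=-1)
    valid = roi_mask & (sd > 0)
    n_excluded = int(np.sum(roi_mask) - np.sum(valid))
    if n_excluded:
        log.info("%d zero-SD voxels excluded from the SNR ROI", n_excluded)
    if not valid.any():
        raise ValueError("no valid voxels: replica SD is zero everywhere in the ROI")
    return float(np.mean(mean[valid] / sd[valid]))


def accuracy_mean_relative_error(
    value_map: np.ndarray, truth_value: float, mask: np.ndarray
) -> tuple[float, float]:
    """Signed and absolute mean relative error (%) over the mask.

    Positive signed error means underestimation: 100 * mean((truth - value)
    / truth).  The absolute variant averages |truth - value| / truth.
    """
    if truth_value <= 0:
        raise ValueError("ground-truth value must be positive")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty evaluation mask")
    err = (truth_value - np.asarray(value_map, dtype=float)[mask]) / truth_value
    return 100.0 * float(err.mean()), 100.0 * float(np.abs(err).mean())


def cov_across_voxels(value_map: np.ndarray, mask: np.ndarray) -> float:
    """Coefficient of variation (%) across masked voxels (population SD)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    vals = np.asarray(value_map, dtype=float)[mask]
    mean = vals.mean()
    if mean == 0:
        raise ValueError("zero mean; CoV undefined")
    return 100.0 * float(vals.std() / mean)


def ghost_to_signal_ratio(magnitude_image: np.ndarray, object_mask: np.ndarray) -> float:
    """Mean magnitude over the half-FOV-shifted ghost region divided by the
    mean over the object.  The ghost mask is the object mask circularly
    shifted by FOV/2 along the phase-encode (y) axis, minus the object."""
    obj = np.asarray(object_mask, dtype=bool)
    ghost = np.roll(obj, obj.shape[1] // 2, axis=1) & ~obj
    if not ghost.any():
        raise ValueError("ghost mask is empty (object fills the FOV along y); use a smaller phantom")
    img = np.asarray(magnitude_image, dtype=float)
    return float(img[ghost].mean() / img[obj].mean())


def compare_pipelines(
    dataset,
    pipeline_list: Sequence[str],
    config: Mapping | None = None,
) -> pd.DataFrame:
    """Run each named pipeline on the same raw dataset and tabulate the
    benchmarks: replica SNR, MD mean/SD (x10^-3 mm^2/s), MD CoV, signed mean
    relative MD error, model NRMSE and ghost-to-signal ratio — one row per
    pipeline.

    ``dataset`` is a RawDataContainer holding a ground-truth bundle.
    """
    from .diffusion import fit_dti_irls, model_nrmse, predict_signal, tensor_metrics
    from .pipelines import PIPELINES, run_pipeline

    unknown = [p for p in pipeline_list if p not in PIPELINES and p != "reference"]
    if unknown:
        raise ValueError(
            f"unknown pipeline(s) {unknown}; valid names: {sorted(PIPELINES)}"
        )
    cfg = dict(config or {})
    truth = dataset.truth
    if truth is None:
        raise ValueError("dataset carries no ground-truth bundle")
    obj = truth.object_mask
    # in-plane erosion (slices are independent EPI excitations; the phantom
    # has no partial volume along z in this simulation)
    roi = binary_erosion(obj, structure=np.ones((3, 3, 1), bool), iterations=2)
    b0 = dataset.protocol.b0_indices
    md_truth = float(np.mean(truth.md[roi]))

    rows = []
    cache: dict = {}
    for name in pipeline_list:
        if name == "reference":
            # ground-truth stand-in for the ghost-free, noiseless reference
            # acquisition: fit the noiseless coil-combined series directly
            mag = np.abs(truth.images)
            snr = np.nan  # no replica noise
        else:
            result = run_pipeline(dataset, name, cfg, _cache=cache)
            mag = result["magnitude"]
            snr = snr_from_replicas(mag[..., b0], roi)
        fit = fit_dti_irls(mag, dataset.protocol, b_max=cfg.get("b_max", 1000.0), mask=obj)
        md, _fa = tensor_metrics(fit)
        signed, _abs_err = accuracy_mean_relative_error(md, md_truth, roi)
        _, nrmse = model_nrmse(mag[..., fit.volumes_used], predict_signal(fit), roi)
        gsr = ghost_to_signal_ratio(mag[..., b0].mean(axis=-1), obj)
        rows.append(
            {
                "pipeline": name,
                "snr": snr,
                "md_mean": 1e3 * float(md[roi].mean()),
                "md_sd": 1e3 * float(md[roi].std()),
                "md_cov_pct": cov_across_voxels(md, roi),
                "md_error_pct": signed,
                "nrmse_pct": nrmse,
                "gsr": gsr,
            }
        )
        log.info("pipeline %s: %s", name, rows[-1])
    report = pd.DataFrame(rows).set_index("pipeline")
    report.attrs["seed"] = getattr(dataset, "seed", None)
    report.attrs["config_hash"] = hash(tuple(sorted((k, str(v)) for k, v in cfg.items())))
    return report
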