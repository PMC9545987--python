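"""Diffusion tensor and kurtosis model fitting.

Log-linear forms are used throughout.  The tensor fit is iteratively
re-weighted least squares (IRLS) with weights equal to the squared current
signal prediction — the correct variance weighting for log-transformed
Gaussian data — restricted to volumes with b <= b_max (default 1000 s/mm^2).
The kurtosis fit is weighted linear least squares on the 22-parameter
expansion

    ln S = ln S0 - b g^T D g + (b^2/6) * sum_ijkl g_i g_j g_k g_l V_ijkl,

where V = MD^2 * W absorbs the mean diffusivity so the model stays linear;
apparent kurtosis along g is K(g) = (sum g g g g V) / (g^T D g)^2 and MK is
its mean over the protocol's diffusion directions.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np

from .simulate import DiffusionProtocol

__all__ = [
    "TensorFitResult",
    "KurtosisFitResult",
    "design_matrix",
    "fit_dti_irls",
    "fit_dki_lls",
    "tensor_metrics",
    "fa_from_eigenvalues",
    "predict_signal",
    "model_nrmse",
]

log = logging.getLogger(__name__)

#: unique diffusion-tensor elements, in design-matrix column order (cols 1-6)
TENSOR_ELEMENTS = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
TENSOR_MULT = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])

#: unique kurtosis-tensor index quadruples, lexicographic, with multiplicities
KURTOSIS_ELEMENTS = list(itertools.combinations_with_replacement(range(3), 4))
KURTOSIS_MULT = np.array(
    [
        math.factorial(4)
        // np.prod([math.factorial(q.count(i)) for i in range(3)])
        for q in KURTOSIS_ELEMENTS
    ],
    dtype=float,
)


@dataclass
class TensorFitResult:
    """Per-voxel [ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz] plus bookkeeping."""

    params: np.ndarray  # [..., 7]
    mask: np.ndarray
    converged: np.ndarray
    iterations: int
    protocol: DiffusionProtocol
    volumes_used: np.ndarray  # indices of volumes entering the fit

    def tensors(self) -> np.ndarray:
        return _assemble_tensor(self.params[..., 1:7])


@dataclass
class KurtosisFitResult:
    params: np.ndarray  # [..., 22]
    mask: np.ndarray
    protocol: DiffusionProtocol

    def tensors(self) -> np.ndarray:
        return _assemble_tensor(self.params[..., 1:7])

    def mk_map(self) -> np.ndarray:
        """Mean apparent kurtosis over the protocol's diffusion directions."""
        dirs = np.unique(
            np.round(self.protocol.bvecs[self.protocol.bvals > 0], 12), axis=0
        )
        d6 = self.params[..., 1:7]
        v15 = self.params[..., 7:22]
        gq = _quartic_weights(dirs)  # [ndir, 15]
        g2 = _quadratic_weights(dirs)  # [ndir, 6]
        adc = d6 @ g2.T  # [..., ndir]
        vapp = v15 @ gq.T
        with np.errstate(divide="ignore", invalid="ignore"):
            k = np.where(adc > 0, vapp / np.maximum(adc, 1e-300) ** 2, 0.0)
        out = k.mean(axis=-1)
        out[~self.mask] = 0.0
        return out


def _assemble_tensor(d6: np.ndarray) -> np.ndarray:
    t = np.zeros(d6.shape[:-1] + (3, 3))
    for col, (i, j) in enumerate(TENSOR_ELEMENTS):
        t[..., i, j] = d6[..., col]
        t[..., j, i] = d6[..., col]
    return t


def _quadratic_weights(g: np.ndarray) -> np.ndarray:
    """Per-direction weights of the 6 unique tensor elements in g^T D g."""
    return np.stack(
        [TENSOR_MULT[c] * g[:, i] * g[:, j] for c, (i, j) in enumerate(TENSOR_ELEMENTS)],
        axis=1,
    )


def _quartic_weights(g: np.ndarray) -> np.ndarray:
    """Per-direction weights of the 15 unique kurtosis elements."""
    cols = []
    for mult, q in zip(KURTOSIS_MULT, KURTOSIS_ELEMENTS):
        w = mult * np.ones(g.shape[0])
        for i in q:
            w = w * g[:, i]
        cols.append(w)
    return np.stack(cols, axis=1)


def design_matrix(protocol: DiffusionProtocol, order: str = "dti") -> np.ndarray:
    """Log-linear design matrix: [volumes x 7] for DTI, [volumes x 22] for DKI.

    Column order: intercept (ln S0); -b-weighted Dxx, Dyy, Dzz, Dxy, Dxz,
    Dyz; then for DKI +(b^2/6)-weighted V elements in lexicographic index
    order (V = MD^2 W).
    """
    b = protocol.bvals
    g = protocol.bvecs
    a = np.column_stack([np.ones_like(b), -b[:, None] * _quadratic_weights(g)])
    if order == "dti":
        return a
    if order != "dki":
        raise ValueError("order must be 'dti' or 'dki'")
    if protocol.shells().size < 2:
        raise ValueError("DKI requires at least 2 nonzero b-value shells")
    return np.column_stack([a, (b[:, None] ** 2 / 6.0) * _quartic_weights(g)])


def _prepare_log_signals(
    series: np.ndarray, vols: np.ndarray, bvals: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Log-transform signals for fitting.

    Nonpositive samples are floored at machine epsilon (times the data
    scale) so the transform stays finite, and flagged for exclusion from
    the fit via zero weights.  Returns (log signals, validity mask)."""
    s = np.asarray(series, dtype=float)[..., vols]
    valid = s > 0
    bad = int(valid.size - valid.sum())
    if bad:
        log.info("%d nonpositive signal samples excluded from the fit", bad)
    eps = np.finfo(float).eps * max(float(np.max(s, initial=0.0)), 1.0)
    return np.log(np.maximum(s, eps)), valid


def _wls_solve(a: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Batched weighted LS: a [nvol, p], y [vox, nvol], w [vox, nvol].

    Columns are equilibrated before the normal-equations solve (the raw
    design mixes scales from 1 to b^2 ~ 1e6) and a tiny relative ridge keeps
    voxels with degenerate valid-sample patterns solvable (their unsupported
    parameters shrink to 0).
    """
    scale = np.linalg.norm(a, axis=0)
    scale[scale == 0] = 1.0
    a_s = a / scale
    aw = w[:, :, None] * a_s[None, :, :]  # [vox, nvol, p]
    ata = np.einsum("vnp,nq->vpq", aw, a_s)
    aty = np.einsum("vnp,vn->vp", aw, y)
    idx = np.arange(a.shape[1])
    diag = ata[:, idx, idx]
    ata[:, idx, idx] += (
        1e-12 * np.abs(diag)
        + 1e-14 * np.abs(diag).max(axis=1, keepdims=True)
        + 1e-300
    )
    return np.linalg.solve(ata, aty[..., None])[..., 0] / scale


def fit_dti_irls(
    series: np.ndarray,
    protocol: DiffusionProtocol,
    b_max: float = 1000.0,
    mask: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> TensorFitResult:
    """IRLS diffusion-tensor fit on volumes with b <= b_max.

    Initialized from the unweighted log-linear fit; iterates with weights
    equal to the squared predicted signal until the relative parameter
    change drops below ``tol`` (or ``max_iter``).
    """
    vols = np.flatnonzero(protocol.bvals <= b_max)
    if vols.size < 7 or not np.any(protocol.bvals[vols] == 0):
        raise ValueError("need at least 7 volumes with b <= b_max including a b=0")
    sub = DiffusionProtocol(protocol.bvals[vols], protocol.bvecs[vols])
    a = design_matrix(sub, "dti")
    shape = np.asarray(series).shape[:-1]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    y_all, valid_all = _prepare_log_signals(series, vols, protocol.bvals)
    y = y_all[mask]  # [vox, nvol]
    valid = valid_all[mask]
    # voxels with too few usable samples cannot support a 7-parameter fit
    fittable = valid.sum(axis=1) >= 7
    valid = valid & fittable[:, None]
    # keep the solve nonsingular for excluded voxels (their params stay 0)
    valid[~fittable] = True
    y = np.where(valid, y, 0.0)

    beta = _wls_solve(a, y, valid.astype(float))
    beta[~fittable] = 0.0
    active = fittable.copy()
    it = 0
    for it in range(1, max_iter + 1):
        # clip the linear predictor: keeps weights finite on divergent voxels
        pred = np.exp(np.clip(beta[active] @ a.T, -60.0, 60.0))
        w = np.maximum(pred, 1e-6 * pred.max(axis=1, keepdims=True)) ** 2
        w = w * valid[active]
        new = _wls_solve(a, y[active], w)
        bad = ~np.all(np.isfinite(new), axis=1)
        new[bad] = beta[active][bad]
        change = np.max(
            np.abs(new - beta[active]) / np.maximum(np.abs(beta[active]), 1e-12), axis=1
        )
        change[bad] = 0.0  # give up on numerically degenerate voxels
        beta[active] = new
        still = change >= tol
        active[np.flatnonzero(active)[~still]] = False
        if not active.any():
            break

    params = np.zeros(shape + (7,))
    params[mask] = beta
    converged = np.zeros(shape, dtype=bool)
    converged[mask] = ~active
    return TensorFitResult(
        params=params,
        mask=mask,
        converged=converged,
        iterations=it,
        protocol=protocol,
        volumes_used=vols,
    )


def fit_dki_lls(
    series: np.ndarray,
    protocol: DiffusionProtocol,
    mask: np.ndarray | None = None,
    n_reweight: int = 2,
) -> KurtosisFitResult:
    """Weighted linear LS kurtosis fit (22 parameters, 2 reweighting passes)."""
    if protocol.n_volumes < 22:
        raise ValueError("DKI requires at least 22 volumes")
    a = design_matrix(protocol, "dki")
    shape = np.asarray(series).shape[:-1]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    y, valid = _prepare_log_signals(series, np.arange(protocol.n_volumes), protocol.bvals)
    y, valid = y[mask], valid[mask]
    fittable = valid.sum(axis=1) >= 22
    valid = valid & fittable[:, None]
    valid[~fittable] = True
    y = np.where(valid, y, 0.0)
    beta = _wls_solve(a, y, valid.astype(float))
    for _ in range(n_reweight):
        pred = np.exp(np.clip(beta @ a.T, -60.0, 60.0))
        w = np.maximum(pred, 1e-6 * pred.max(axis=1, keepdims=True)) ** 2
        beta = _wls_solve(a, y, w * valid)
    beta[~fittable] = 0.0
    params = np.zeros(shape + (22,))
    params[mask] = beta
    return KurtosisFitResult(params=params, mask=mask, protocol=protocol)


def fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """Fractional anisotropy from tensor eigenvalues (last axis)."""
    evals = np.asarray(evals, dtype=float)
    md = evals.mean(axis=-1, keepdims=True)
    num = np.sum((evals - md) ** 2, axis=-1)
    den = np.sum(evals**2, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fa = np.sqrt(1.5 * num / den)
    return np.where(den > 0, fa, 0.0)


def tensor_metrics(fit: TensorFitResult | KurtosisFitResult) -> tuple[np.ndarray, np.ndarray]:
    """MD and FA maps from a tensor (or kurtosis) fit."""
    tensors = fit.tensors()
    finite = np.all(np.isfinite(tensors), axis=(-2, -1))
    if not finite.all():
        log.info("%d voxels with non-finite tensors zeroed", int((~finite).sum()))
        tensors[~finite] = 0.0
    evals = np.linalg.eigvalsh(tensors)
    md = evals.mean(axis=-1)
    fa = fa_from_eigenvalues(evals)
    md[~fit.mask] = 0.0
    fa[~fit.mask] = 0.0
    return md, fa


def predict_signal(fit: TensorFitResult | KurtosisFitResult) -> np.ndarray:
    """Model-predicted signal series on the volumes entering the fit."""
    if isinstance(fit, TensorFitResult):
        sub = DiffusionProtocol(
            fit.protocol.bvals[fit.volumes_used], fit.protocol.bvecs[fit.volumes_used]
        )
        a = design_matrix(sub, "dti")
    else:
        a = design_matrix(fit.protocol, "dki")
    pred = np.exp(np.clip(fit.params @ a.T, -60.0, 60.0))
    pred[~fit.mask] = 0.0
    return pred


def model_nrmse(
    series: np.ndarray, prediction: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-voxel normalized RMS error between data and model prediction (%).

    NRMSE = RMS over volumes of (data - prediction), divided by the mean of
    the data over volumes.  Voxels with nonpositive mean are NaN and excluded
    from the masked mean.
    """
    data = np.asarray(series, dtype=float)
    pred = np.asarray(prediction, dtype=float)
    if data.shape != pred.shape:
        raise ValueError("data and prediction shapes differ")
    rms = np.sqrt(np.mean((data - pred) ** 2, axis=-1))
    mean = data.mean(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        nrmse = np.where(mean > 0, 100.0 * rms / np.where(mean > 0, mean, 1.0), np.nan)
    valid = mask & np.isfinite(nrmse)
    return nrmse, float(np.mean(nrmse[valid]))
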