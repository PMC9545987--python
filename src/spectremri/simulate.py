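"""Synthetic multi-coil DW-EPI generator.

Produces ground-truthed datasets with the statistical and artifact structure
the reconstruction pipelines assume: a piecewise-constant diffusion phantom,
smooth complex coil sensitivities, mono-exponential tensor diffusion
contrast, parity-dependent (odd/even readout line) 2D phase errors causing
Nyquist ghosting, uniform undersampling, and zero-mean correlated complex
Gaussian coil noise with a specified coil covariance.

Conventions
-----------
* image arrays are ``[x, y, z, volume]`` with ``y`` the phase-encode axis;
* coil arrays carry the coil axis first (``[coil, x, y, z]`` sensitivities,
  ``[coil, kx, ky, z, volume]`` k-space);
* "odd" parity is the first acquired ky line and every second acquired line
  after it, and the parity phase error is assigned wholly to odd lines (only
  the odd/even difference is observable);
* noise is generated on the acquired k-space samples, correlated across
  coils through the Cholesky factor of the true covariance, i.i.d. across
  samples, with unit-variance meaning total complex variance 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .fourier import fft2c, ifft2c

__all__ = [
    "PhantomDefinition",
    "DiffusionProtocol",
    "PhaseErrorSpec",
    "MultiCoilKSpace",
    "GroundTruthBundle",
    "build_phantom",
    "default_phantom",
    "simulate_coil_sensitivities",
    "simulate_dwi_series",
    "encode_epi",
    "sample_noise_region",
    "make_directions",
    "default_protocol",
    "default_phase_error",
    "default_noise_covariance",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class PhantomDefinition:
    """Piecewise-constant diffusion phantom: a label map plus per-label
    proton density S0 (arbitrary units) and 3x3 diffusion tensor (mm^2/s).
    Label 0 is background with S0 = 0."""

    label_map: np.ndarray  # int [x, y, z]
    s0: dict[int, float]
    tensors: dict[int, np.ndarray]

    @property
    def support(self) -> np.ndarray:
        return self.label_map > 0

    def s0_map(self) -> np.ndarray:
        out = np.zeros(self.label_map.shape)
        for lab, v in self.s0.items():
            out[self.label_map == lab] = v
        return out

    def _eigs(self, lab: int) -> np.ndarray:
        return np.linalg.eigvalsh(self.tensors[lab])

    def md_map(self) -> np.ndarray:
        out = np.zeros(self.label_map.shape)
        for lab in self.tensors:
            out[self.label_map == lab] = np.trace(self.tensors[lab]) / 3.0
        return out

    def fa_map(self) -> np.ndarray:
        out = np.zeros(self.label_map.shape)
        for lab in self.tensors:
            ev = self._eigs(lab)
            md = ev.mean()
            denom = np.sum(ev**2)
            fa = 0.0 if denom == 0 else float(np.sqrt(1.5 * np.sum((ev - md) ** 2) / denom))
            out[self.label_map == lab] = fa
        return out


@dataclass
class DiffusionProtocol:
    """FSL-style diffusion protocol: b-values (s/mm^2) and unit gradient
    directions, one per volume.  b = 0 volumes may carry a zero vector."""

    bvals: np.ndarray  # (nvol,)
    bvecs: np.ndarray  # (nvol, 3)

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float).reshape(-1, 3)
        if self.bvals.shape[0] != self.bvecs.shape[0]:
            raise ValueError("bvals and bvecs disagree on the number of volumes")
        if np.any(self.bvals < 0):
            raise ValueError("negative b-value in protocol")
        nz = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[nz], axis=1)
        if np.any(norms == 0):
            raise ValueError("zero gradient direction for a b > 0 volume")
        self.bvecs[nz] /= norms[:, None]

    @property
    def n_volumes(self) -> int:
        return self.bvals.size

    @property
    def n_b0(self) -> int:
        return int(np.sum(self.bvals == 0))

    @property
    def b0_indices(self) -> np.ndarray:
        return np.flatnonzero(self.bvals == 0)

    def shells(self) -> np.ndarray:
        return np.unique(self.bvals[self.bvals > 0])


@dataclass
class PhaseErrorSpec:
    """Ground-truth odd-even phase difference as a low-order polynomial in
    normalized in-plane coordinates (radians), plus an optional per-volume
    jitter of the constant term (uniform in +-jitter)."""

    constant: float = 0.0
    linear_x: float = 0.0
    linear_y: float = 0.0
    quad_x: float = 0.0
    quad_y: float = 0.0
    cross: float = 0.0
    jitter: float = 0.0

    def evaluate(self, nx: int, ny: int, constant_offset: float = 0.0) -> np.ndarray:
        """Evaluate the polynomial on the [x, y] grid (coords in [-1, 1))."""
        x = (np.arange(nx) - nx // 2) / (nx / 2)
        y = (np.arange(ny) - ny // 2) / (ny / 2)
        xx, yy = np.meshgrid(x, y, indexing="ij")
        out = (
            self.constant
            + constant_offset
            + self.linear_x * xx
            + self.linear_y * yy
            + self.quad_x * xx**2
            + self.quad_y * yy**2
            + self.cross * xx * yy
        )
        if not np.all(np.isfinite(out)):
            raise ValueError("phase-error polynomial evaluated to non-finite values")
        return out


@dataclass
class MultiCoilKSpace:
    """Undersampled multi-coil k-space with sampling mask and per-line
    parity labels (+1 odd, -1 even, 0 unacquired) over the ky axis."""

    data: np.ndarray  # complex [coil, kx, ky, z, volume]
    mask: np.ndarray  # bool (ky,)
    parity: np.ndarray  # int8 (ky,)
    R: int

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.parity = np.asarray(self.parity, dtype=np.int8)

    @property
    def n_coils(self) -> int:
        return self.data.shape[0]

    @property
    def acquired(self) -> np.ndarray:
        return np.flatnonzero(self.mask)

    @property
    def offset(self) -> int:
        return int(self.acquired[0])

    def validate(self) -> None:
        ny = self.data.shape[2]
        acq = self.acquired
        if acq.size != ny // self.R or np.any(np.diff(acq) != self.R):
            raise ValueError("sampling mask inconsistent with acceleration factor R")
        unacq = ~self.mask
        if np.any(self.data[:, :, unacq] != 0):
            raise ValueError("unacquired ky lines must be exactly zero")
        if np.any(self.parity[unacq] != 0):
            raise ValueError("parity labels present on unacquired lines")
        lab = self.parity[acq]
        if np.any(lab == 0):
            raise ValueError("acquired lines must carry parity labels")
        alternating = np.all(lab[0::2] == lab[0]) and np.all(lab[1::2] == -lab[0])
        uniform = np.all(lab == lab[0])  # a parity child keeps one parity only
        if not (alternating or uniform):
            raise ValueError("parity must alternate over acquired lines")


@dataclass
class GroundTruthBundle:
    """Everything the evaluation module needs to score a reconstruction."""

    images: np.ndarray  # noiseless coil-combined series [x, y, z, volume]
    phase_maps: np.ndarray  # true odd-even phase difference [x, y, volume]
    psi_true: np.ndarray  # true coil noise covariance [coil, coil]
    md: np.ndarray  # true mean diffusivity [x, y, z]
    fa: np.ndarray  # true fractional anisotropy [x, y, z]
    object_mask: np.ndarray  # bool [x, y, z]
    noise_rows: int = 8  # rows x < noise_rows are guaranteed object-free


# ---------------------------------------------------------------------------
# phantom
# ---------------------------------------------------------------------------


def build_phantom(
    grid_shape: Sequence[int], compartment_spec: Sequence[Mapping]
) -> PhantomDefinition:
    """Rasterize labeled cylindrical compartments into a phantom.

    Each compartment is a mapping with keys ``label`` (int > 0), ``center``
    ((x, y) voxels), ``radius`` (voxels), ``s0`` (> 0) and ``tensor``
    (3x3 symmetric PSD, mm^2/s); optional ``z_range`` restricts slices.
    Later compartments overwrite earlier ones, so nested geometries are
    expressed by listing the outer cylinder first.
    """
    nx, ny, nz = grid_shape
    if min(nx, ny) < 32:
        raise ValueError("in-plane grid must be at least 32x32")
    label_map = np.zeros((nx, ny, nz), dtype=np.int32)
    s0: dict[int, float] = {}
    tensors: dict[int, np.ndarray] = {}
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    for comp in compartment_spec:
        lab = int(comp["label"])
        if lab <= 0:
            raise ValueError("compartment labels must be positive (0 is background)")
        D = np.asarray(comp["tensor"], dtype=float)
        if D.shape != (3, 3) or not np.allclose(D, D.T):
            raise ValueError(f"tensor for label {lab} is not a symmetric 3x3 matrix")
        ev = np.linalg.eigvalsh(D)
        if ev.min() < -1e-12 * max(ev.max(), 1e-30):
            raise ValueError(f"tensor for label {lab} is not positive semi-definite")
        cx, cy = comp["center"]
        inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= comp["radius"] ** 2
        z0, z1 = comp.get("z_range", (0, nz))
        label_map[:, :, z0:z1][inside] = lab
        s0[lab] = float(comp["s0"])
        tensors[lab] = D
    return PhantomDefinition(label_map=label_map, s0=s0, tensors=tensors)


def _rotated_tensor(evals: Sequence[float], axis_angle: float, tilt: float = 0.3) -> np.ndarray:
    """Diagonal tensor with eigenvalues ``evals`` whose principal axis points
    along (cos a, sin a, tilt)/|.| in the xy-plane (angle in radians)."""
    v1 = np.array([np.cos(axis_angle), np.sin(axis_angle), tilt])
    v1 /= np.linalg.norm(v1)
    # complete an orthonormal frame
    helper = np.array([0.0, 0.0, 1.0]) if abs(v1[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    v2 = np.cross(v1, helper)
    v2 /= np.linalg.norm(v2)
    v3 = np.cross(v1, v2)
    rot = np.stack([v1, v2, v3], axis=1)
    return rot @ np.diag(evals) @ rot.T


def default_phantom(
    grid_shape: Sequence[int] = (64, 64, 8), n_wedges: int = 24
) -> PhantomDefinition:
    """Constant-MD anisotropic wedge cylinder.

    A cylinder of azimuthal wedges, each carrying the same eigenvalues
    (3.0, 1.5, 1.5)x10^-3 mm^2/s (MD = 2.0x10^-3, the reference diffusivity
    of the physical phantom this stands in for; FA ~ 0.41, with the largest
    eigenvalue kept at or below the free-water diffusivity) with the
    principal axis rotating from wedge to wedge.  The rotating
    orientation gives the volume series direction-dependent signal content —
    the spectral richness real DW data have and PCA-based denoising is
    sensitive to — while keeping ground-truth MD and FA spatially constant
    so across-voxel accuracy/precision statistics remain meaningful.  The
    cylinder is kept clear of the top readout rows (noise-only region) and
    small enough along y that its half-FOV Nyquist ghost does not overlap
    the object.
    """
    nx, ny, nz = grid_shape
    cx, cy = nx // 2 + nx // 10, ny // 2
    radius = 0.22 * min(nx, ny)
    evals = (3.0e-3, 1.5e-3, 1.5e-3)
    spec = []
    for k in range(n_wedges):
        spec.append(
            {
                "label": k + 1,
                "s0": 1.0,
                "tensor": _rotated_tensor(evals, np.pi * k / n_wedges),
            }
        )
    ph = build_phantom_wedges(grid_shape, (cx, cy), radius, spec)
    return ph


def build_phantom_wedges(
    grid_shape: Sequence[int],
    center: tuple[float, float],
    radius: float,
    wedge_spec: Sequence[Mapping],
) -> PhantomDefinition:
    """Rasterize azimuthal wedge compartments of one cylinder (equal angular
    sectors, one labeled compartment per entry of ``wedge_spec``)."""
    nx, ny, nz = grid_shape
    if min(nx, ny) < 32:
        raise ValueError("in-plane grid must be at least 32x32")
    n = len(wedge_spec)
    cx, cy = center
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
    theta = np.mod(np.arctan2(yy - cy, xx - cx), 2 * np.pi)
    sector = np.minimum((theta / (2 * np.pi) * n).astype(int), n - 1)
    label_map = np.zeros((nx, ny, nz), dtype=np.int32)
    s0: dict[int, float] = {}
    tensors: dict[int, np.ndarray] = {}
    for k, comp in enumerate(wedge_spec):
        lab = int(comp["label"])
        D = np.asarray(comp["tensor"], dtype=float)
        ev = np.linalg.eigvalsh(D)
        if ev.min() < -1e-12 * max(ev.max(), 1e-30):
            raise ValueError(f"tensor for label {lab} is not positive semi-definite")
        label_map[inside & (sector == k)] = lab
        s0[lab] = float(comp["s0"])
        tensors[lab] = D
    return PhantomDefinition(label_map=label_map, s0=s0, tensors=tensors)


# ---------------------------------------------------------------------------
# coils
# ---------------------------------------------------------------------------


def simulate_coil_sensitivities(
    n_coils: int,
    grid_shape: Sequence[int],
    profile_params: Mapping | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Smooth complex coil sensitivity maps ``[coil, x, y, z]``.

    Coil centers sit on a ring around the FOV; magnitudes are Gaussian lobes
    and phases low-order polynomials, which is a standard surrogate for
    measured array-coil profiles.  Deterministic for a fixed seed.
    """
    params = dict(profile_params or {})
    nx, ny, nz = grid_shape
    if params.get("kind") == "uniform":
        maps = np.ones((n_coils, nx, ny, nz), dtype=complex)
        return maps
    if n_coils < 2:
        warnings.warn(
            "fewer than 2 coils: SENSE unfolding with R >= 2 will be singular",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    ring_radius = params.get("ring_radius", 0.55) * max(nx, ny)
    width = params.get("width", 0.25) * max(nx, ny)
    phase_scale = params.get("phase_scale", 2.0)
    angle0 = rng.uniform(0, 2 * np.pi)
    xx, yy = np.meshgrid(np.arange(nx) - nx / 2, np.arange(ny) - ny / 2, indexing="ij")
    maps = np.empty((n_coils, nx, ny, nz), dtype=complex)
    for k in range(n_coils):
        th = angle0 + 2 * np.pi * k / n_coils
        cx, cy = ring_radius * np.cos(th), ring_radius * np.sin(th)
        mag = np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2)) / (2 * width**2))
        # smooth per-coil phase: constant + ramp toward the coil center
        a, b, c = rng.uniform(-phase_scale, phase_scale, size=3)
        ph = a + b * (xx - cx) / nx + c * (yy - cy) / ny
        maps[k] = (mag * np.exp(1j * ph))[:, :, None]
    maps /= np.abs(maps).max()
    return maps


# ---------------------------------------------------------------------------
# diffusion forward model
# ---------------------------------------------------------------------------


def simulate_dwi_series(phantom: PhantomDefinition, protocol: DiffusionProtocol) -> np.ndarray:
    """Noiseless coil-combined series from the mono-exponential tensor model
    S(b, g) = S0 * exp(-b * g^T D g), returned as ``[x, y, z, volume]``."""
    if protocol.n_volumes < 1:
        raise ValueError("protocol must contain at least one volume")
    nx, ny, nz = phantom.label_map.shape
    out = np.zeros((nx, ny, nz, protocol.n_volumes))
    for lab, D in phantom.tensors.items():
        adc = np.einsum("vi,ij,vj->v", protocol.bvecs, D, protocol.bvecs)
        sig = phantom.s0[lab] * np.exp(-protocol.bvals * adc)
        out[phantom.label_map == lab] = sig
    return out


# ---------------------------------------------------------------------------
# EPI encoding
# ---------------------------------------------------------------------------


def default_noise_covariance(n_coils: int, sigma: float, rho: float = 0.2) -> np.ndarray:
    """Exponentially correlated coil covariance: Psi_ij = sigma^2 rho^|i-j|.

    ``sigma**2`` is the total complex variance per coil sample.
    """
    idx = np.arange(n_coils)
    return sigma**2 * rho ** np.abs(idx[:, None] - idx[None, :])


def default_phase_error() -> PhaseErrorSpec:
    """Residual 2D phase error left after a 1D (constant + linear-x) on-scanner
    correction: modest constant/linear terms plus curvature, ~1 rad span."""
    return PhaseErrorSpec(constant=0.3, linear_x=0.4, linear_y=0.25, quad_x=0.25)


def encode_epi(
    images: np.ndarray,
    coilmaps: np.ndarray,
    phase_error_spec: PhaseErrorSpec | None,
    R: int,
    noise_covariance: np.ndarray | None,
    seed: int = 0,
    ground_truth: Mapping | None = None,
    n_noise_samples: int = 4096,
    noise_rows: int = 8,
) -> tuple[MultiCoilKSpace, GroundTruthBundle, np.ndarray]:
    """Forward-encode an image series into ghosted, undersampled multi-coil
    k-space.

    Odd-parity ky lines sample the coil-weighted image multiplied by
    ``exp(i*dphi(x, y))``; even-parity lines sample it unmodified.  Every
    R-th line is kept (offset chosen so the DC line is acquired) and
    zero-mean complex Gaussian noise with coil covariance Psi is added to
    the acquired samples.  Returns the k-space, a ground-truth bundle, and a
    dedicated noise-only sample matrix ``[coil, n_noise_samples]`` drawn
    from the same covariance.
    """
    images = np.asarray(images)
    nx, ny, nz, nv = images.shape
    nc = coilmaps.shape[0]
    if coilmaps.shape[1:] != (nx, ny, nz):
        raise ValueError("coil map grid does not match the image grid")
    if ny % R:
        raise ValueError(f"R={R} does not divide the ky grid size {ny}")
    spec = phase_error_spec or PhaseErrorSpec()
    rng = np.random.default_rng(seed)

    off = (ny // 2) % R  # keep the DC line acquired
    mask = np.zeros(ny, dtype=bool)
    mask[off::R] = True
    acq = np.flatnonzero(mask)
    parity = np.zeros(ny, dtype=np.int8)
    parity[acq[0::2]] = 1  # odd = first acquired line and every other after
    parity[acq[1::2]] = -1
    odd_lines = parity == 1
    even_lines = parity == -1

    phase_maps = np.empty((nx, ny, nv))
    kspace = np.zeros((nc, nx, ny, nz, nv), dtype=complex)
    for v in range(nv):
        jit = rng.uniform(-spec.jitter, spec.jitter) if spec.jitter > 0 else 0.0
        dphi = spec.evaluate(nx, ny, constant_offset=jit)
        phase_maps[:, :, v] = dphi
        weighted = coilmaps * images[None, :, :, :, v]
        k_even = fft2c(weighted, axes=(1, 2))
        k_odd = fft2c(weighted * np.exp(1j * dphi)[None, :, :, None], axes=(1, 2))
        kv = np.where(odd_lines[None, None, :, None], k_odd, k_even)
        kv[:, :, ~mask] = 0.0
        kspace[..., v] = kv

    noise_samples = np.zeros((nc, n_noise_samples), dtype=complex)
    psi_true = np.zeros((nc, nc), dtype=complex)
    if noise_covariance is not None:
        psi_true = np.asarray(noise_covariance, dtype=complex)
        if psi_true.shape != (nc, nc) or not np.allclose(psi_true, psi_true.conj().T):
            raise ValueError("noise covariance must be Hermitian [coil x coil]")
        if np.any(psi_true):  # an all-zero covariance means noiseless
            ev = np.linalg.eigvalsh(psi_true)
            if ev.min() <= 0:
                raise ValueError("noise covariance must be positive-definite")
            L = np.linalg.cholesky(psi_true)
            n_acq = acq.size

            def draw(shape):
                eps = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
                return np.einsum("ij,j...->i...", L, eps * np.sqrt(0.5))

            kspace[:, :, acq] += draw((nc, nx, n_acq, nz, nv))
            noise_samples = draw((nc, n_noise_samples))

    ks = MultiCoilKSpace(data=kspace, mask=mask, parity=parity, R=R)
    truth = GroundTruthBundle(
        images=images,
        phase_maps=phase_maps,
        psi_true=psi_true,
        md=(ground_truth or {}).get("md", np.zeros((nx, ny, nz))),
        fa=(ground_truth or {}).get("fa", np.zeros((nx, ny, nz))),
        object_mask=np.asarray(
            (ground_truth or {}).get("object_mask", np.abs(images).max(axis=-1) > 0)
        ),
        noise_rows=noise_rows,
    )
    return ks, truth, noise_samples


def sample_noise_region(
    images: np.ndarray,
    n_rows: int = 8,
    support: np.ndarray | None = None,
    seed: int | None = None,
    max_samples: int | None = None,
) -> np.ndarray:
    """Extract noise-only samples from the top image rows of each coil.

    ``images`` is any coil-first array ``[coil, x, ...]``; the top ``n_rows``
    rows along the readout (x) axis are taken as noise-only, mirroring the
    practice of reading noise statistics off an object-free strip of each
    coil image.  Returns a ``[coil, samples]`` matrix.
    """
    images = np.asarray(images)
    if n_rows <= 0:
        raise ValueError("noise region has zero area")
    nc = images.shape[0]
    if support is not None:
        frac = float(np.mean(support[:n_rows]))
        if frac > 0:
            warnings.warn(
                f"noise region overlaps object support (overlap fraction {frac:.3f})",
                stacklevel=2,
            )
    samples = images[:, :n_rows].reshape(nc, -1)
    if samples.shape[1] < 10 * nc:
        warnings.warn(
            f"noise region yields only {samples.shape[1]} samples per coil", stacklevel=2
        )
    if max_samples is not None and samples.shape[1] > max_samples:
        rng = np.random.default_rng(seed)
        keep = rng.choice(samples.shape[1], size=max_samples, replace=False)
        samples = samples[:, keep]
    return samples


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------


def make_directions(n: int) -> np.ndarray:
    """n roughly isotropically distributed unit vectors (golden-spiral)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1 + 5**0.5) * i
    z = 1 - 2 * i / n
    r = np.sqrt(1 - z**2)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def default_protocol(
    shells: Sequence[float] = (1000.0, 2000.0, 3000.0),
    n_dirs: int = 10,
    n_b0: int = 6,
) -> DiffusionProtocol:
    """Multi-shell protocol mirroring the in-vivo acquisition design (three
    shells up to b=3000 s/mm^2 plus interleaved b=0 volumes), scaled to a
    direction count that keeps desk-scale simulations fast."""
    dirs = make_directions(n_dirs)
    bvals = [0.0] * n_b0
    bvecs = [np.zeros(3)] * n_b0
    for b in shells:
        bvals += [float(b)] * n_dirs
        bvecs += list(dirs)
    return DiffusionProtocol(bvals=np.array(bvals), bvecs=np.array(bvecs))
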