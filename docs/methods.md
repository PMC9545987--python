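# Methods

This note records the models, conventions and design choices behind the
package, in the spirit of a methods appendix: what is simulated, how each
stage is computed, which knobs matter, and what the synthetic validation
does and does not establish about real data.

## Conventions

* Image arrays are `[x, y, z, volume]`; `y` is the phase-encode axis; coil
  arrays carry the coil axis first.
* All Fourier transforms are centered (DC at index `n//2`) and orthonormal,
  so white noise keeps its variance between k-space and image space.
* "Odd" parity is the first acquired ky line and every second acquired line
  after it.  Only the odd-even phase *difference* is observable, so the
  ground-truth and estimated phase errors are assigned wholly to the odd
  lines (a gauge choice; a constant offset moved between the odd data and
  the map leaves every output magnitude unchanged, and a test asserts it).
* Noise: "sigma" for complex data always means the total per-element
  standard deviation (real + imaginary).  Coil noise is drawn in k-space on
  the acquired samples, correlated across coils through the Cholesky factor
  of the true covariance, i.i.d. across samples.

## Undersampling and unfolding

With stride `s` and first acquired line `off`, the zero-filled centered
inverse FFT obeys an exact folding identity: each voxel of the aliased
image is `(1/s)·Σ_r u^r·I(y + r·N/s)` with the unit-modulus constant
`u = (−1)^{N/s}·e^{−2πi·off/s}` (verified against brute-force DFT).
Aliased coil images are stored as `sqrt(s)` times the zero-filled inverse
FFT, truncated to the first `N/s` block (the other blocks repeat it up to a
global phase).  That scaling makes the noise variance per aliased-image
voxel equal to the k-space channel covariance, so after prewhitening the
unfolding noise model is exactly unit-variance and the replica noise law
`std = g·sqrt(R)·sigma/rss(C)` holds with no fudge factors (asserted to 10%
over 200 replicas).

Unfolding solves the per-voxel least-squares system with unweighted normal
equations — inputs are prewhitened, which a test shows is identical (to
1e-8) to carrying the covariance through a generalized least-squares solve.
The g-factor at folded position j is `sqrt([(EᴴE)⁻¹]_jj·[EᴴE]_jj)`.
Background fold positions (no coil sensitivity) are decoupled and set to 0
with g = NaN; systems with condition number above 1e8 are zeroed and
counted.

## Phase-error estimation and the joint solve

The parity split doubles the effective acceleration (stride 2R, two
offsets).  Each parity is SENSE-unfolded on its own; the raw phase map is
the argument of `I_odd·conj(I_even)`.  Smoothing filters the complex
product with a 2D Gaussian of FWHM 5 voxels per slice and takes the
argument afterwards — magnitude-weighted and wrap-safe.  The width is a
free parameter (`phase_fwhm`); nothing in the correction pins it, and 3–8
voxels behave similarly on the default geometry.  Maps are estimated per
slice and per volume (EPI phase errors are per-excitation); per-volume
jitter in the simulator exercises exactly this.

The final solve stacks, for every group of 2R folded voxels, the even-parity
equations with sensitivities `Cw` and the odd-parity equations with
`Cw·e^{iΔφ}` — 2·n_coils equations, 2R unknowns, solved per volume since
the map is per volume.  With Δφ = 0 this is algebraically the same
information as the merged SENSE problem and the outputs agree to machine
precision; with the true simulated Δφ the ghost is removed exactly on
noiseless data (both asserted).

## MPPCA

Eigenvalues of the Gram matrix of the complex Casorati matrix (no
real/imaginary stacking, no mean-centering, transposed when the kernel
volume is smaller than the volume count) are scanned for the smallest
signal count p such that the remaining eigenvalues fit inside the
Marcenko–Pastur bulk: `λ_max_noise − λ_min ≤ 4·sqrt(γ)·σ̂²`, with σ̂² the
mean of the candidate noise eigenvalues and γ their count over the larger
dimension.  The factor 4·sqrt(γ) is the asymptotic edge-to-edge width of
the MP distribution; eigenvalues below 1e-12 of the largest are treated as
exact zeros so noiseless low-rank data report their true rank.  Edge voxels
keep their own row of a kernel shifted to stay in bounds (no overlap
averaging).  `sigma_map` stores the total per-element sigma; for real
(magnitude) input this is the per-component Rician sigma, which is what the
method-of-moments correction expects.

## Post-reconstruction denoising variants

* magnitude mode: MPPCA on the modulus, then `Â = sqrt(max(M² − 2σ̂², 0))`
  with MPPCA's own spatially varying sigma map;
* complex mode: a smooth background phase (argument of a Gaussian-filtered
  copy, FWHM 8 voxels) is conjugated away — magnitude preserved exactly —
  then complex MPPCA, then the modulus.  The phase-flattening step is a
  deliberately simple low-pass stand-in for decorrelated phase filtering;
  it serves the same purpose (keeping smooth phase structure from
  masquerading as signal components) without reproducing that algorithm.

## Diffusion models

The tensor fit is log-linear IRLS restricted to b ≤ 1000 s/mm² (volumes
above the cutoff are excluded): weights equal the squared current signal
prediction, iterated from an unweighted fit to a relative parameter change
below 1e-6 (max 50 iterations).  Nonpositive samples are floored at machine
epsilon for the transform and excluded through zero weights; voxels with
fewer than 7 usable samples are left at zero.  Design columns are
equilibrated before the normal-equations solve (the raw design mixes scales
1 to b² ≈ 1e6) and a relative ridge of 1e-12 keeps degenerate valid-sample
patterns solvable.  The kurtosis fit is the 22-column weighted linear
least-squares form with the mean diffusivity absorbed into `V = MD²·W`
(two reweighting passes); MK is the mean apparent kurtosis over the
acquisition's diffusion directions rather than an analytic sphere integral.

Two estimator facts surfaced during validation and are worth knowing.
First, on *rectified* (Rician) magnitudes around SNR 10 the IRLS weighting
buys nothing over the unweighted log-linear fit (log-magnitude noise has
bounded variance at low signal); its clear advantage appears under additive
Gaussian noise, its design condition — both are pinned by tests.  Second,
the zero-clamp in the method-of-moments correction adds a small positive
bias to the corrected second moment (≈3.6% at A/σ = 2, vanishing by
A/σ = 4).

## The simulated study

Defaults (all in `SimulationConfig`):

| parameter | default | why |
| --- | --- | --- |
| grid | 64×64×8 | full eight-pipeline comparison in ~1.5 min on one CPU |
| coils | 8 | smallest array that keeps the stride-4 parity unfolds well conditioned (lobe width 0.25·FOV, ring radius 0.55·FOV, per-coil phase ramps ~2 rad) |
| R | 2 | standard clinical acceleration; parity children run at 4 |
| protocol | b = 1000/2000/3000 s/mm², 10 directions/shell, 6 b=0 | the in-vivo-style multishell design, scaled down |
| phantom | constant-MD anisotropic wedge cylinder, MD 2.0×10⁻³ mm²/s, FA 0.41 | see below |
| phase error | 0.3 + 0.4x̃ + 0.25ỹ + 0.25x̃² rad | residual 2D error after a 1D (constant/linear) correction; ~1 rad span produces an obvious ghost |
| noise sigma | 0.045 (fraction of S0, per coil sample) | calibrated once so the undenoised reconstructions sit at the reference b=0 SNR regime (SENSE ≈ 11.5, PEC-SENSE ≈ 9) |
| coil noise correlation | exponential, ρ = 0.2 | realistic mild inter-channel coupling; exercises prewhitening |

The phantom deserves a note.  A homogeneous isotropic object under a
three-shell protocol produces a volume series of rank 4, which makes
PCA-based denoising unrealistically effective and its rank selection
degenerate.  The default phantom therefore rotates the principal axis of a
fixed-eigenvalue tensor ((3.0, 1.5, 1.5)×10⁻³ mm²/s — largest eigenvalue at
the free-water ceiling) across 24 azimuthal wedges: the series gains the
direction-dependent spectral content real diffusion data have, while
ground-truth MD and FA stay spatially constant so across-voxel
accuracy/precision statistics remain meaningful.  The top 8 readout rows
are kept object-free as the noise calibration region, and the cylinder is
small enough along y that its half-FOV ghost lands outside the object.

## What the synthetic validation shows — and what it does not

The simulation reproduces the qualitative mechanics end to end: exact ghost
removal given the true phase map, order-of-magnitude ghost suppression with
the estimated map, the SNR cost of phase correction, the noise-floor bias
of MD under g-noise amplification, and its recovery by channel-wise complex
denoising (bias cut >10×, CoV >10×).  Two caveats:

* MPPCA is *more* effective here than on scanner data: even the wedge
  phantom's series has far fewer significant components than in-vivo data
  with physiological fluctuation, so post-denoising SNR values are
  optimistic in absolute terms.  Orderings between pipelines are the
  meaningful output, not SNR magnitudes.
* The magnitude-domain post-reconstruction pipeline (`*_m`) is fragile in
  this regime, and measurably worse than the real study it imitates: the
  spatially varying g-noise inside a 5×5×5 patch inflates the MPPCA sigma
  estimate (~1.5×), the method-of-moments correction then clamps a sizable
  fraction of b = 1000 samples to zero, and the resulting per-voxel
  direction dropout lets a percent of voxels fit unbounded tensors that
  dominate mean/SD statistics.  A protocol with additional low-b shells
  (such as the 20-shell phantom protocol the reference values come from)
  anchors those fits and bounds the effect; the scaled-down three-shell
  design does not.  This is documented rather than patched: it is the same
  iid-violation argument that motivates denoising the channel data before
  image formation.

## Known limitations

* No pulse-sequence physics: relaxation, susceptibility distortion, eddy
  currents, motion, partial Fourier and multi-shot EPI are out of scope.
* Phase errors are 2D polynomials constant across slices (per-volume jitter
  optional); real residual errors can have higher spatial orders.
* No constrained (positive-definite) tensor estimation or outlier
  rejection; fits in noise-floor-dominated voxels can be wild, as discussed
  above.
* The decorrelated-phase-filtering step of the complex post-recon pipeline
  is a simplified low-pass surrogate.
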