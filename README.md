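# spectremri

Ghost-corrected, noise-mitigated reconstruction of diffusion-weighted EPI
(DW-EPI) from multi-coil k-space, with a ground-truthed simulator and a
quantitative evaluation harness.

## The problem

EPI acquires alternate k-space lines under opposite readout gradients.
Residual phase differences between odd and even lines displace part of the
signal by half the field of view — the Nyquist (N/2) ghost.  A 2D phase
error map can be estimated self-referentially by reconstructing the two
line parities separately with SENSE, but splitting the lines doubles the
effective acceleration, and the geometry-factor (g-factor) noise penalty of
that ill-posed unfold is severe exactly where diffusion imaging is already
starved for SNR (high b-values).  The resulting noise floor biases
diffusion metrics: mean diffusivity (MD) is underestimated, mean kurtosis
(MK) inflated.

This package implements the reconstruction strategy that resolves the
conflict: denoise the **complex channel data** with Marcenko–Pastur PCA
(MPPCA) *before* phase correction and image formation, then apply
phase-error-corrected SENSE (PEC-SENSE).  Eight pipelines are provided for
controlled comparison — `{sense, pecsense} × {no denoising, magnitude (_m),
complex (_c), channel-wise (_ch)}` — where `pecsense_ch` is the flagship
combination, exposed under the name `spectre`.

## Method sketch

1. **Prewhitening** — coil noise covariance Ψ from a noise-only image
   region; channels and sensitivities decorrelated with D = L⁻¹ (Ψ = LLᴴ),
   so that Sw = D·S, Cw = D·C carry i.i.d. unit-variance noise.
2. **Channel-wise MPPCA** — per coil, a sliding 5×5×5 kernel forms the
   Casorati matrix X (voxels × volumes); eigenvalues of (1/M)XᴴX are
   compared against the Marcenko–Pastur law to split signal from noise
   components and estimate σ² simultaneously.
3. **PEC-SENSE** — odd/even k-space lines reconstructed separately at 2R;
   the smoothed argument of I_odd·conj(I_even) gives the 2D phase map
   Δφ(x, y) per slice and volume; a joint solve stacks even rows (Cw) and
   odd rows (Cw·e^{iΔφ}) over the 2R folded positions.
4. **Diffusion models** — tensor fit by iteratively reweighted least
   squares on volumes with b ≤ 1000 s/mm² (MD = tr(D)/3, FA from the
   eigenvalues), kurtosis fit by weighted linear least squares on the
   22-parameter log-linear expansion, NRMSE between data and model.
5. **Evaluation** — replica SNR (per-voxel mean/SD over b=0 volumes),
   accuracy (mean voxel-wise error relative to ground truth; positive =
   underestimation), precision (CoV across voxels) and a ghost-to-signal
   ratio against the known object mask.

The simulator generates the whole study synthetically: a constant-MD
anisotropic phantom (MD = 2.0×10⁻³ mm²/s), smooth complex coil
sensitivities, mono-exponential diffusion contrast over three shells
(b = 1000/2000/3000 s/mm²), polynomial odd-even phase errors, R = 2
undersampling and correlated complex Gaussian coil noise — all with ground
truth retained for scoring.

## Worked example

```python
from spectremri.config import SimulationConfig
from spectremri.evaluation import compare_pipelines
from spectremri.study import make_dataset

raw = make_dataset(SimulationConfig(), seed=7)
report = compare_pipelines(raw, ["sense", "pecsense", "spectre", "reference"])
cols = ["snr", "md_mean", "md_sd", "md_cov_pct", "md_error_pct", "gsr"]
print(report[cols].to_string(float_format=lambda v: f"{v:7.3f}"))
```

prints

```
              snr  md_mean   md_sd  md_cov_pct  md_error_pct     gsr
pipeline
sense      10.922    1.875   0.759      40.461         6.250   0.085
pecsense    8.811    1.535   0.999      65.108        23.247   0.095
spectre    71.376    1.965   0.078       3.977         1.735   0.038
reference     NaN    2.000   0.000       0.000         0.000   0.000
```

Reading the table: plain SENSE leaves a visible ghost (ghost-to-signal
ratio 0.085) but moderate noise; PEC-SENSE removes the coherent ghost at
the cost of g-noise amplification, which drives a 23% underestimation of MD
(1.535 vs the true 2.000×10⁻³ mm²/s) and poor precision (CoV 65%).
`spectre` — channel-wise complex denoising *before* the phase-corrected
unfold — recovers MD to within 2% at a CoV of 4%.  The `reference` row fits
the noiseless ground-truth series, standing in for a ghost-free spin-echo
reference acquisition.

The same chain is available from the shell:

```bash
spectre simulate --grid 64,64,8 --coils 8 --b 1000,2000,3000 --seed 7 --out raw.h5
spectre recon --raw raw.h5 --pipeline spectre --out rec          # NIfTI output
spectre fit  --data rec_mag.nii.gz --bvals raw.bvals --bvecs raw.bvecs --out maps
spectre eval --raw raw.h5 --pipelines sense,pecsense,spectre --out report.csv
```

## Layout

| module | contents |
| --- | --- |
| `spectremri.simulate` | phantom, coil maps, diffusion contrast, EPI encoding, noise |
| `spectremri.prewhiten` | Ψ estimation, inverse-Cholesky decorrelation |
| `spectremri.mppca` | MP threshold, sliding-kernel series/channel denoising |
| `spectremri.sense` | aliased-image formation, SENSE unfold, g-factor maps |
| `spectremri.pecsense` | parity split, Δφ estimation, joint corrected unfold |
| `spectremri.postproc` | magnitude+method-of-moments and complex post-recon denoising |
| `spectremri.diffusion` | DTI (IRLS), DKI (WLS), MD/FA/MK, NRMSE |
| `spectremri.evaluation` | replica SNR, accuracy, CoV, ghost ratio, pipeline comparison |
| `spectremri.io`, `.config`, `.cli`, `.study` | HDF5/NIfTI/bval-bvec formats, validated config, CLI, dataset factory |

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
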