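"""Diffusion tensor / kurtosis fitting and derived scalar maps."""

import numpy as np
import pytest

from spectremri.diffusion import (
    design_matrix,
    fa_from_eigenvalues,
    fit_dki_lls,
    fit_dti_irls,
    model_nrmse,
    predict_signal,
    tensor_metrics,
)
from spectremri.simulate import DiffusionProtocol, default_protocol, make_directions


def _signals_from_tensor(protocol, d, s0=1.0):
    adc = np.einsum("vi,ij,vj->v", protocol.bvecs, d, protocol.bvecs)
    return s0 * np.exp(-protocol.bvals * adc)


def _fa_oracle(evals):
    ev = np.asarray(evals, dtype=float)
    md = ev.mean()
    return np.sqrt(1.5 * np.sum((ev - md) ** 2) / np.sum(ev**2))


class TestDesignMatrix:
    def test_b0_row(self):
        prot = DiffusionProtocol([0.0, 1000.0], [[0, 0, 0], [1, 0, 0]])
        a = design_matrix(prot, "dti")
        assert np.array_equal(a[0], [1, 0, 0, 0, 0, 0, 0])

    def test_axis_aligned_direction(self):
        prot = DiffusionProtocol([1000.0], [[1, 0, 0]])
        row = design_matrix(prot, "dti")[0]
        assert row[1] == -1000.0 and np.all(row[2:] == 0)

    def test_dki_needs_two_shells(self):
        prot = DiffusionProtocol([0.0, 1000.0], [[0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValueError, match="2 nonzero"):
            design_matrix(prot, "dki")

    def test_forward_model_consistency(self):
        """Design matrix times stacked true parameters reproduces the
        log-signals of the exponential tensor forward model to 1e-10."""
        prot = default_protocol(n_dirs=8, n_b0=2)
        rng = np.random.default_rng(0)
        q = rng.standard_normal((3, 3))
        d = 1e-3 * (q @ q.T / np.abs(q @ q.T).max() + np.eye(3))
        sig = _signals_from_tensor(prot, d, s0=2.0)
        params = np.concatenate(
            [[np.log(2.0)], [d[0, 0], d[1, 1], d[2, 2], d[0, 1], d[0, 2], d[1, 2]]]
        )
        a = design_matrix(prot, "dti")
        assert np.abs(a @ params - np.log(sig)).max() < 1e-10


class TestDtiFit:
    def test_noiseless_isotropic_exact(self):
        prot = default_protocol(n_dirs=8, n_b0=2)
        sig = _signals_from_tensor(prot, 1.0e-3 * np.eye(3))
        fit = fit_dti_irls(np.tile(sig, (2, 2, 1, 1)), prot)
        md, fa = tensor_metrics(fit)
        assert np.abs(md - 1.0e-3).max() < 1e-10
        assert np.abs(fa).max() < 1e-8

    def test_bmax_default_and_volume_selection(self):
        prot = default_protocol(n_dirs=8, n_b0=2)
        sig = _signals_from_tensor(prot, 1.0e-3 * np.eye(3))
        fit = fit_dti_irls(sig[None, None, None], prot)
        assert set(prot.bvals[fit.volumes_used]) == {0.0, 1000.0}

    def test_noiseless_anisotropic_matches_oracle(self):
        evals = np.array([1.7e-3, 0.3e-3, 0.3e-3])
        rng = np.random.default_rng(1)
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        d = q @ np.diag(evals) @ q.T
        prot = default_protocol(n_dirs=10, n_b0=2)
        sig = _signals_from_tensor(prot, d)
        fit = fit_dti_irls(sig[None, None, None], prot)
        assert np.abs(fit.tensors()[0, 0, 0] - d).max() < 1e-8 * np.abs(d).max()
        md, fa = tensor_metrics(fit)
        assert abs(fa[0, 0, 0] - _fa_oracle(evals)) < 1e-8

    def test_requires_b0_and_enough_volumes(self):
        prot = DiffusionProtocol([1000.0] * 8, make_directions(8))
        with pytest.raises(ValueError, match="b="):
            fit_dti_irls(np.ones((1, 1, 1, 8)), prot)

    def test_irls_beats_ols_under_gaussian_noise(self):
        """Reweighting corrects the heteroscedasticity the log transform
        induces on additive Gaussian noise: median |MD error| of IRLS is
        below the unweighted log-linear fit's."""
        rng = np.random.default_rng(2)
        prot = default_protocol(n_dirs=10, n_b0=4)
        d = np.diag([2.5e-3, 1.8e-3, 1.2e-3])
        sig = _signals_from_tensor(prot, d)
        n = 2000
        noisy = np.clip(
            sig + 0.1 * rng.standard_normal((n, prot.n_volumes)), 1e-6, None
        ).reshape(n, 1, 1, -1)
        md_true = np.trace(d) / 3
        md_i, _ = tensor_metrics(fit_dti_irls(noisy, prot))
        md_o, _ = tensor_metrics(fit_dti_irls(noisy, prot, max_iter=0))
        assert np.median(np.abs(md_i - md_true)) <= np.median(np.abs(md_o - md_true))

    def test_irls_near_parity_under_rician(self):
        """On rectified (Rician) magnitudes at SNR 10 the bounded variance of
        log-magnitude noise removes most of the reweighting advantage; the
        IRLS estimate stays within 15% of the unweighted fit's error."""
        rng = np.random.default_rng(2)
        prot = default_protocol(n_dirs=10, n_b0=4)
        d = np.diag([1.5e-3, 1.0e-3, 0.5e-3])
        sig = _signals_from_tensor(prot, d)
        n = 2000
        noisy = np.abs(
            sig
            + 0.1 * (rng.standard_normal((n, prot.n_volumes)) * 1j
                     + rng.standard_normal((n, prot.n_volumes)))
        ).reshape(n, 1, 1, -1)
        md_true = np.trace(d) / 3
        md_i, _ = tensor_metrics(fit_dti_irls(noisy, prot))
        md_o, _ = tensor_metrics(fit_dti_irls(noisy, prot, max_iter=0))
        assert np.median(np.abs(md_i - md_true)) <= 1.15 * np.median(np.abs(md_o - md_true))

    def test_rotation_equivariance(self):
        """Rotating gradients and tensor together leaves MD and FA fixed."""
        rng = np.random.default_rng(3)
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        d = np.diag([1.7e-3, 0.5e-3, 0.2e-3])
        dirs = make_directions(12)
        prot_a = DiffusionProtocol([0.0, 0.0] + [1000.0] * 12,
                                   np.vstack([np.zeros((2, 3)), dirs]))
        prot_b = DiffusionProtocol(prot_a.bvals, prot_a.bvecs @ q.T)
        sig_a = _signals_from_tensor(prot_a, d)
        sig_b = _signals_from_tensor(prot_b, q @ d @ q.T)
        assert np.abs(sig_a - sig_b).max() < 1e-12  # same scalar contrast
        md_a, fa_a = tensor_metrics(fit_dti_irls(sig_a[None, None, None], prot_a))
        md_b, fa_b = tensor_metrics(fit_dti_irls(sig_b[None, None, None], prot_b))
        assert abs(md_a[0, 0, 0] - md_b[0, 0, 0]) < 1e-8
        assert abs(fa_a[0, 0, 0] - fa_b[0, 0, 0]) < 1e-8


class TestFaMd:
    def test_isotropic_fa_zero(self):
        assert fa_from_eigenvalues(np.array([1.0, 1.0, 1.0])) == 0.0

    def test_rank_one_fa_one(self):
        assert fa_from_eigenvalues(np.array([1.0, 0.0, 0.0])) == pytest.approx(1.0)

    def test_all_zero_tensor(self):
        assert fa_from_eigenvalues(np.zeros(3)) == 0.0

    def test_closed_form_oracle(self):
        evals = np.array([1.7e-3, 0.3e-3, 0.3e-3])
        assert abs(fa_from_eigenvalues(evals) - _fa_oracle(evals)) < 1e-10


class TestDkiFit:
    def _known_pair_signals(self, prot, seed=4):
        rng = np.random.default_rng(seed)
        d = np.diag([1.7e-3, 1.0e-3, 0.4e-3])
        w15 = rng.uniform(0.0, 0.8, 15)
        md = np.trace(d) / 3
        params = np.concatenate(
            [[0.3], [d[0, 0], d[1, 1], d[2, 2], d[0, 1], d[0, 2], d[1, 2]], md**2 * w15]
        )
        a = design_matrix(prot, "dki")
        return np.exp(a @ params), params

    def test_zero_kurtosis_gives_zero_mk(self):
        prot = default_protocol(n_dirs=10, n_b0=2)
        sig = _signals_from_tensor(prot, 1.2e-3 * np.eye(3))
        fit = fit_dki_lls(sig[None, None, None], prot)
        assert abs(fit.mk_map()[0, 0, 0]) < 1e-8

    def test_known_pair_recovered(self):
        """Noiseless signals from a known (D, W) pair on the 3-shell protocol
        invert to the generating parameters."""
        prot = default_protocol(shells=(1000.0, 2000.0, 3000.0), n_dirs=10, n_b0=2)
        sig, params = self._known_pair_signals(prot)
        fit = fit_dki_lls(sig[None, None, None], prot)
        assert np.abs(fit.params[0, 0, 0] - params).max() < 1e-6

    def test_too_few_volumes_rejected(self):
        prot = default_protocol(n_dirs=3, n_b0=2)  # 11 volumes < 22
        with pytest.raises(ValueError, match="22"):
            fit_dki_lls(np.ones((1, 1, 1, prot.n_volumes)), prot)

    def test_noise_floor_bias_directions(self):
        """Deep Rician floor biases MD downward and MK upward (median)."""
        rng = np.random.default_rng(5)
        prot = default_protocol(n_dirs=10, n_b0=6)
        md_true = 2.0e-3
        sig = np.exp(-prot.bvals * md_true)
        n = 2000
        sigma = 0.3  # total complex sigma: deep noise floor at b >= 1000
        noise = (rng.standard_normal((n, prot.n_volumes))
                 + 1j * rng.standard_normal((n, prot.n_volumes))) * (sigma * np.sqrt(0.5))
        noisy = np.abs(sig + noise).reshape(n, 1, 1, -1)
        dfit = fit_dti_irls(noisy, prot)
        md, _ = tensor_metrics(dfit)
        kfit = fit_dki_lls(noisy, prot)
        assert md.mean() < md_true  # floor flattens the b<=1000 decay
        assert np.median(kfit.mk_map()) > 0.1  # apparent kurtosis from the floor


class TestNrmse:
    def test_perfect_prediction(self):
        data = np.abs(np.random.default_rng(0).standard_normal((3, 3, 1, 5))) + 1
        _, mean = model_nrmse(data, data, np.ones((3, 3, 1), bool))
        assert mean == 0.0

    def test_constant_offset_closed_form(self):
        data = np.full((2, 2, 1, 10), 10.0)
        nrmse_map, mean = model_nrmse(data, data - 1.0, np.ones((2, 2, 1), bool))
        assert np.allclose(nrmse_map, 10.0) and mean == pytest.approx(10.0)

    def test_zero_mean_voxel_excluded(self):
        data = np.zeros((2, 1, 1, 4))
        data[0] = 5.0
        nrmse_map, mean = model_nrmse(data, data * 0 + 4.0, np.ones((2, 1, 1), bool))
        assert np.isnan(nrmse_map[1, 0, 0])
        assert mean == pytest.approx(20.0)

    def test_noise_propagation(self):
        """With prediction = truth, masked-mean NRMSE estimates the noise-to-
        signal ratio (100 seeded repeats, within 10%)."""
        ratios = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            truth = np.full((5, 5, 1, 20), 4.0)
            data = truth + 0.4 * rng.standard_normal(truth.shape)
            _, mean = model_nrmse(data, truth, np.ones((5, 5, 1), bool))
            ratios.append(mean)
        assert abs(np.mean(ratios) - 10.0) < 1.0  # sigma/signal = 10%

    def test_prediction_matches_forward_model(self):
        prot = default_protocol(n_dirs=8, n_b0=2)
        sig = _signals_from_tensor(prot, 1.0e-3 * np.eye(3))
        fit = fit_dti_irls(sig[None, None, None], prot)
        pred = predict_signal(fit)
        assert np.abs(pred[0, 0, 0] - sig[fit.volumes_used]).max() < 1e-8
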