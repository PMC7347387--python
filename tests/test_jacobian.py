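"""Exact linearization: locally connected conversion, DSTRF routes, masking."""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.signal import correlate2d

from dstrf import nn
from dstrf.cnn import CnnModel, CnnSpec, TrainingConfig
from dstrf.jacobian import (apply_mask, cnn_to_mlp, compute_dstrf,
                            compute_dstrf_series, conv_to_locally_connected,
                            count_state_switches, jackknife_mean_se,
                            significance_mask, train_jackknife_ensemble)
from dstrf.synth import SyntheticNeuronSpec, make_dataset


class TestConvToLocallyConnected:
    def test_identity_convolution(self):
        k = np.ones((1, 1, 1, 1))
        m = conv_to_locally_connected(k, (4, 5))
        np.testing.assert_array_equal(np.asarray(m.todense()), np.eye(20))

    def test_support_structure(self, rng):
        k = rng.standard_normal((3, 3, 1, 1))
        m = conv_to_locally_connected(k, (5, 5)).tocsc()
        nnz_per_out = np.diff(m.indptr)
        assert nnz_per_out.max() <= 9
        # interior outputs see the full kernel
        assert nnz_per_out[2 * 5 + 2] == 9

    @pytest.mark.parametrize("cin,cout", [(1, 3), (4, 2)])
    def test_matches_convolution_oracle(self, rng, cin, cout):
        k = rng.standard_normal((3, 3, cin, cout))
        h, w = 6, 7
        x = rng.standard_normal((h, w, cin))
        m = conv_to_locally_connected(k, (h, w))
        got = (x.ravel() @ m).reshape(h, w, cout)
        # independent oracle: scipy 2-D correlation per channel pair
        want = np.zeros((h, w, cout))
        for l in range(cout):
            for c in range(cin):
                want[:, :, l] += correlate2d(x[:, :, c], k[:, :, c, l], mode="same")
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_rejects_unsupported(self, rng):
        with pytest.raises(ValueError):
            conv_to_locally_connected(rng.random((3, 3, 1, 1)), (4, 4), stride=2)
        with pytest.raises(ValueError):
            conv_to_locally_connected(rng.random((2, 2, 1, 1)), (4, 4))


class TestCnnToMlp:
    def test_forward_equivalence_on_random_windows(self, untrained_cnn, random_windows):
        mlp = cnn_to_mlp(untrained_cnn)
        cnn_out = untrained_cnn.predict(random_windows[:20])
        for i in range(20):
            assert mlp.forward(random_windows[i]) == pytest.approx(cnn_out[i], abs=1e-8)

    def test_zero_input_gives_bias(self, untrained_cnn):
        mlp = cnn_to_mlp(untrained_cnn)
        assert mlp.forward(np.zeros((40, 32))) == pytest.approx(
            untrained_cnn.output_bias, abs=1e-12)

    def test_dense_layers_pass_through(self, untrained_cnn):
        mlp = cnn_to_mlp(untrained_cnn)
        dense = [w for w in mlp.layer_weights if not sp.issparse(w)]
        assert len(dense) == 2
        assert dense[0].shape == (1280, 32) and dense[1].shape == (32, 1)


class TestComputeDstrf:
    def test_methods_agree(self, untrained_cnn, random_windows):
        for i in range(5):
            a = compute_dstrf(untrained_cnn, random_windows[i], "gradient")
            b = compute_dstrf(untrained_cnn, random_windows[i], "weight_product")
            np.testing.assert_allclose(a, b, atol=1e-10)

    def test_matches_finite_differences(self, untrained_cnn, random_windows):
        x = random_windows[3]
        d = compute_dstrf(untrained_cnn, x, "gradient")
        eps = 1e-4
        idx = [(0, 0), (12, 7), (39, 31), (20, 16)]
        perturbed = []
        for i, j in idx:
            for s in (+eps, -eps):
                xx = x.copy()
                xx[i, j] += s
                perturbed.append(xx)
        out = untrained_cnn.predict(np.stack(perturbed))
        for k, (i, j) in enumerate(idx):
            fd = (out[2 * k] - out[2 * k + 1]) / (2 * eps)
            assert d[i, j] == pytest.approx(fd, abs=1e-6)

    def test_local_linearity_identity(self, untrained_cnn, random_windows):
        for i in range(10):
            x = random_windows[i]
            d = compute_dstrf(untrained_cnn, x, "weight_product")
            yhat = untrained_cnn.predict(x[None])[0]
            assert (d * x).sum() + untrained_cnn.output_bias == pytest.approx(
                yhat, abs=1e-8)

    def test_fully_active_network_is_globally_linear(self):
        model = CnnModel(CnnSpec(dropout_conv=0.0, dropout_dense=0.0), seed=2)
        model.set_weights([np.abs(w) + 0.01 for w in model.get_weights()])
        x1 = np.full((40, 32), 0.5)
        x2 = np.random.default_rng(0).uniform(0.1, 1.0, (40, 32))
        d1 = compute_dstrf(model, x1, "weight_product")
        d2 = compute_dstrf(model, x2, "weight_product")
        np.testing.assert_array_equal(d1, d2)  # same (fully active) region

    def test_region_stability_under_tiny_perturbation(self, untrained_cnn,
                                                      random_windows):
        x = random_windows[0]
        d1 = compute_dstrf(untrained_cnn, x, "weight_product")
        d2 = compute_dstrf(untrained_cnn, x + 1e-12, "weight_product")
        np.testing.assert_array_equal(d1, d2)

    def test_series_matches_pointwise(self, untrained_cnn, random_windows):
        series = compute_dstrf_series(untrained_cnn, random_windows[:6])
        assert series.n_slices == 6
        one = compute_dstrf(untrained_cnn, random_windows[4], "gradient")
        np.testing.assert_allclose(series.values[4], one, atol=1e-12)


class TestJackknifeFormula:
    def test_equal_estimates(self):
        mean, se = jackknife_mean_se(np.full(8, 3.3))
        assert mean == pytest.approx(3.3)
        assert se == pytest.approx(0.0)

    def test_two_point_case(self):
        mean, se = jackknife_mean_se(np.array([0.0, 2.0]))
        assert mean == pytest.approx(1.0)
        assert se == pytest.approx(1.0)

    def test_matches_direct_formula(self, rng):
        x = rng.standard_normal((10, 3))
        mean, se = jackknife_mean_se(x, axis=0)
        n = 10
        want = np.sqrt((n - 1) / n * ((x - x.mean(0)) ** 2).sum(0))
        np.testing.assert_allclose(se, want)
        np.testing.assert_allclose(mean, x.mean(0))

    def test_rejects_single_estimate(self):
        with pytest.raises(ValueError):
            jackknife_mean_se(np.array([1.0]))


class TestSignificanceMask:
    def test_full_agreement_kept(self, rng):
        est = np.abs(rng.standard_normal((20, 4, 4))) + 0.1
        assert significance_mask(est, min_agree=19).all()

    def test_18_of_20_zeroed(self, rng):
        est = np.abs(rng.standard_normal((20, 1, 1))) + 0.1
        est[0, 0, 0] = -1.0
        est[1, 0, 0] = -1.0
        assert not significance_mask(est, min_agree=19)[0, 0]
        est[1, 0, 0] = 1.0
        assert significance_mask(est, min_agree=19)[0, 0]

    def test_matches_counting_oracle(self, rng):
        est = rng.standard_normal((20, 5, 6))
        mask = significance_mask(est, min_agree=19)
        for i in range(5):
            for j in range(6):
                pos = sum(est[m, i, j] > 0 for m in range(20))
                neg = sum(est[m, i, j] < 0 for m in range(20))
                assert mask[i, j] == (pos >= 19 or neg >= 19)

    def test_apply_mask_idempotent_and_sign_preserving(self, rng):
        series = rng.standard_normal((7, 4, 4))
        mask = rng.random((7, 4, 4)) > 0.5
        once = apply_mask(series, mask)
        twice = apply_mask(once, mask)
        np.testing.assert_array_equal(once, twice)
        kept = once[mask]
        np.testing.assert_array_equal(np.sign(kept), np.sign(series[mask]))

    def test_default_min_agree_scales(self, rng):
        est = np.abs(rng.standard_normal((5, 2, 2))) + 0.1
        est[0, 0, 0] *= -1  # 4/5 < ceil(0.95*5) = 5
        mask = significance_mask(est)
        assert not mask[0, 0] and mask[1, 1]

    def test_min_agree_bounds(self, rng):
        with pytest.raises(ValueError):
            significance_mask(rng.standard_normal((5, 2)), min_agree=6)


class TestStateSwitches:
    def test_identical_windows_give_zero(self, untrained_cnn, random_windows):
        same = np.repeat(random_windows[:1], 5, axis=0)
        assert count_state_switches(untrained_cnn, same) == 0.0

    def test_matches_activation_pattern_oracle(self, untrained_cnn, random_windows):
        x = random_windows[:8]
        got = count_state_switches(untrained_cnn, x, batch_size=3)
        mlp = cnn_to_mlp(untrained_cnn)
        pats = []
        for w in x:
            _, masks = mlp.forward(w, return_activations=True)
            pats.append(np.concatenate([m.ravel() for m in masks]))
        pats = np.array(pats)
        want = np.sum(pats[:-1] != pats[1:]) / (len(x) - 1)
        assert got == pytest.approx(want)

    def test_rejects_single_window(self, untrained_cnn, random_windows):
        with pytest.raises(ValueError):
            count_state_switches(untrained_cnn, random_windows[:1])


def test_jackknife_ensemble_minimal_case():
    spec = SyntheticNeuronSpec(kind="linear", noise_sd=0.3, seed=15)
    ds = make_dataset(spec, duration_s=15.0, fractions=(0.7, 0.15, 0.15), seed=15)
    cfg = TrainingConfig(learning_rate=1e-3, max_epochs=1, patience=1, seed=1)
    ens = train_jackknife_ensemble(ds.split, config=cfg, n=2)
    assert ens.n_models == 2
    segs = ens.segments
    assert segs[0][1] == segs[1][0]  # contiguous partition
    assert abs((segs[0][1] - segs[0][0]) - (segs[1][1] - segs[1][0])) <= 1
    with pytest.raises(ValueError):
        train_jackknife_ensemble(ds.split, config=cfg, n=1)
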