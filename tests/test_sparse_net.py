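"""Sparse-coding network: sampling, whitening, LIF encoding, training."""

import numpy as np
import pytest

from v1sal.sparse_net import (
    ReceptiveFieldSet,
    SparseCodingModel,
    TrainingConfig,
    apply_whitener,
    compute_response_map,
    encode_patches,
    reconstruct_image,
    reconstruct_patches,
    sample_patches,
    whiten_patches,
)


class TestSamplePatches:
    def test_shape_and_determinism(self):
        rng_img = np.random.default_rng(0).uniform(size=(40, 40))
        pm1 = sample_patches([rng_img], 1000, 14, seed=7)
        pm2 = sample_patches([rng_img], 1000, 14, seed=7)
        assert pm1.shape == (1000, 196)
        assert np.array_equal(pm1, pm2)

    def test_constant_image_gives_constant_patches(self):
        pm = sample_patches([np.full((30, 30), 0.4)], 50, 8, seed=1)
        assert np.all(pm == 0.4)

    def test_rejects_small_image(self):
        with pytest.raises(ValueError):
            sample_patches([np.zeros((10, 10))], 5, 14, seed=0)

    def test_row_major_vectorization(self):
        img = np.arange(36, dtype=float).reshape(6, 6)
        pm = sample_patches([img], 20, 6, seed=0)  # only one valid position
        assert np.array_equal(pm[0], img.ravel())


class TestWhitening:
    def test_centering_and_identity_covariance(self):
        X = np.random.default_rng(2).normal(size=(5000, 16)) @ \
            np.random.default_rng(3).uniform(0.5, 2.0, size=(16, 16))
        Xw, V, mean = whiten_patches(X)
        assert np.all(np.abs(Xw.mean(axis=0)) < 1e-8)
        cov = Xw.T @ Xw / len(Xw)
        assert np.allclose(cov, np.eye(16), atol=1e-6)

    def test_stored_whitener_reproduces_output(self):
        X = np.random.default_rng(4).normal(size=(500, 9))
        Xw, V, mean = whiten_patches(X)
        assert np.allclose(apply_whitener(X, V, mean), Xw, atol=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            whiten_patches(np.ones((100, 4)))

    def test_warns_when_underdetermined(self):
        with pytest.warns(UserWarning):
            whiten_patches(np.random.default_rng(5).normal(size=(10, 16)))


def _toy_rf(Q, W=None, theta=None, T=50, eta=0.2):
    K, D = Q.shape
    cfg = TrainingConfig(
        n_neurons=K, patch_side=int(np.sqrt(D)), lif_steps=T, lif_leak=eta,
        n_epochs=1,
    )
    return ReceptiveFieldSet(
        Q=Q,
        W=np.zeros((K, K)) if W is None else W,
        theta=np.ones(K) if theta is None else theta,
        whitener=np.eye(D),
        mean=np.zeros(D),
        config=cfg,
    )


def _scalar_lif_oracle(drive, theta, T, eta):
    """Independent single-neuron simulation: plain python loop."""
    u, n = 0.0, 0
    for _ in range(T):
        u = (1 - eta) * u + eta * drive
        if u > theta:
            n += 1
            u = 0.0
    return n


class TestEncode:
    def test_zero_input_is_silent(self):
        Q = np.random.default_rng(6).normal(size=(5, 9))
        counts = encode_patches(np.zeros((3, 9)), Q, np.zeros((5, 5)), np.ones(5), 50, 0.2)
        assert np.all(counts == 0)

    @pytest.mark.parametrize("drive,theta", [(2.0, 0.5), (1.1, 1.0), (0.8, 1.0), (5.0, 0.2)])
    def test_matches_scalar_oracle(self, drive, theta):
        # one neuron, no inhibition, constant drive: exhaustive scalar sim
        Q = np.array([[drive]])
        x = np.ones((1, 1))
        counts = encode_patches(x, Q, np.zeros((1, 1)), np.array([theta]), 50, 0.2)
        assert counts[0, 0] == _scalar_lif_oracle(drive, theta, 50, 0.2)

    def test_count_grows_with_T(self):
        Q = np.array([[3.0]])
        x = np.ones((1, 1))
        args = (Q, np.zeros((1, 1)), np.array([0.2]))
        c25 = encode_patches(x, *args, 25, 0.2)[0, 0]
        c100 = encode_patches(x, *args, 100, 0.2)[0, 0]
        assert c100 > c25 > 0

    def test_inhibition_lowers_joint_counts(self):
        # duplicate neurons with strong mutual W fire less than without W
        Q = np.tile(np.random.default_rng(7).normal(size=(1, 16)), (2, 1)) * 2
        x = Q[0:1] / np.linalg.norm(Q[0])
        theta = np.full(2, 0.3)
        free = encode_patches(x, Q, np.zeros((2, 2)), theta, 50, 0.2).sum()
        W = np.array([[0.0, 5.0], [5.0, 0.0]])
        inhibited = encode_patches(x, Q, W, theta, 50, 0.2).sum()
        assert inhibited < free

    def test_threshold_monotonicity(self):
        # raising every threshold never increases any count (W = 0)
        rng = np.random.default_rng(8)
        Q = rng.normal(size=(6, 9))
        X = rng.normal(size=(20, 9))
        W = np.zeros((6, 6))
        base = encode_patches(X, Q, W, np.full(6, 0.5), 50, 0.2)
        higher = encode_patches(X, Q, W, np.full(6, 1.0), 50, 0.2)
        assert np.all(higher <= base)

    def test_counts_are_nonnegative_integers(self):
        rng = np.random.default_rng(9)
        counts = encode_patches(
            rng.normal(size=(10, 4)), rng.normal(size=(3, 4)),
            np.zeros((3, 3)), np.ones(3), 30, 0.2,
        )
        assert counts.dtype.kind == "i" and counts.min() >= 0

    def test_rejects_bad_T(self):
        with pytest.raises(ValueError):
            encode_patches(np.zeros((1, 4)), np.zeros((2, 4)),
                           np.zeros((2, 2)), np.ones(2), 0, 0.2)


class TestTraining:
    def test_determinism(self):
        patches = np.random.default_rng(10).normal(size=(2000, 25))
        cfg = TrainingConfig(n_neurons=8, patch_side=5, n_epochs=2, seed=3)
        r1 = SparseCodingModel(patches, cfg).fit()
        r2 = SparseCodingModel(patches, cfg).fit()
        assert np.array_equal(r1.receptive_fields.Q, r2.receptive_fields.Q)
        assert np.array_equal(r1.receptive_fields.theta, r2.receptive_fields.theta)

    def test_divergence_guard(self):
        patches = np.random.default_rng(11).normal(size=(1000, 16))
        cfg = TrainingConfig(n_neurons=4, patch_side=4, n_epochs=1, seed=0,
                             q_bound=1e-6)
        with pytest.raises(RuntimeError, match="diverged"):
            SparseCodingModel(patches, cfg).fit()

    def test_summary_mentions_key_quantities(self, dict_fit):
        results, _ = dict_fit
        text = results.summary()
        assert "neurons" in text and "recon error" in text

    def test_rate_homeostasis(self, dict_fit):
        results, _ = dict_fit
        p = results.receptive_fields.config.target_rate
        assert abs(results.final_rate - p) / p < 0.25

    def test_reconstruction_error_decreases(self, dict_fit):
        results, _ = dict_fit
        assert results.final_recon_error < results.recon_error_per_epoch[0]

    def test_save_load_roundtrip(self, tmp_path, dict_fit):
        rf = dict_fit[0].receptive_fields
        path = tmp_path / "rf.npz"
        rf.save(path)
        rf2 = ReceptiveFieldSet.load(path)
        assert np.array_equal(rf.Q, rf2.Q)
        assert np.array_equal(rf.W, rf2.W)
        assert rf2.config.patch_side == rf.config.patch_side
        assert rf2.gain == rf.gain


class TestResponseMap:
    def test_constant_channel_uniform_responses(self, trained_rf):
        rm = compute_response_map(np.full((24, 24), 0.5), trained_rf, stride=1)
        assert rm.shape == (24, 24, 128)
        # translation invariance on constant input: one response everywhere
        assert np.all(rm == rm[0, 0])

    def test_output_dims_default_config(self, trained_rf):
        rm = compute_response_map(np.random.default_rng(12).uniform(size=(20, 26)),
                                  trained_rf, stride=2)
        assert rm.shape == (10, 13, 128)

    def test_flip_equivariance_symmetric_rf(self):
        # a single left-right symmetric RF: flipping the image flips the map
        side = 5
        field = np.zeros((side, side))
        field[:, 2] = 1.0  # vertical bar, symmetric under lr-flip
        rf = _toy_rf(field.ravel()[None, :] * 2, theta=np.array([0.1]))
        img = np.random.default_rng(13).uniform(size=(12, 12))
        rm = compute_response_map(img, rf)[:, :, 0]
        rm_flipped = compute_response_map(img[:, ::-1], rf)[:, :, 0]
        assert np.array_equal(rm_flipped, rm[:, ::-1])


class TestReconstruct:
    def test_zero_responses_give_mean_patch(self, trained_rf):
        out = reconstruct_patches(np.zeros(trained_rf.n_neurons), trained_rf)
        assert np.allclose(out[0], trained_rf.mean, atol=1e-9)

    def test_orthonormal_identity_limit(self):
        # Q orthonormal, identity whitener, unit gain: responses equal to the
        # patch coefficients reconstruct the patch exactly
        rng = np.random.default_rng(14)
        Q, _ = np.linalg.qr(rng.normal(size=(9, 9)))
        rf = _toy_rf(Q)
        coeffs = rng.integers(0, 5, size=9).astype(float)
        patch = coeffs @ Q
        assert np.allclose(reconstruct_patches(coeffs, rf)[0], patch, atol=1e-10)

    def test_mismatched_K_rejected(self, trained_rf):
        with pytest.raises(ValueError):
            reconstruct_patches(np.zeros(7), trained_rf)

    def test_image_reconstruction_error_below_half(self, trained_rf):
        # overlap-averaged whole-image reconstruction of a held-out
        # natural-statistics image
        from v1sal.fixtures import make_pink_noise_images

        img = make_pink_noise_images(1, 64, seed=99)[0]
        rm = compute_response_map(img, trained_rf, stride=1)
        err = (np.linalg.norm(reconstruct_image(rm, trained_rf) - img)
               / np.linalg.norm(img))
        assert err < 0.5

    def test_trained_beats_rate_matched_random_network(self, dict_fit):
        # trained vs untrained network at the same spike budget, whole-image
        # reconstruction of a mosaic of held-out dictionary patches
        from v1sal.fixtures import make_sparse_patch_set
        from v1sal.sparse_net import _extract_patch_grid, calibrate_thresholds

        results, _ = dict_fit
        rf = results.receptive_fields
        cfg = rf.config
        held_out, _ = make_sparse_patch_set(
            n_patches=36, n_atoms=64, side=10, sparsity=4,
            noise_sigma=0.02, seed=6,
        )
        img = held_out.reshape(6, 6, 10, 10).transpose(0, 2, 1, 3).reshape(60, 60)

        def image_error(rfset):
            rm = compute_response_map(img, rfset, stride=1)
            recon = reconstruct_image(rm, rfset)
            return np.linalg.norm(recon - img) / np.linalg.norm(img)

        err_trained = image_error(rf)

        rng = np.random.default_rng(15)
        Q = rng.standard_normal(rf.Q.shape)
        Q /= np.linalg.norm(Q, axis=1, keepdims=True)
        grid_patches, _, _ = _extract_patch_grid(img, cfg.patch_side, 1)
        X = apply_whitener(grid_patches, rf.whitener, rf.mean)
        theta = calibrate_thresholds(
            Q, rf.W * 0, X[:400], cfg.target_rate, cfg.lif_steps, cfg.lif_leak
        )
        random_rf = ReceptiveFieldSet(
            Q=Q, W=rf.W * 0, theta=theta,
            whitener=rf.whitener, mean=rf.mean, config=cfg, gain=1.0,
        )
        # refit the random network's reconstruction gain on its own codes
        rm_r = compute_response_map(img, random_rf, stride=1)
        counts = rm_r.reshape(-1, rf.n_neurons).astype(float)
        recon_w = counts @ Q
        den = (recon_w * recon_w).sum()
        if den > 0:
            random_rf.gain = float((recon_w * X).sum() / den)
        err_random = image_error(random_rf)

        assert err_trained < err_random
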