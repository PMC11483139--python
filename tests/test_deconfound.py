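import numpy as np
import pytest
from scipy import stats

from xvaekit.confound import apply_effects, categorical_effect, linear_effect, \
    draw_numeric_confounder
from xvaekit.deconfound import (AdversaryConfig, CrPenaltySpec, FsCriterion,
                                build_cxvae, cr_penalty, cross_entropy,
                                encode_confounders, filter_latent_features,
                                lr_pca_baseline, train_adv_xvae, train_cr_xvae)
from xvaekit.metrics import ari
from xvaekit.nn import Tensor
from xvaekit.xvae import build_xvae, train_xvae
from sklearn.cluster import KMeans


class TestEncodeConfounders:
    def test_onehot_rows_sum_to_one(self):
        c = np.array([1, 2, 3, 4, 5, 6, 1, 2, 3, 4])
        enc = encode_confounders([c], ["onehot"])
        assert enc.matrix.shape == (10, 6)
        np.testing.assert_allclose(enc.matrix.sum(axis=1), 1.0)

    def test_numeric_standardized(self):
        c = np.array([0, 1, 2, 3, 4, 5])
        enc = encode_confounders([c], ["standardized_scalar"])
        assert abs(enc.matrix.mean()) < 1e-9
        assert abs(enc.matrix.std() - 1) < 1e-9

    def test_mixed_width(self):
        num = np.arange(12) % 6
        cat = np.arange(12) % 6 + 1
        enc = encode_confounders([num, cat], ["standardized_scalar", "onehot"])
        assert enc.m == 1 + 6

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            encode_confounders([np.ones(4)], ["frequency"])


class TestCxvae:
    def test_conditioning_block_shapes(self, tiny_cfg):
        enc = encode_confounders([np.arange(12) % 6 + 1], ["onehot"])
        model = build_cxvae(50, 50, tiny_cfg, enc, level="input_embed")
        assert model.enc1.W_extra.data.shape == (6, tiny_cfg.view_hidden)
        assert model.enc2.W_extra.data.shape == (6, tiny_cfg.view_hidden)
        assert model.dec_fuse.W_extra.data.shape == (6, tiny_cfg.fused_hidden)
        assert model.fuse.W_extra is None

    @pytest.mark.parametrize("level,layers", [
        ("input", ["enc1", "enc2"]),
        ("fused", ["fuse"]),
        ("embed", ["dec_fuse"]),
    ])
    def test_levels_attach_where_stated(self, tiny_cfg, level, layers):
        enc = encode_confounders([np.arange(12) % 6 + 1], ["onehot"])
        model = build_cxvae(8, 8, tiny_cfg, enc, level=level)
        for name in layers:
            assert getattr(model, name).W_extra is not None

    def test_invalid_level_rejected(self, tiny_cfg):
        enc = encode_confounders([np.arange(12) % 6 + 1], ["onehot"])
        with pytest.raises(ValueError):
            build_cxvae(8, 8, tiny_cfg, enc, level="everywhere")

    def test_zeroed_conditioning_equals_vanilla_trajectory(
            self, small_dataset, tiny_cfg):
        enc = encode_confounders([np.zeros(150)], ["standardized_scalar"])
        assert np.all(enc.matrix == 0)
        vanilla = build_xvae(12, 12, tiny_cfg)
        _, h_v = train_xvae(vanilla, small_dataset, tiny_cfg)
        cond = build_cxvae(12, 12, tiny_cfg, enc)
        _, h_c = train_xvae(cond, small_dataset, tiny_cfg,
                            conditioning=enc.matrix)
        assert h_v["train_loss"] == h_c["train_loss"]
        assert h_v["val_loss"] == h_c["val_loss"]

    def test_missing_conditioning_rejected(self, small_dataset, tiny_cfg):
        enc = encode_confounders([np.zeros(150)], ["standardized_scalar"])
        model = build_cxvae(12, 12, tiny_cfg, enc)
        with pytest.raises(ValueError):
            train_xvae(model, small_dataset, tiny_cfg)


class TestAdversary:
    def test_cross_entropy_uniform_logits(self):
        logits = Tensor(np.zeros((4, 3)))
        ce = cross_entropy(logits, np.array([0, 1, 2, 0]))
        assert ce.item() == pytest.approx(np.log(3))

    def test_lambda_zero_equals_vanilla(self, small_dataset, tiny_cfg):
        vanilla = build_xvae(12, 12, tiny_cfg)
        _, h_v = train_xvae(vanilla, small_dataset, tiny_cfg)
        classes = [np.arange(150) % 6]
        adv_cfg = AdversaryConfig(lambda_adv=0.0, pretrain_epochs=2)
        _, h_a, _ = train_adv_xvae(small_dataset, tiny_cfg, adv_cfg, classes)
        assert h_v["train_loss"] == h_a["train_loss"]
        assert h_v["val_loss"] == h_a["val_loss"]

    def test_continuous_confounder_rejected(self, small_dataset, tiny_cfg):
        with pytest.raises(ValueError, match="discret"):
            train_adv_xvae(small_dataset, tiny_cfg, AdversaryConfig(),
                           [np.random.default_rng(0).normal(size=150)])

    def test_adversary_beats_chance_on_confounded_data(self, tiny_cfg):
        from xvaekit.data import generate_paired_omics, rescale_dataset
        base = rescale_dataset(generate_paired_omics(150, 12, 12, 3, 2.0, 0))
        eff = categorical_effect((150, 12, 12), seed=1)
        conf = apply_effects(base, [eff])
        cfg = tiny_cfg
        cfg.epochs = 20
        adv_cfg = AdversaryConfig(lambda_adv=0.1, pretrain_epochs=4,
                                  learning_rate=1e-2)
        model, _, advs = train_adv_xvae(conf, cfg, adv_cfg,
                                        [eff.confounder_label - 1])
        from xvaekit.xvae import encode
        emb = encode(model, conf.confounded1, conf.confounded2).mean
        logits = advs[0](emb).data
        acc = np.mean(np.argmax(logits, axis=1) == eff.confounder_label - 1)
        assert acc > 1 / 6

    def test_sequential_variant_one_adversary_per_confounder(
            self, small_dataset, tiny_cfg):
        classes = [np.arange(150) % 6, np.arange(150) % 4]
        _, _, advs = train_adv_xvae(small_dataset, tiny_cfg,
                                    AdversaryConfig(pretrain_epochs=1),
                                    classes, variant="sequential")
        assert len(advs) == 2


class TestCrPenalty:
    def test_copied_dim_has_unit_sq_corr(self):
        rng = np.random.default_rng(0)
        c = rng.integers(0, 6, 100).astype(float)
        z = rng.normal(size=(100, 4))
        z[:, 0] = c
        spec = CrPenaltySpec(method="sq_corr", lambda_cr=1.0)
        # the copied dim contributes r^2 = 1; others are near zero
        val = cr_penalty(z, c, spec).item()
        assert val >= 1 / 4 - 1e-6
        only = cr_penalty(z[:, :1], c, spec).item()
        assert only == pytest.approx(1.0, abs=1e-9)

    def test_null_abs_corr_small(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=(1000, 8))
        c = rng.integers(0, 6, 1000).astype(float)
        val = cr_penalty(z, c, CrPenaltySpec(method="abs_corr")).item()
        assert val < 0.1

    def test_sq_below_abs(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=(50, 6))
        c = rng.integers(0, 6, 50).astype(float)
        sq = cr_penalty(z, c, CrPenaltySpec(method="sq_corr")).item()
        ab = cr_penalty(z, c, CrPenaltySpec(method="abs_corr")).item()
        assert sq <= ab + 1e-12

    def test_constant_confounder_contributes_zero(self):
        z = np.random.default_rng(3).normal(size=(20, 3))
        val = cr_penalty(z, np.full(20, 2.0), CrPenaltySpec()).item()
        assert val == 0.0

    @pytest.mark.parametrize("method", ["mi_histogram", "mi_kde"])
    def test_mi_detects_dependence(self, method):
        rng = np.random.default_rng(4)
        c = rng.integers(0, 3, 300).astype(float)
        z_dep = (c * 2.0 + rng.normal(scale=0.3, size=300))[:, None]
        z_ind = rng.normal(size=(300, 1))
        spec = CrPenaltySpec(method=method)
        assert cr_penalty(z_dep, c, spec).item() > cr_penalty(z_ind, c, spec).item()

    @pytest.mark.parametrize("method", ["abs_corr", "sq_corr",
                                        "mi_histogram", "mi_kde"])
    def test_penalty_nonnegative_and_differentiable(self, method):
        rng = np.random.default_rng(5)
        z = Tensor(rng.normal(size=(40, 3)), requires_grad=True)
        c = rng.integers(0, 6, 40).astype(float)
        val = cr_penalty(z, c, CrPenaltySpec(method=method))
        assert val.item() >= 0
        val.backward()
        assert np.all(np.isfinite(z.grad))

    def test_invalid_method_rejected(self):
        with pytest.raises(ValueError):
            CrPenaltySpec(method="spearman")


class TestTrainCr:
    def test_lambda_zero_equals_vanilla(self, small_dataset, tiny_cfg):
        vanilla = build_xvae(12, 12, tiny_cfg)
        _, h_v = train_xvae(vanilla, small_dataset, tiny_cfg)
        spec = CrPenaltySpec(method="sq_corr", lambda_cr=0.0)
        _, h_c = train_cr_xvae(small_dataset, tiny_cfg, spec,
                               np.arange(150) % 6)
        assert h_v["train_loss"] == h_c["train_loss"]

    def test_penalty_log_nonnegative(self, small_dataset, tiny_cfg):
        spec = CrPenaltySpec(method="sq_corr", lambda_cr=1.0)
        _, hist = train_cr_xvae(small_dataset, tiny_cfg, spec,
                                np.arange(150) % 6)
        assert len(hist["cr_penalty"]) > 0
        assert np.all(np.asarray(hist["cr_penalty"]) >= 0)

    def test_reduces_latent_confounder_correlation(self):
        from xvaekit.data import generate_paired_omics, rescale_dataset
        from xvaekit.xvae import XvaeConfig, encode

        deltas = []
        for seed in range(10):
            base = rescale_dataset(generate_paired_omics(120, 10, 10, 3, 2.0, seed))
            c = draw_numeric_confounder(120, seed=seed + 10)
            eff = linear_effect((120, 10, 10), c, seed=seed + 20)
            conf = apply_effects(base, [eff])
            cfg = XvaeConfig(view_hidden=16, fused_hidden=16, latent_dim=4,
                             epochs=12, batch_size=32, learning_rate=3e-3,
                             seed=seed)
            vanilla = build_xvae(10, 10, cfg)
            vanilla, _ = train_xvae(vanilla, conf, cfg)
            spec = CrPenaltySpec(method="sq_corr", lambda_cr=5.0)
            reg, _ = train_cr_xvae(conf, cfg, spec, c.values)

            def mean_abs_r(model):
                z = encode(model, conf.confounded1, conf.confounded2).mean
                rs = [abs(stats.pearsonr(z[:, j], c.values)[0])
                      if z[:, j].std() > 0 else 0.0
                      for j in range(z.shape[1])]
                return np.mean(rs)

            deltas.append(mean_abs_r(vanilla) - mean_abs_r(reg))
        assert np.mean(deltas) > 0


class TestFeatureSelection:
    def _orthonormal_pair(self, n, seed):
        rng = np.random.default_rng(seed)
        c = rng.integers(0, 6, n).astype(float)
        u = c - c.mean()
        u /= np.linalg.norm(u)
        v = rng.normal(size=n)
        v -= v.mean()
        v -= (v @ u) * u
        v /= np.linalg.norm(v)
        return c, u, v

    def test_copy_of_confounder_removed_by_all_criteria(self):
        rng = np.random.default_rng(0)
        c = rng.integers(0, 6, 100).astype(float)
        z = rng.normal(size=(100, 5))
        z[:, 2] = c
        for crit in (FsCriterion("pvalue", 0.05), FsCriterion("abs_corr", 0.3),
                     FsCriterion("abs_corr", 0.5)):
            kept = filter_latent_features(z, [c], crit)
            assert 2 not in kept

    def test_threshold_semantics_at_r_04(self):
        c, u, v = self._orthonormal_pair(500, 1)
        dim = 0.4 * u + np.sqrt(1 - 0.16) * v  # exact r = 0.4 with c
        z = np.column_stack([dim, v])
        kept03 = filter_latent_features(z, [c], FsCriterion("abs_corr", 0.3))
        kept05 = filter_latent_features(z, [c], FsCriterion("abs_corr", 0.5))
        assert 0 not in kept03
        assert 0 in kept05

    def test_null_calibration_pvalue(self):
        removals = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            z = rng.normal(size=(2000, 20))
            c = rng.integers(0, 6, 2000).astype(float)
            kept = filter_latent_features(z, [c], FsCriterion("pvalue", 0.05))
            removals.append(20 - len(kept))
        mean_removed = np.mean(removals)
        # binomial(20, 0.05) oracle: mean 1, sd of the mean over 200 trials
        sd = np.sqrt(20 * 0.05 * 0.95 / 200)
        assert abs(mean_removed - 1.0) < 3 * sd

    def test_all_removed_fallback_keeps_least_confounded(self):
        c, u, v = self._orthonormal_pair(300, 2)
        z = np.column_stack([0.9 * u + np.sqrt(1 - 0.81) * v,
                             0.7 * u + np.sqrt(1 - 0.49) * v])
        with pytest.warns(UserWarning, match="retaining"):
            kept = filter_latent_features(z, [c], FsCriterion("abs_corr", 0.5))
        np.testing.assert_array_equal(kept, [1])

    def test_any_confounder_rule(self):
        c1, u1, v1 = self._orthonormal_pair(400, 3)
        rng = np.random.default_rng(4)
        c2 = rng.integers(0, 6, 400).astype(float)
        z = np.column_stack([u1 * 0.9 + v1 * np.sqrt(1 - 0.81), v1])
        kept = filter_latent_features(z, [c2, c1], FsCriterion("abs_corr", 0.5))
        assert 0 not in kept


class TestLrPca:
    def test_pure_linear_confounding_residual_zero(self):
        c = draw_numeric_confounder(40, seed=0)
        eff = linear_effect((40, 6, 7), c, seed=1)
        labels, emb = lr_pca_baseline(eff.E1, eff.E2, [c.values], ["numeric"],
                                      n_pcs=5, k=2, seed=0)
        # residual of a noiseless linear system is numerically zero, so the
        # PCA embedding collapses
        assert np.abs(emb).max() < 1e-6

    def test_orthogonal_confounder_preserves_clustering(self):
        from xvaekit.data import generate_paired_omics
        ds = generate_paired_omics(300, 20, 20, 3, signal=4.0, seed=5)
        rng = np.random.default_rng(6)
        c = rng.integers(0, 6, 300)
        lab_adj, _ = lr_pca_baseline(ds.view1.values, ds.view2.values,
                                     [c], ["numeric"], n_pcs=10, k=3, seed=0)
        km = KMeans(3, n_init=10, random_state=0).fit_predict(
            np.hstack([ds.view1.values, ds.view2.values]))
        assert abs(ari(lab_adj, ds.true_labels) - ari(km, ds.true_labels)) < 0.05

    def test_full_rank_pca_preserves_distances(self):
        rng = np.random.default_rng(7)
        x1 = rng.normal(size=(25, 4))
        x2 = rng.normal(size=(25, 3))
        c = rng.integers(0, 6, 25)
        _, emb = lr_pca_baseline(x1, x2, [c], ["numeric"], n_pcs=50, k=2, seed=0)
        design = np.column_stack([np.ones(25), c])
        X = np.hstack([x1, x2])
        resid = X - design @ np.linalg.lstsq(design, X, rcond=None)[0]
        from scipy.spatial.distance import pdist
        np.testing.assert_allclose(pdist(emb), pdist(resid), atol=1e-6)

    def test_collinear_design_warns(self):
        rng = np.random.default_rng(8)
        x1 = rng.normal(size=(30, 3))
        x2 = rng.normal(size=(30, 3))
        c = rng.integers(0, 3, 30)
        with pytest.warns(UserWarning, match="collinear"):
            lr_pca_baseline(x1, x2, [c, c], ["numeric", "numeric"],
                            n_pcs=4, k=2, seed=0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            lr_pca_baseline(np.ones((3, 2)), np.ones((3, 2)),
                            [np.array([1, 2, 3]), np.array([1, 0, 1]),
                             np.array([0, 1, 0])],
                            ["numeric"] * 3, n_pcs=2, k=2, seed=0)
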