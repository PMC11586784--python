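import numpy as np
import pytest

from pertstream import (
    DualStreamModel,
    ModelConfig,
    build_attention_mask,
    build_coexpression_graph,
    build_perturbation_graph,
    regenerate_nonzero,
)
from pertstream.graphs import AttentionMask
from pertstream.nn import Tensor


@pytest.fixture(scope="module")
def small_model(request):
    names = [f"G{i:02d}" for i in range(20)]
    config = ModelConfig(hidden_dim=16, vae_latent_dim=4, vae_intermediate_dim=8,
                         ff_dim=32, n_attention_heads=2)
    return DualStreamModel(names, names, config, seed=0)


@pytest.fixture
def default_model(tiny_dataset, tiny_annotations):
    g_gene = build_coexpression_graph(tiny_dataset, threshold=0.3)
    g_pert = build_perturbation_graph(
        tiny_annotations.go_sets, tiny_dataset.gene_names, h_pert=5
    )
    mask = build_attention_mask(
        tiny_dataset.gene_names, tiny_annotations.hierarchy, tiny_dataset
    )
    config = ModelConfig(hidden_dim=16, vae_latent_dim=4, vae_intermediate_dim=8,
                         ff_dim=32, n_attention_heads=2)
    return DualStreamModel(tiny_dataset.gene_names, tiny_dataset.gene_names, config,
                           gene_graph=g_gene, pert_graph=g_pert, mask=mask, seed=1)


class TestModelConfig:
    def test_defaults_follow_reference_setup(self):
        c = ModelConfig()
        assert (c.hidden_dim, c.vae_latent_dim, c.vae_intermediate_dim, c.ff_dim) == (
            64, 16, 32, 512
        )
        assert c.n_gnn_layers_gene == c.n_gnn_layers_pert == 1

    def test_heads_must_divide_dim(self):
        with pytest.raises(ValueError):
            ModelConfig(hidden_dim=64, n_attention_heads=5)


class TestVAE:
    def test_encode_shapes_and_determinism(self, small_model, rng):
        x = rng.uniform(1, 5, size=(3, 20))
        mu, sigma = small_model.vae_encode(x)
        mu2, sigma2 = small_model.vae_encode(x)
        assert mu.shape == sigma.shape == (3, 4)
        assert np.array_equal(mu.data, mu2.data)
        assert (sigma.data > 0).all()

    def test_default_latent_dimension_is_16(self):
        m = DualStreamModel(["g"] * 0 or [f"g{i}" for i in range(30)],
                            [f"g{i}" for i in range(30)], ModelConfig(), seed=0)
        mu, sigma = m.vae_encode(np.ones((1, 30)))
        assert mu.shape == (1, 16)

    def test_zeroed_heads_give_standard_normal_posterior(self, small_model, rng):
        small_model.enc_mu.weight.data[:] = 0
        small_model.enc_mu.bias.data[:] = 0
        small_model.enc_logvar.weight.data[:] = 0
        small_model.enc_logvar.bias.data[:] = 0
        mu, sigma = small_model.vae_encode(rng.uniform(0, 3, size=(2, 20)))
        np.testing.assert_array_equal(mu.data, 0.0)
        np.testing.assert_array_equal(sigma.data, 1.0)

    def test_nan_input_rejected(self, small_model):
        x = np.ones((1, 20))
        x[0, 3] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            small_model.vae_encode(x)

    def test_reparameterize_eval_mode_returns_mean(self):
        mu = Tensor(np.array([[1.0, 2.0]]))
        sigma = Tensor(np.array([[3.0, 4.0]]))
        z = DualStreamModel.reparameterize(mu, sigma, training=False)
        np.testing.assert_array_equal(z.data, mu.data)

    def test_reparameterize_seeded_and_calibrated(self):
        mu = Tensor(np.zeros((100_000, 1)))
        sigma = Tensor(np.ones((100_000, 1)))
        z1 = DualStreamModel.reparameterize(mu, sigma, np.random.default_rng(7))
        z2 = DualStreamModel.reparameterize(mu, sigma, np.random.default_rng(7))
        assert np.array_equal(z1.data, z2.data)
        assert abs(z1.data.mean()) < 0.02


class TestRegenerateNonzero:
    @pytest.mark.parametrize("x,x_hat,expected", [
        ([0.0, 0.0], [9.0, 9.0], [0.0, 0.0]),
        ([1.0, 2.0], [3.0, 4.0], [3.0, 4.0]),
        ([0.0, 2.0, 0.0, 5.0], [9.0, 3.0, 9.0, 4.0], [0.0, 3.0, 0.0, 4.0]),
    ])
    def test_positional_rule(self, x, x_hat, expected):
        out = regenerate_nonzero(np.array(x), np.array(x_hat))
        np.testing.assert_array_equal(out, expected)

    def test_zeros_are_bit_exact_through_tensors(self, rng):
        x = rng.uniform(0, 3, size=(4, 7))
        x[rng.random(x.shape) < 0.5] = 0.0
        out = regenerate_nonzero(x, Tensor(rng.normal(size=(4, 7))))
        assert np.all(out.data[x == 0] == 0.0)


class TestCombineAndCollapse:
    def test_control_cell_passes_through(self, small_model):
        gene_emb = small_model.sgc_propagate(
            small_model.gene_embedding, small_model.gene_adj, 1, small_model.gene_linear
        )
        out = small_model.combine_perturbation(gene_emb, [frozenset()])
        np.testing.assert_allclose(out.data[0], gene_emb.data, atol=1e-12)

    def test_two_gene_perturbation_adds_both_embeddings(self, small_model):
        gene_emb = small_model.sgc_propagate(
            small_model.gene_embedding, small_model.gene_adj, 1, small_model.gene_linear
        )
        pert_prop = small_model.sgc_propagate(
            small_model.pert_embedding, small_model.pert_adj, 1, small_model.pert_linear
        )
        p, q = small_model.pert_names[2], small_model.pert_names[7]
        out = small_model.combine_perturbation(gene_emb, [frozenset({p, q})])
        delta = out.data[0] - gene_emb.data
        expected = pert_prop.data[2] + pert_prop.data[7]
        np.testing.assert_allclose(delta, np.tile(expected, (20, 1)), atol=1e-12)

    def test_unknown_perturbation_rejected(self, small_model):
        gene_emb = Tensor(np.zeros((20, 16)))
        with pytest.raises(KeyError):
            small_model.combine_perturbation(gene_emb, [frozenset({"NOPE"})])

    def test_collapse_sums_feature_axis_and_adds(self):
        post = Tensor(np.array([[[1.5, -0.5]]]))
        regenerated = np.array([[2.0]])
        out = DualStreamModel.collapse_and_fuse(post, regenerated)
        assert out.data[0, 0] == pytest.approx(3.0)

    def test_collapse_is_linear_in_post_embedding(self, rng):
        post = rng.normal(size=(2, 5, 3))
        reg = rng.uniform(1, 2, size=(2, 5))
        d1 = DualStreamModel.collapse_and_fuse(Tensor(post), reg).data - reg
        d2 = DualStreamModel.collapse_and_fuse(Tensor(2 * post), reg).data - reg
        np.testing.assert_allclose(d2, 2 * d1, atol=1e-12)


class TestMaskedAttention:
    def test_permissive_mask_matches_no_mask_bitwise(self, small_model, rng):
        layer = small_model.transformer_layers[0]
        x = Tensor(rng.normal(size=(2, 20, 16)))
        with_zeros = layer(x, np.zeros((20, 20)))
        without = layer(x, None)
        assert np.array_equal(with_zeros.data, without.data)

    def test_diagonal_only_mask_gives_one_hot_weights(self, small_model, rng):
        from pertstream.graphs import MASK_NEG
        mask = np.full((20, 20), MASK_NEG)
        np.fill_diagonal(mask, 0.0)
        attn = small_model.transformer_layers[0].attn
        x = small_model.transformer_layers[0].norm1(Tensor(rng.normal(size=(1, 20, 16))))
        weights = attn.attention_weights(x, mask)
        np.testing.assert_array_equal(weights, np.broadcast_to(np.eye(20), weights.shape))

    def test_hand_computed_softmax_oracle(self, rng):
        from pertstream.nn import MultiheadSelfAttention
        mha = MultiheadSelfAttention(2, 1, rng)
        # identity projections: Q = K = V = x
        for lin in (mha.wq, mha.wk, mha.wv, mha.wo):
            lin.weight.data = np.eye(2)
            lin.bias.data[:] = 0
        x = np.array([[[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]])
        mask = np.zeros((3, 3))
        mask[0, 1] = mask[1, 0] = -1e9
        scores = (x[0] @ x[0].T) / np.sqrt(2) + mask
        expected = np.exp(scores - scores.max(axis=1, keepdims=True))
        expected /= expected.sum(axis=1, keepdims=True)
        weights = mha.attention_weights(Tensor(x), mask)
        np.testing.assert_allclose(weights[0, 0], expected, atol=1e-12)
        out = mha(Tensor(x), mask)
        np.testing.assert_allclose(out.data[0], expected @ x[0], atol=1e-12)

    def test_masked_attention_mass_is_negligible(self, default_model, rng):
        forbidden = default_model.mask.matrix != 0.0
        if not forbidden.any():
            pytest.skip("fixture mask has no forbidden pairs")
        layer = default_model.transformer_layers[0]
        x = layer.norm1(Tensor(rng.normal(size=(2, 20, 16))))
        weights = layer.attn.attention_weights(x, default_model.mask.matrix)
        assert weights[:, :, forbidden].max() < 1e-20


class TestForward:
    def test_degenerate_ablation_is_identity(self, tiny_dataset):
        config = ModelConfig(hidden_dim=16, vae_latent_dim=4, vae_intermediate_dim=8,
                             ff_dim=32, n_attention_heads=2,
                             use_vae=False, use_attention=False)
        model = DualStreamModel(tiny_dataset.gene_names, tiny_dataset.gene_names,
                                config, seed=0)
        model.gene_embedding.data[:] = 0
        model.pert_embedding.data[:] = 0
        for lin in (model.gene_linear, model.pert_linear):
            lin.weight.data[:] = 0
            lin.bias.data[:] = 0
        x = tiny_dataset.expression[:5]
        pred, mu, sigma = model.forward(x, [frozenset()] * 5)
        np.testing.assert_array_equal(pred.data, x)
        assert mu is None and sigma is None

    def test_vae_stream_preserves_zeros(self, default_model, tiny_dataset):
        x = tiny_dataset.expression[:6]
        mu, sigma = default_model.vae_encode(x)
        z = default_model.reparameterize(mu, sigma, training=False)
        reg = regenerate_nonzero(x, default_model.vae_decode(z))
        assert np.all(reg.data[x == 0] == 0.0)

    def test_eval_mode_is_deterministic(self, default_model, tiny_dataset):
        x = tiny_dataset.expression[:4]
        perts = [frozenset({default_model.gene_names[0]})] * 4
        p1 = default_model.predict(x, perts)
        p2 = default_model.predict(x, perts)
        assert np.array_equal(p1, p2)

    def test_mask_off_equals_permissive_mask(self, default_model, tiny_dataset):
        import copy

        x = tiny_dataset.expression[:3]
        perts = [frozenset()] * 3
        permissive = copy.deepcopy(default_model)
        permissive.mask = AttentionMask(
            matrix=np.zeros_like(default_model.mask.matrix),
            gene_names=default_model.gene_names,
        )
        masked_off = copy.deepcopy(default_model)
        masked_off.config = ModelConfig(
            hidden_dim=16, vae_latent_dim=4, vae_intermediate_dim=8, ff_dim=32,
            n_attention_heads=2, use_mask=False,
        )
        np.testing.assert_array_equal(
            permissive.predict(x, perts), masked_off.predict(x, perts)
        )

    def test_every_parameter_group_receives_gradient(self, default_model, rng):
        x = rng.uniform(0.5, 4.0, size=(6, 20))  # dense: no zero columns
        perts = [frozenset({default_model.gene_names[i]}) for i in range(6)]
        pred, mu, sigma = default_model.forward(
            x, perts, training=True, rng=np.random.default_rng(0)
        )
        loss = (pred ** 2.0).mean() + (mu ** 2.0).mean() + (sigma ** 2.0).mean()
        loss.backward()
        for p in default_model.parameters():
            assert p.grad is not None
            assert np.any(p.grad != 0)


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, default_model, tiny_dataset, tmp_path):
        x = tiny_dataset.expression[:3]
        perts = [frozenset({default_model.gene_names[1]})] * 3
        before = default_model.predict(x, perts)
        path = tmp_path / "model.npz"
        default_model.save(path)
        loaded = DualStreamModel.load(path)
        np.testing.assert_array_equal(loaded.predict(x, perts), before)
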