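"""Architecture contracts: shapes, attention row-stochasticity, the
pseudo-fragment bookkeeping, permutation equivariance, determinism and the
dense single-head attention oracle."""

import numpy as np
import pytest

from badger._autodiff import Tensor
from badger.network import (Badger, ModelConfig, load_checkpoint,
                            pathway_association_scores, save_checkpoint)
from badger.nn import MultiheadAttention


def random_inputs(cfg, k=3, seed=0):
    rng = np.random.default_rng(seed)
    F = (rng.random((k, cfg.n_bits)) < 0.3).astype(float)
    sim = rng.uniform(-1, 1, cfg.n_anchors)
    return F, sim


class TestEncodersAndFusion:
    def test_molecule_encoder_shape(self, tiny_model):
        F, _ = random_inputs(tiny_model.config, k=3)
        out = tiny_model.encode_molecule(F)
        assert out.shape == (3, tiny_model.config.embed_dim)

    def test_cell_encoder_shape_and_dim_check(self, tiny_model):
        _, sim = random_inputs(tiny_model.config)
        assert tiny_model.encode_cell(sim).shape == \
            (tiny_model.config.embed_dim,)
        with pytest.raises(ValueError):
            tiny_model.encode_cell(sim[:-1])

    def test_zeroed_parameters_give_zero_embeddings(self, tiny_model_config):
        model = Badger(tiny_model_config)
        model.eval()
        state = {k: np.zeros_like(v) for k, v in model.state_dict().items()}
        model.load_state_dict(state)
        F, sim = random_inputs(model.config)
        assert not model.encode_molecule(F).numpy().any()
        assert not model.encode_cell(sim).numpy().any()

    def test_fusion_is_row_local(self, tiny_model):
        cfg = tiny_model.config
        F, sim = random_inputs(cfg, k=4)
        x_c = tiny_model.encode_cell(sim)
        x_m = tiny_model.encode_molecule(F).detach()
        fused = tiny_model.fuse_molecule_cell(x_m, x_c).numpy()
        bumped = x_m.numpy().copy()
        bumped[2] += 1.0
        fused2 = tiny_model.fuse_molecule_cell(Tensor(bumped), x_c).numpy()
        assert np.allclose(fused[[0, 1, 3]], fused2[[0, 1, 3]])
        assert not np.allclose(fused[2], fused2[2])

    def test_identical_fragment_rows_fuse_identically(self, tiny_model):
        cfg = tiny_model.config
        rng = np.random.default_rng(1)
        row = (rng.random(cfg.n_bits) < 0.3).astype(float)
        F = np.stack([row, row])
        _, sim = random_inputs(cfg)
        x_mc = tiny_model.fuse_molecule_cell(
            tiny_model.encode_molecule(F), tiny_model.encode_cell(sim))
        assert np.allclose(x_mc.numpy()[0], x_mc.numpy()[1])

    @pytest.mark.parametrize("k", [1, 7])
    def test_pseudo_fragment_is_appended_last(self, tiny_model, k):
        cfg = tiny_model.config
        F, sim = random_inputs(cfg, k=k)
        x_mc = tiny_model.fuse_molecule_cell(
            tiny_model.encode_molecule(F), tiny_model.encode_cell(sim))
        x_plus = tiny_model.append_pseudo_fragment(x_mc)
        assert x_plus.shape == (k + 1, cfg.embed_dim)
        assert np.array_equal(x_plus.numpy()[-1],
                              tiny_model.pseudo_fragment.numpy()[0])

    def test_pooled_fusion_uses_row_mean(self, tiny_model, rng):
        cfg = tiny_model.config
        x_mc = Tensor(rng.normal(size=(4, cfg.embed_dim)))
        x_g = Tensor(rng.normal(size=(cfg.n_genes, cfg.embed_dim)))
        pooled = x_mc.numpy().mean(axis=0)
        same = tiny_model.fuse_molecule_cell_gene(x_g, x_mc).numpy()
        again = tiny_model.fuse_molecule_cell_gene(
            x_g, Tensor(np.tile(pooled, (9, 1)))).numpy()
        assert np.allclose(same, again, atol=1e-9)


class TestAttentionBlocks:
    def test_ppab_attention_is_row_stochastic(self, tiny_model):
        cfg = tiny_model.config
        F, sim = random_inputs(cfg, k=3)
        out = tiny_model.predict(F, sim)
        A = out.attention
        assert A.shape == (cfg.n_pathways, 4)
        assert np.allclose(A.sum(axis=1), 1.0, atol=1e-6)
        assert (A >= 0).all()

    def test_association_scores_complement_pseudo_column(self, tiny_model):
        F, sim = random_inputs(tiny_model.config, k=3)
        out = tiny_model.predict(F, sim)
        assert np.allclose(out.association_scores,
                           1.0 - out.attention[:, -1], atol=1e-6)
        assert ((out.association_scores >= 0)
                & (out.association_scores <= 1)).all()

    def test_association_scores_equal_row_sum_oracle(self, rng):
        A = rng.random((5, 4))
        A /= A.sum(axis=1, keepdims=True)
        assert np.allclose(pathway_association_scores(A, 3),
                           A[:, :3].sum(axis=1), atol=1e-12)

    def test_uniform_rows_give_k_over_k_plus_one(self):
        A = np.full((2, 5), 0.2)
        assert np.allclose(pathway_association_scores(A, 4), 0.8)

    def test_single_head_matches_dense_softmax_oracle(self, rng):
        d = 4
        mha = MultiheadAttention(d, 1, np.random.default_rng(0))
        q_in = rng.normal(size=(2, d))
        kv_in = rng.normal(size=(3, d))
        out, A = mha(Tensor(q_in), Tensor(kv_in), Tensor(kv_in))
        # dense oracle
        q = q_in @ mha.wq.weight.data + mha.wq.bias.data
        k = kv_in @ mha.wk.weight.data + mha.wk.bias.data
        v = kv_in @ mha.wv.weight.data + mha.wv.bias.data
        scores = q @ k.T / np.sqrt(d)
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        attn = e / e.sum(axis=1, keepdims=True)
        expected = attn @ v @ mha.wo.weight.data + mha.wo.bias.data
        assert np.allclose(A.numpy(), attn, atol=1e-5)
        assert np.allclose(out.numpy(), expected, atol=1e-5)

    def test_ggab_is_permutation_equivariant(self, tiny_model, rng):
        cfg = tiny_model.config
        x = Tensor(rng.normal(size=(cfg.n_genes, cfg.embed_dim)))
        base, _ = tiny_model.ggab_forward(x)
        for _ in range(5):
            perm = rng.permutation(cfg.n_genes)
            permuted, _ = tiny_model.ggab_forward(Tensor(x.numpy()[perm]))
            assert np.allclose(permuted.numpy(), base.numpy()[perm],
                               atol=1e-9)

    def test_pgab_output_covers_all_genes(self, tiny_model, rng):
        cfg = tiny_model.config
        x_p = Tensor(rng.normal(size=(cfg.n_pathways, cfg.embed_dim)))
        x_g, A = tiny_model.pgab_forward(x_p)
        assert x_g.shape == (cfg.n_genes, cfg.embed_dim)
        assert np.allclose(A.numpy().sum(axis=1), 1.0, atol=1e-6)


class TestHeadsAndForward:
    def test_gene_head_locality(self, tiny_model, rng):
        cfg = tiny_model.config
        x = Tensor(rng.normal(size=(cfg.n_genes, cfg.embed_dim)))
        base = tiny_model.predict_gene_values(x).numpy()
        tiny_model.heads.w1.data[5] += 1.0
        bumped = tiny_model.predict_gene_values(x).numpy()
        changed = np.flatnonzero(~np.isclose(base, bumped))
        assert changed.tolist() == [5]

    def test_forward_outputs_are_finite_and_sized(self, tiny_model):
        cfg = tiny_model.config
        F, sim = random_inputs(cfg, k=2)
        out = tiny_model.predict(F, sim)
        assert out.predicted_profile.shape == (cfg.n_genes,)
        assert np.isfinite(out.predicted_profile).all()

    def test_eval_mode_is_deterministic(self, tiny_model):
        F, sim = random_inputs(tiny_model.config, k=3)
        a = tiny_model.predict(F, sim)
        b = tiny_model.predict(F, sim)
        assert np.array_equal(a.predicted_profile, b.predicted_profile)
        assert np.array_equal(a.attention, b.attention)

    def test_ablated_model_has_no_attention_readout(self, tiny_model_config):
        from dataclasses import replace
        model = Badger(replace(tiny_model_config, use_ppab=False))
        model.eval()
        F, sim = random_inputs(model.config, k=2)
        out = model.predict(F, sim)
        assert out.attention is None
        assert out.association_scores is None
        assert np.isfinite(out.predicted_profile).all()

    def test_same_seed_same_model(self, tiny_model_config):
        a, b = Badger(tiny_model_config), Badger(tiny_model_config)
        F, sim = random_inputs(tiny_model_config, k=2)
        assert np.array_equal(a.eval().predict(F, sim).predicted_profile,
                              b.eval().predict(F, sim).predicted_profile)

    def test_checkpoint_round_trip(self, tiny_model, tmp_path):
        F, sim = random_inputs(tiny_model.config, k=3)
        before = tiny_model.predict(F, sim)
        path = tmp_path / "model.npz"
        save_checkpoint(tiny_model, path)
        restored = load_checkpoint(path)
        after = restored.predict(F, sim)
        assert np.array_equal(before.predicted_profile,
                              after.predicted_profile)
        assert np.array_equal(before.attention, after.attention)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(embed_dim=10, n_heads=3)
        with pytest.raises(ValueError):
            ModelConfig(dropout=1.0)

    def test_smiles_to_prediction_pipeline(self, rng):
        import pandas as pd
        from badger.network import badger_forward
        cfg = ModelConfig(embed_dim=16, n_heads=2, mlp_hidden=32,
                          head_hidden=4, n_genes=12, n_pathways=4,
                          n_anchors=3, n_bits=128, seed=9)
        model = Badger(cfg).eval()
        genes = [f"G{i}" for i in range(25)]
        anchors = pd.DataFrame(rng.normal(size=(25, 3)), index=genes,
                               columns=["a", "b", "c"])
        out = badger_forward(model, "CC(=O)Oc1ccccc1C(=O)O", anchors["b"],
                             anchors)
        assert out.predicted_profile.shape == (12,)
        # aspirin has 4 BRICS fragments -> 5 attention columns
        assert out.attention.shape == (4, 5)
        assert np.allclose(out.attention.sum(axis=1), 1.0, atol=1e-6)
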