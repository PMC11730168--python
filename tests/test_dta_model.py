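import numpy as np
import pytest

from powerdta import _autodiff as ad
from powerdta.chem_graph import build_power_graph_set, smiles_to_graph
from powerdta.dta_model import DTANetwork, ModelConfig, gcn_layer


def featurize(smiles):
    g = smiles_to_graph(smiles)
    return g.node_features, build_power_graph_set(g).as_dict()


def protein_input(config, seed=0):
    rng = np.random.default_rng(seed)
    return rng.normal(size=(config.protein_rows, config.protein_channels))


class TestGcnLayer:
    def test_identity_propagation(self):
        h = np.random.default_rng(0).random((4, 3))
        out = gcn_layer(h, np.eye(4), np.eye(3))
        assert np.allclose(out, h)

    def test_scalar_case(self):
        out = gcn_layer([[2.0]], [[1.0]], [[3.0]])
        assert out.shape == (1, 1) and out[0, 0] == pytest.approx(6.0)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(1)
        a = rng.random((5, 5))
        a = (a + a.T) / 2
        h, w = rng.normal(size=(5, 3)), rng.normal(size=(3, 4))
        expected = np.zeros((5, 4))
        for i in range(5):
            for o in range(4):
                for j in range(5):
                    for m in range(3):
                        expected[i, o] += a[i, j] * h[j, m] * w[m, o]
        expected = np.maximum(expected, 0)
        assert np.allclose(gcn_layer(h, a, w), expected)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gcn_layer(np.zeros((3, 2)), np.eye(4), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            gcn_layer(np.zeros((3, 2)), np.eye(3), np.zeros((5, 2)))


class TestModelConfig:
    def test_block_depths_enforced(self):
        with pytest.raises(ValueError):
            ModelConfig(gcn_block_dims={1: (78,), 2: (156, 312), 3: (312,)})

    def test_dropout_and_power_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(dropout_rate=1.0)
        with pytest.raises(ValueError):
            ModelConfig(powers=())
        with pytest.raises(ValueError):
            ModelConfig(powers=(4,))

    def test_json_roundtrip(self, tiny_model_config):
        restored = ModelConfig.from_json(tiny_model_config.to_json())
        assert restored == tiny_model_config


class TestEncoders:
    def test_drug_vector_length_is_sum_of_final_widths(self, tiny_model_config):
        model = DTANetwork(tiny_model_config, seed=0)
        x, powers = featurize("CCOC(=O)c1ccccc1")
        vec = model.encode_drug(x, powers)
        assert vec.shape == (1, 8 + 8 + 8)

    def test_diameter_one_molecule_feeds_identical_adjacency(self):
        _, powers = featurize("CC")
        assert np.array_equal(powers[1], powers[2])
        assert np.array_equal(powers[2], powers[3])

    def test_protein_vector_length_is_last_filter_count(self, tiny_model_config):
        model = DTANetwork(tiny_model_config, seed=0)
        vec = model.encode_protein(protein_input(tiny_model_config))
        assert vec.shape == (1, tiny_model_config.protein_conv_filters[-1])

    def test_zero_protein_input_depends_only_on_biases(self, tiny_model_config):
        model = DTANetwork(tiny_model_config, seed=0)
        zeros = np.zeros((tiny_model_config.protein_rows,
                          tiny_model_config.protein_channels))
        a = model.encode_protein(zeros).data
        b = model.encode_protein(zeros.copy()).data
        assert np.array_equal(a, b)

    def test_protein_shape_mismatch_rejected(self, tiny_model_config):
        model = DTANetwork(tiny_model_config, seed=0)
        with pytest.raises(ValueError):
            model.encode_protein(np.zeros((5, 5)))

    def test_prediction_invariant_under_atom_permutation(self, tiny_model_config):
        model = DTANetwork(tiny_model_config, seed=2)
        x, powers = featurize("CC(=O)Oc1ccccc1C(=O)O")
        prot = protein_input(tiny_model_config, seed=3)
        base = model.predict(x, powers, prot)
        rng = np.random.default_rng(4)
        perm = rng.permutation(x.shape[0])
        permuted_powers = {k: m[np.ix_(perm, perm)] for k, m in powers.items()}
        permuted = model.predict(x[perm], permuted_powers, prot)
        assert permuted == pytest.approx(base, rel=1e-9)


class TestFusionHead:
    def test_evaluation_mode_deterministic(self, tiny_model_config):
        model = DTANetwork(tiny_model_config, seed=5)
        x, powers = featurize("CCN")
        prot = protein_input(tiny_model_config)
        assert model.predict(x, powers, prot) == model.predict(x, powers, prot)

    def test_training_dropout_reproducible_under_seed(self, tiny_model_config):
        model = DTANetwork(tiny_model_config, seed=5)
        x, powers = featurize("CCN")
        prot = protein_input(tiny_model_config)
        outs = [model.forward(x, powers, prot, training=True,
                              rng=np.random.default_rng(9)).item()
                for _ in range(2)]
        assert outs[0] == outs[1]

    def test_mode_flag_contract(self, tiny_model_config):
        model = DTANetwork(tiny_model_config, seed=5)
        x, powers = featurize("CCN")
        prot = protein_input(tiny_model_config)
        with pytest.raises(ValueError):
            model.forward(x, powers, prot, training=True)  # no generator
        with pytest.raises(ValueError):
            model.forward(x, powers, prot, training=False,
                          rng=np.random.default_rng(0))

    def test_zero_final_weights_predict_the_bias(self, tiny_model_config):
        model = DTANetwork(tiny_model_config, seed=6)
        model.params["fc_w_out"].data[:] = 0.0
        model.params["fc_b_out"].data[:] = 4.25
        for smiles in ("C", "CCO", "c1ccccc1"):
            x, powers = featurize(smiles)
            assert model.predict(x, powers,
                                 protein_input(tiny_model_config)) == 4.25

    def test_single_power_config_touches_only_its_adjacency(self):
        config = ModelConfig(
            drug_feature_dim=78, powers=(2,),
            gcn_block_dims={2: (4, 8)},
            protein_channels=4, protein_rows=8,
            protein_conv_filters=(4,), protein_kernel_sizes=(3,),
            fusion_dims=(8, 4))
        model = DTANetwork(config, seed=0)
        x, powers = featurize("CCCCO")
        model.predict(x, powers, protein_input(config))
        assert model.touched_powers == {2}

    def test_checkpoint_roundtrip(self, tmp_path, tiny_model_config):
        model = DTANetwork(tiny_model_config, seed=7)
        x, powers = featurize("CCOC")
        prot = protein_input(tiny_model_config)
        before = model.predict(x, powers, prot)
        path = tmp_path / "model.npz"
        model.save(path)
        restored = DTANetwork.load(path)
        assert restored.config == tiny_model_config
        assert restored.predict(x, powers, prot) == before


class TestGradients:
    def test_full_forward_matches_central_differences(self, tiny_model_config):
        """Analytic gradients of squared error agree with finite differences."""
        from dataclasses import replace
        config = replace(tiny_model_config, dropout_rate=0.0)
        model = DTANetwork(config, seed=3)
        x, powers = featurize("CCO")   # 3 heavy atoms
        prot = protein_input(config, seed=5)
        target = 7.0

        def loss_value():
            return (model.predict(x, powers, prot) - target) ** 2

        out = model.forward(x, powers, prot, training=False)
        loss = ad.square(ad.sub(out, ad.Tensor([[target]])))
        ad.backward(loss)

        rng = np.random.default_rng(8)
        eps = 1e-6
        for name, tensor in model.params.items():
            flat = tensor.data.reshape(-1)
            grads = tensor.grad.reshape(-1)
            picks = rng.choice(flat.size, size=min(10, flat.size),
                               replace=False)
            for i in picks:
                orig = flat[i]
                flat[i] = orig + eps
                up = loss_value()
                flat[i] = orig - eps
                down = loss_value()
                flat[i] = orig
                numeric = (up - down) / (2 * eps)
                scale = max(abs(numeric), abs(grads[i]), 1e-8)
                assert abs(numeric - grads[i]) / scale < 1e-4, name
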