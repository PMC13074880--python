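"""Encoder/decoder forward math, losses, gradients and training contracts."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pmal.chem_io import MolecularGraph, TaskSpec, TaskType, smiles_to_graph
from pmal.model import (
    MixtureParams,
    ModelConfig,
    PMALModel,
    gcn_layer_forward,
    mixture_loss,
    multitask_loss,
    point_prediction,
    train_model,
)


def _dense_gcn_oracle(h, edges, W):
    """Loop-based Â H W with symmetric normalization and self-loops."""
    n = h.shape[0]
    adj = np.eye(n)
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1.0
    deg = adj.sum(axis=1)
    out = np.zeros((n, W.shape[1]))
    for v in range(n):
        for u in range(n):
            if adj[v, u]:
                out[v] += h[u] @ W / np.sqrt(deg[v] * deg[u])
    return np.maximum(out, 0.0)


class TestGcnLayer:
    def test_isolated_node_identity(self):
        h = np.array([[1.0, 2.0, 3.0]])
        out = gcn_layer_forward(h, [], np.eye(3))
        assert np.allclose(out, h)

    def test_two_node_symmetry(self):
        h = np.array([[1.0], [1.0]])
        out = gcn_layer_forward(h, [(0, 1)], np.eye(1))
        assert np.allclose(out, 1.0)  # self 1/2 + neighbor 1/2

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_dense_oracle_on_small_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        h = rng.normal(size=(n, 4))
        W = rng.normal(size=(4, 3))
        possible = [(i, j) for i in range(n) for j in range(i + 1, n)]
        k = int(rng.integers(0, len(possible) + 1))
        edges = [possible[i] for i in rng.choice(len(possible), size=k, replace=False)]
        out = gcn_layer_forward(h, edges, W)
        assert np.allclose(out, _dense_gcn_oracle(h, edges, W), atol=1e-12)

    def test_out_of_range_edge_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            gcn_layer_forward(np.ones((2, 2)), [(0, 5)], np.eye(2))


def _tiny_model(**over):
    cfg = ModelConfig(**{"n_tasks": 2, "n_layers": 2, "hidden_dim": 8,
                         "n_components": 3, "seed": 3, **over})
    return PMALModel(cfg)


class TestEncoder:
    def test_permutation_invariance(self):
        g = smiles_to_graph("CCOc1ccccc1N")
        rng = np.random.default_rng(0)
        perm = rng.permutation(g.n_atoms)
        inv = np.argsort(perm)
        permuted = MolecularGraph(
            smiles=g.smiles,
            node_features=g.node_features[inv],
            edges=sorted(tuple(sorted((perm[i], perm[j]))) for i, j in g.edges),
            n_atoms=g.n_atoms,
        )
        m = _tiny_model()
        z1 = m.encode([g])
        z2 = m.encode([permuted])
        assert np.allclose(z1, z2, atol=1e-12)

    def test_single_atom_mean_equals_sum(self):
        g = smiles_to_graph("C")
        z_mean = _tiny_model(readout="mean").encode([g])
        z_sum = _tiny_model(readout="sum").encode([g])
        assert np.allclose(z_mean, z_sum)

    def test_mean_vs_sum_factor_two_on_two_nodes(self):
        g = smiles_to_graph("CC")
        z_mean = _tiny_model(readout="mean").encode([g])
        z_sum = _tiny_model(readout="sum").encode([g])
        assert np.allclose(2.0 * z_mean, z_sum, atol=1e-12)


class TestMixtureHeads:
    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_decoded_params_always_valid(self, seed):
        m = _tiny_model(seed=seed)
        z = np.random.default_rng(seed).normal(size=(4, 8))
        for params in m.decode_regression(z, 0):
            assert params.weights.sum() == pytest.approx(1.0, abs=1e-6)
            assert np.all(params.variances >= m.config.var_floor)
            assert np.all(np.isfinite(params.means))

    def test_zero_final_layer_gives_uniform_mixture(self):
        m = _tiny_model()
        m.params["dec0_W3"][:] = 0.0
        m.params["dec0_b3"][:] = 0.0
        (params,) = m.decode_regression(np.ones((1, 8)), 0)
        assert np.allclose(params.weights, 1.0 / 3.0)
        assert np.ptp(params.means) == 0.0

    def test_different_embeddings_give_different_means(self):
        m = _tiny_model()
        a, b = m.decode_regression(np.vstack([np.ones(8), -np.ones(8)]), 0)
        assert not np.allclose(a.means, b.means)

    def test_classification_probabilities_on_simplex(self):
        tasks = [TaskSpec(0, "cls", TaskType.CLASSIFICATION)]
        m = PMALModel(ModelConfig(n_tasks=1, n_layers=1, hidden_dim=8,
                                  n_components=2, seed=1), tasks)
        p = m.decode_classification(np.random.default_rng(0).normal(size=(5, 8)), 0)
        assert np.allclose(p.sum(axis=1), 1.0)
        assert np.all(p >= 0)

    def test_classification_zero_noise_is_plain_softmax(self):
        tasks = [TaskSpec(0, "cls", TaskType.CLASSIFICATION)]
        m = PMALModel(ModelConfig(n_tasks=1, n_layers=1, hidden_dim=8,
                                  n_components=2, seed=1), tasks)
        z = np.random.default_rng(2).normal(size=(3, 8))
        # variances sit near the floor when the raw head is very negative
        m.params["dec0_b3"][2 + 2 * 2:] = -40.0
        m.params["dec0_W3"][:, 2 + 2 * 2:] = 0.0
        gamma = np.random.default_rng(3).standard_normal((2, 2))
        assert np.allclose(m.decode_classification(z, 0, gamma=gamma),
                           m.decode_classification(z, 0), atol=1e-4)


class TestMixtureLoss:
    def test_unit_height_gaussian_gives_zero(self):
        params = MixtureParams([1.0], [2.0], [1.0 / (2 * np.pi)])
        assert mixture_loss(params, 2.0) == pytest.approx(0.0, abs=1e-12)

    def test_two_standard_normals_at_origin(self):
        params = MixtureParams([0.5, 0.5], [0.0, 0.0], [1.0, 1.0])
        assert mixture_loss(params, 0.0) == pytest.approx(0.5 * np.log(2 * np.pi))

    def test_component_permutation_invariance(self):
        params = MixtureParams([0.2, 0.8], [1.0, -1.0], [0.5, 2.0])
        swapped = MixtureParams([0.8, 0.2], [-1.0, 1.0], [2.0, 0.5])
        y = 0.3
        assert mixture_loss(params, y) == pytest.approx(mixture_loss(swapped, y))

    def test_mixture_nll_form_lower_bounds_weighted_form(self):
        # Jensen: -log sum pi p  <=  -sum pi log p
        params = MixtureParams([0.3, 0.7], [0.0, 2.0], [0.4, 1.5])
        assert mixture_loss(params, 1.0, form="mixture_nll") <= mixture_loss(params, 1.0)

    def test_nonfinite_label_rejected(self):
        params = MixtureParams([1.0], [0.0], [1.0])
        with pytest.raises(ValueError, match="finite"):
            mixture_loss(params, np.nan)


class TestMultitaskLoss:
    def test_single_task_is_its_mean(self):
        assert multitask_loss([[1.0, 3.0]]) == pytest.approx(2.0)

    def test_equal_tasks_add(self):
        assert multitask_loss([[2.0], [2.0]]) == pytest.approx(4.0)

    def test_fully_masked_batch_is_zero(self):
        assert multitask_loss([[1.0, 2.0]], masks=[[False, False]]) == 0.0


class TestPointPrediction:
    @pytest.mark.parametrize(
        "weights,means,expected",
        [([1.0, 0.0], [2.0, 7.0], 2.0), ([0.5, 0.5], [0.0, 2.0], 1.0)],
    )
    def test_mixture_mean(self, weights, means, expected):
        params = MixtureParams(weights, means, [1.0, 1.0])
        assert point_prediction(params) == pytest.approx(expected)

    def test_matches_monte_carlo_mean(self):
        rng = np.random.default_rng(11)
        params = MixtureParams([0.2, 0.5, 0.3], [-1.0, 0.5, 3.0], [0.5, 1.0, 2.0])
        n = 10**6
        comp = rng.choice(3, size=n, p=params.weights)
        draws = rng.normal(params.means[comp], np.sqrt(params.variances[comp]))
        se = draws.std() / np.sqrt(n)
        assert abs(point_prediction(params) - draws.mean()) < 3 * se


class TestGradients:
    @pytest.mark.parametrize("loss_form", ["weighted_component_nll", "mixture_nll"])
    @pytest.mark.parametrize("readout", ["mean", "sum", "max"])
    def test_backprop_matches_finite_differences(self, loss_form, readout,
                                                 small_dataset):
        graphs = small_dataset.graphs[:6]
        labels = np.nan_to_num(small_dataset.labels[:6])
        mask = small_dataset.label_mask[:6]
        m = _tiny_model(readout=readout, loss=loss_form, activation="tanh")
        _, grads = m._batch_loss_and_grads(graphs, labels, mask)
        rng = np.random.default_rng(0)
        for name in ["enc0_W", "enc1_b", "dec0_W3", "dec1_W1", "dec0_b3"]:
            p = m.params[name]
            for _ in range(3):
                idx = tuple(rng.integers(s) for s in p.shape)
                eps, orig = 1e-6, p[idx]
                p[idx] = orig + eps
                up, _ = m._batch_loss_and_grads(graphs, labels, mask)
                p[idx] = orig - eps
                down, _ = m._batch_loss_and_grads(graphs, labels, mask)
                p[idx] = orig
                fd = (up - down) / (2 * eps)
                assert grads[name][idx] == pytest.approx(fd, rel=1e-4, abs=1e-7)


class TestTraining:
    def test_same_seed_gives_identical_traces(self, small_dataset):
        sub = small_dataset.subset(range(80))
        cfg = ModelConfig(n_tasks=2, n_layers=2, hidden_dim=16, epochs=2, seed=9)
        _, t1 = train_model(sub, cfg)
        _, t2 = train_model(sub, cfg)
        assert t1 == t2

    def test_zero_learning_rate_freezes_the_trace(self, small_dataset):
        sub = small_dataset.subset(range(80))
        cfg = ModelConfig(n_tasks=2, n_layers=2, hidden_dim=16, epochs=3,
                          learning_rate=0.0, weight_decay=0.0, seed=9)
        _, trace = train_model(sub, cfg)
        assert len(trace) == 3
        assert np.ptp(trace) == 0.0

    def test_zero_epochs_empty_trace(self, small_dataset):
        sub = small_dataset.subset(range(40))
        cfg = ModelConfig(n_tasks=2, n_layers=1, hidden_dim=8, epochs=0, seed=0)
        _, trace = train_model(sub, cfg)
        assert trace == []

    def test_loss_improves_on_small_task(self, small_dataset):
        sub = small_dataset.subset(range(200))
        wins = 0
        for seed in range(5):
            cfg = ModelConfig(n_tasks=2, n_layers=2, hidden_dim=32, epochs=5,
                              seed=seed)
            _, trace = train_model(sub, cfg)
            wins += trace[-1] < trace[0]
        assert wins >= 3

    def test_no_labels_errors(self, small_dataset):
        sub = small_dataset.subset(range(10))
        cfg = ModelConfig(n_tasks=2, n_layers=1, hidden_dim=8, epochs=1, seed=0)
        with pytest.raises(ValueError, match="no labeled"):
            train_model(sub, cfg, labeled_mask=np.zeros_like(sub.label_mask))

    def test_checkpoint_round_trip_is_bit_exact(self, small_dataset, tmp_path):
        sub = small_dataset.subset(range(60))
        cfg = ModelConfig(n_tasks=2, n_layers=2, hidden_dim=16, epochs=1, seed=4)
        model, _ = train_model(sub, cfg)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = type(model).load(path)
        assert loaded.config == model.config
        for k, v in model.params.items():
            assert np.array_equal(loaded.params[k], v)
        assert np.array_equal(loaded.predict_point(sub.graphs[:5], 0),
                              model.predict_point(sub.graphs[:5], 0))
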