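import numpy as np
import pytest

from ncdlink import (
    AssociationDataset,
    LinearResidualGCN,
    build_adjacency,
    generate_synthetic,
    normalize,
)
from ncdlink.model import (
    Hyperparameters,
    ModelState,
    TrainingDivergedError,
    bpr_gradients,
    bpr_loss,
    init_embeddings,
    propagate,
    sample_bpr_triples,
    score,
    train,
)

from conftest import random_dataset


def neighbor_loop_step(ds, E0, W):
    """Independent oracle: one propagation step via explicit neighbor sums.

    Uses the self-looped degrees d = raw degree + 1, so the self term is
    e / d and each neighbor contributes e_neighbor / sqrt(d_i d_j), all
    multiplied by the layer transform.
    """
    m, n = ds.m, ds.n
    deg = np.ones(m + n)
    for i, j in ds.pairs:
        deg[i] += 1
        deg[m + j] += 1
    E1 = np.zeros_like(E0)
    for a in range(m):  # ncRNA rows
        acc = E0[a] / deg[a]
        for j in ds.drugs_of(a):
            acc = acc + E0[m + j] / np.sqrt(deg[a] * deg[m + j])
        E1[a] = acc @ W
    for b in range(n):  # drug rows
        acc = E0[m + b] / deg[m + b]
        for i in ds.ncrnas_of(b):
            acc = acc + E0[i] / np.sqrt(deg[m + b] * deg[i])
        E1[m + b] = acc @ W
    return E1


class TestInitEmbeddings:
    def test_deterministic(self):
        hp = Hyperparameters(seed=5)
        a = init_embeddings(10, 4, hp)
        b = init_embeddings(10, 4, hp)
        assert np.array_equal(a.E0, b.E0)
        assert all(np.array_equal(x, y) for x, y in zip(a.W, b.W))

    def test_sample_std_matches_init_std(self):
        # reference network size: 625 + 121 = 746 nodes
        hp = Hyperparameters(embedding_dim=32, init_std=0.1, seed=0)
        st = init_embeddings(625, 121, hp)
        assert abs(np.std(st.E0) - 0.1) / 0.1 < 0.05

    def test_zero_init_std_forbidden(self):
        with pytest.raises(ValueError):
            Hyperparameters(init_std=0.0)

    def test_weights_near_identity(self):
        hp = Hyperparameters(embedding_dim=8, seed=1)
        st = init_embeddings(5, 3, hp)
        for w in st.W:
            assert np.max(np.abs(w - np.eye(8))) < 0.1


class TestPropagate:
    def test_identity_operator_fixed_point(self):
        # no edges: P = D^-1/2 (0 + I) D^-1/2 = I; identity transforms
        ds = AssociationDataset(["a", "b"], ["X"], set())
        P = normalize(build_adjacency(ds))
        hp = Hyperparameters(n_layers=3, embedding_dim=4, seed=0)
        st = init_embeddings(2, 1, hp)
        st.W = [np.eye(4)] * 3
        out = propagate(st, P, hp)
        for E_k in out.layers:
            assert np.allclose(E_k, st.E0, atol=1e-12)

    def test_single_step_matches_neighbor_loops(self):
        ds = random_dataset(5, 3, 0.5, seed=10)
        P = normalize(build_adjacency(ds))
        hp = Hyperparameters(n_layers=1, embedding_dim=6, seed=3)
        st = init_embeddings(5, 3, hp)
        out = propagate(st, P, hp)
        expected = neighbor_loop_step(ds, st.E0, st.W[0])
        assert np.max(np.abs(out.layers[1] - expected)) < 1e-9

    def test_depth_k_equals_iterated_single_steps(self):
        ds = random_dataset(6, 4, 0.4, seed=2)
        P = normalize(build_adjacency(ds))
        hp = Hyperparameters(n_layers=4, embedding_dim=5, seed=8)
        st = init_embeddings(6, 4, hp)
        out = propagate(st, P, hp)
        E = st.E0
        for k in range(4):
            E = (P.P @ E) @ st.W[k]
            assert np.allclose(out.layers[k + 1], E, atol=1e-12)

    def test_dimension_mismatch_errors(self):
        ds = random_dataset(5, 3, 0.5, seed=1)
        P = normalize(build_adjacency(ds))
        hp = Hyperparameters(embedding_dim=4)
        st = init_embeddings(6, 3, hp)  # 9 nodes vs operator side 8
        with pytest.raises(ValueError, match="operator side"):
            propagate(st, P, hp)

    def test_linearity_in_initial_embeddings(self):
        ds = random_dataset(7, 4, 0.4, seed=5)
        P = normalize(build_adjacency(ds))
        hp = Hyperparameters(n_layers=3, embedding_dim=4, seed=2)
        st = init_embeddings(7, 4, hp)
        scaled = ModelState(E0=2.5 * st.E0, W=[w.copy() for w in st.W],
                            m=st.m, n=st.n)
        out = propagate(st, P, hp)
        out_scaled = propagate(scaled, P, hp)
        for a, b in zip(out.layers, out_scaled.layers):
            assert np.max(np.abs(2.5 * a - b)) < 1e-9


class TestScore:
    def test_layer0_base_case_is_squared_norm(self):
        v = np.array([[0.3, -0.2, 0.7]])
        st = ModelState(E0=np.vstack([v, v]), W=[], m=1, n=1)
        st = propagate(st, normalize(build_adjacency(
            AssociationDataset(["u"], ["v"], set()))), None)
        O = score(st).O
        assert np.allclose(O, v @ v.T)

    def test_zero_embeddings_zero_scores(self):
        ds = random_dataset(4, 3, 0.5, seed=0)
        P = normalize(build_adjacency(ds))
        hp = Hyperparameters(n_layers=2, embedding_dim=3)
        st = ModelState(E0=np.zeros((7, 3)), W=[np.eye(3)] * 2, m=4, n=3)
        st = propagate(st, P, hp)
        assert not score(st).O.any()

    def test_matches_layer_sum_loop(self):
        ds = random_dataset(5, 4, 0.4, seed=7)
        P = normalize(build_adjacency(ds))
        hp = Hyperparameters(n_layers=3, embedding_dim=4, seed=9)
        st = propagate(init_embeddings(5, 4, hp), P, hp)
        O = score(st).O
        for a in range(5):
            for r in range(4):
                expected = sum(float(E_k[a] @ E_k[5 + r])
                               for E_k in st.layers)
                assert abs(O[a, r] - expected) < 1e-9

    def test_requires_forward_pass(self):
        hp = Hyperparameters(embedding_dim=3)
        st = init_embeddings(3, 2, hp)
        with pytest.raises(RuntimeError, match="propagate"):
            score(st)

    def test_skip_layer0_option(self):
        ds = random_dataset(5, 4, 0.4, seed=7)
        P = normalize(build_adjacency(ds))
        hp = Hyperparameters(n_layers=2, embedding_dim=4, seed=9)
        st = propagate(init_embeddings(5, 4, hp), P, hp)
        full = score(st, include_layer0=True).O
        no0 = score(st, include_layer0=False).O
        E0 = st.layers[0]
        assert np.allclose(full - no0, E0[:5] @ E0[5:].T, atol=1e-12)


class TestBprLoss:
    @staticmethod
    def _state(ds, hp):
        P = normalize(build_adjacency(ds))
        return propagate(init_embeddings(ds.m, ds.n, hp), P, hp), P

    def test_equal_scores_give_ln2_per_triple(self):
        ds = random_dataset(4, 3, 0.5, seed=1)
        hp = Hyperparameters(n_layers=2, embedding_dim=3, reg_lambda=0.0)
        st, _ = self._state(ds, hp)
        st.E0[:] = 0.0  # all scores zero
        st = propagate(st, normalize(build_adjacency(ds)), hp)
        triples = [(0, 0, 1), (1, 2, 0), (2, 1, 2)]
        assert np.isclose(bpr_loss(st, triples, hp), 3 * np.log(2))

    def test_loss_decreases_with_margin(self):
        # score(a, i) - score(a, j) increasing => loss decreasing
        ds = AssociationDataset(["u"], ["v", "w"], {(0, 0)})
        hp = Hyperparameters(n_layers=1, embedding_dim=2, reg_lambda=0.0)
        losses = []
        for scale in [0.1, 1.0, 5.0]:
            st = ModelState(
                E0=np.array([[scale, 0.0], [scale, 0.0], [-scale, 0.0]]),
                W=[np.eye(2)], m=1, n=2)
            st = propagate(st, normalize(build_adjacency(ds)), hp)
            losses.append(bpr_loss(st, [(0, 0, 1)], hp))
        assert losses[0] > losses[1] > losses[2]

    def test_matches_scalar_formula(self):
        ds = random_dataset(4, 3, 0.5, seed=6)
        hp = Hyperparameters(n_layers=2, embedding_dim=3,
                             reg_lambda=0.01, seed=2)
        st, _ = self._state(ds, hp)
        triples = [(0, 1, 2), (1, 0, 1), (3, 2, 0)]
        loss = bpr_loss(st, triples, hp)
        # oracle: scalar-by-scalar evaluation
        O = score(st).O
        sigma = lambda x: 1.0 / (1.0 + np.exp(-x))
        expected = sum(-np.log(sigma(O[a, i] - O[a, j]))
                       for a, i, j in triples)
        expected += 0.01 * (np.sum(st.E0 ** 2)
                            + sum(np.sum(w ** 2) for w in st.W))
        assert abs(loss - expected) < 1e-10

    def test_identical_positive_negative_rejected(self):
        ds = random_dataset(3, 3, 0.5, seed=0)
        hp = Hyperparameters(n_layers=1, embedding_dim=2)
        st, _ = self._state(ds, hp)
        with pytest.raises(ValueError, match="identical"):
            bpr_loss(st, [(0, 1, 1)], hp)


class TestGradients:
    @pytest.mark.parametrize("include_layer0,shared", [
        (True, False), (False, False), (True, True),
    ])
    def test_finite_difference_agreement(self, include_layer0, shared):
        rng = np.random.default_rng(14)
        ds = random_dataset(8, 5, 0.4, seed=14)
        hp = Hyperparameters(n_layers=3, embedding_dim=4, reg_lambda=1e-3,
                             include_layer0=include_layer0,
                             shared_weights=shared, seed=14)
        P = normalize(build_adjacency(ds))
        st = init_embeddings(ds.m, ds.n, hp)
        triples = sample_bpr_triples(ds, rng, 1)
        _, gE0, gW = bpr_gradients(st, P, triples, hp)
        eps = 1e-6
        for _ in range(10):
            r = int(rng.integers(st.E0.shape[0]))
            c = int(rng.integers(st.E0.shape[1]))
            st.E0[r, c] += eps
            lp = bpr_loss(propagate(st, P, hp), triples, hp)
            st.E0[r, c] -= 2 * eps
            lm = bpr_loss(propagate(st, P, hp), triples, hp)
            st.E0[r, c] += eps
            fd = (lp - lm) / (2 * eps)
            assert abs(fd - gE0[r, c]) <= 1e-4 * abs(fd) + 1e-8

    def test_weight_gradients(self):
        rng = np.random.default_rng(21)
        ds = random_dataset(6, 4, 0.5, seed=21)
        hp = Hyperparameters(n_layers=2, embedding_dim=3,
                             reg_lambda=1e-3, seed=21)
        P = normalize(build_adjacency(ds))
        st = init_embeddings(ds.m, ds.n, hp)
        triples = sample_bpr_triples(ds, rng, 1)
        _, _, gW = bpr_gradients(st, P, triples, hp)
        eps = 1e-6
        for _ in range(6):
            k = int(rng.integers(2))
            r, c = int(rng.integers(3)), int(rng.integers(3))
            st.W[k][r, c] += eps
            lp = bpr_loss(propagate(st, P, hp), triples, hp)
            st.W[k][r, c] -= 2 * eps
            lm = bpr_loss(propagate(st, P, hp), triples, hp)
            st.W[k][r, c] += eps
            fd = (lp - lm) / (2 * eps)
            assert abs(fd - gW[k][r, c]) <= 1e-4 * abs(fd) + 1e-8


class TestTrain:
    def test_zero_epochs_returns_initial_state(self):
        ds = random_dataset(10, 5, 0.3, seed=4)
        hp = Hyperparameters(epochs=0, embedding_dim=4, seed=4)
        st, history = train(ds, hp)
        expected = init_embeddings(ds.m, ds.n, hp)
        assert history == []
        assert np.array_equal(st.E0, expected.E0)
        assert all(np.array_equal(a, b) for a, b in zip(st.W, expected.W))

    def test_loss_history_reproducible(self):
        ds = random_dataset(12, 6, 0.3, seed=9)
        hp = Hyperparameters(epochs=15, embedding_dim=4, seed=9)
        _, h1 = train(ds, hp)
        _, h2 = train(ds, hp)
        assert h1 == h2

    def test_loss_decreases_on_block_dataset(self, block_sim):
        hp = Hyperparameters(epochs=200, seed=7)
        _, history = train(block_sim.dataset, hp)
        assert history[-1] < history[0]

    def test_divergence_raises_with_epoch(self):
        ds = random_dataset(6, 4, 0.5, seed=2)
        hp = Hyperparameters(epochs=3, embedding_dim=3,
                             init_std=1e160, seed=2)
        with np.errstate(all="ignore"), pytest.raises(
                TrainingDivergedError, match="epoch"):
            train(ds, hp)

    def test_negative_exclusion_respected(self):
        ds = random_dataset(10, 6, 0.3, seed=3)
        rng = np.random.default_rng(0)
        # forbid every drug except one per ncRNA; sampled j must be allowed
        forbidden = {a: set(range(5)) for a in range(10)}
        triples = sample_bpr_triples(ds, rng, 2, forbidden)
        for a, i, j in triples:
            assert j not in forbidden[a]
            assert (a, j) not in ds.pairs


class TestEstimatorContract:
    def test_sklearn_params_round_trip(self):
        est = LinearResidualGCN(n_layers=2, embedding_dim=8)
        params = est.get_params()
        assert params["n_layers"] == 2
        clone = LinearResidualGCN().set_params(**params)
        assert clone.get_params() == params

    def test_fit_sets_fitted_attributes(self):
        sim = generate_synthetic(20, 8, 2, 0.6, 0.05, seed=1)
        est = LinearResidualGCN(n_epochs=5, embedding_dim=8).fit(sim.dataset)
        assert est.score_matrix_.shape == (20, 8)
        assert len(est.loss_history_) == 5
        assert est.ncrnas_ == sim.dataset.ncrnas

    def test_unfitted_raises(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            LinearResidualGCN().decision_function([(0, 0)])

    def test_relabeling_equivariance_of_scores(self):
        # permuting ncRNA indices with the same embeddings permutes score rows
        ds = random_dataset(6, 4, 0.5, seed=17)
        hp = Hyperparameters(n_layers=2, embedding_dim=4, seed=17)
        perm = np.random.default_rng(1).permutation(ds.m)
        inv = np.argsort(perm)
        ds_perm = AssociationDataset(
            [ds.ncrnas[i] for i in perm], list(ds.drugs),
            {(int(inv[i]), j) for i, j in ds.pairs})
        st = init_embeddings(ds.m, ds.n, hp)
        st_perm = st.copy()
        st_perm.E0[:ds.m] = st.E0[perm]
        O = score(propagate(st, normalize(build_adjacency(ds)), hp)).O
        O_perm = score(propagate(st_perm, normalize(build_adjacency(ds_perm)),
                                 hp)).O
        assert np.max(np.abs(O_perm - O[perm])) < 1e-9

    def test_duplicated_drug_gives_identical_score_columns(self):
        # a drug column duplicated in R plus identical initial embedding
        # rows must produce identical score columns
        ds = AssociationDataset(["a", "b", "c"], ["X", "Y", "Y2"],
                                {(0, 0), (1, 0), (1, 1), (2, 1),
                                 (1, 2), (2, 2)})
        hp = Hyperparameters(n_layers=3, embedding_dim=4, seed=5)
        st = init_embeddings(3, 3, hp)
        st.E0[5] = st.E0[4]  # drug Y2 starts identical to Y
        O = score(propagate(st, normalize(build_adjacency(ds)), hp)).O
        assert np.max(np.abs(O[:, 1] - O[:, 2])) < 1e-12
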