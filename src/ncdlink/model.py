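"""Linear residual graph convolution model with BPR training.

The model keeps one S-dimensional embedding per node (ncRNAs first, then
drugs). Starting from the layer-0 matrix ``E0``, each layer applies the
normalized propagation operator followed by a per-layer linear transform,
with no nonlinearity anywhere:

    E^{k+1} = P E^k W^k,   k = 0 .. K-1.

The predicted association score of ncRNA a and drug r accumulates the
per-layer dot products residually,

    score(a, r) = sum_k e_a^k . e_r^k,

so low-layer (less smoothed) signal survives deep propagation. Training
minimizes the Bayesian Personalized Ranking loss

    L = sum_{(a,i,j)} -ln sigma(score(a,i) - score(a,j))
        + lambda (||E0||^2 + sum_k ||W^k||^2),

where i is an observed positive drug for ncRNA a and j a sampled
non-positive. Because the forward map is linear, gradients are exact
matrix expressions; optimization uses Adam.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .data_io import AssociationDataset
from .graph import NormalizedAdjacency, build_adjacency, normalize

Triple = tuple[int, int, int]  # (ncRNA a, positive drug i, negative drug j)


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite during training."""


@dataclass
class Hyperparameters:
    """Model and training settings.

    Parameters
    ----------
    n_layers : int
        Propagation depth K. Four layers give the best cross-validated
        performance on the reference association network.
    embedding_dim : int
        Embedding size S; 32 is the cross-validated optimum.
    init_std : float
        Standard deviation of the normal initialization of the layer-0
        embeddings.
    reg_lambda : float
        L2 strength applied to E0 and to every linear transform.
    negatives_per_positive : int
        Sampled negatives j per observed positive (a, i) per epoch.
    include_layer0 : bool
        Whether the residual score includes the layer-0 dot product.
    shared_weights : bool
        Use a single linear transform for all layers instead of one per layer.
    """

    n_layers: int = 4
    embedding_dim: int = 32
    init_std: float = 0.1
    reg_lambda: float = 1e-4
    learning_rate: float = 1e-3
    epochs: int = 200
    negatives_per_positive: int = 1
    include_layer0: bool = True
    shared_weights: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.embedding_dim < 1:
            raise ValueError("embedding_dim must be >= 1")
        if self.init_std <= 0:
            raise ValueError("init_std must be > 0")
        if self.reg_lambda < 0:
            raise ValueError("reg_lambda must be >= 0")
        if self.negatives_per_positive < 1:
            raise ValueError("negatives_per_positive must be >= 1")


@dataclass
class ModelState:
    """Layer-0 embeddings, per-layer transforms, and the cached forward pass."""

    E0: np.ndarray                      # (m+n, S)
    W: list[np.ndarray]                 # K matrices, each (S, S)
    m: int
    n: int
    layers: list[np.ndarray] | None = None  # [E^0 .. E^K] after propagate

    @property
    def n_layers(self) -> int:
        return len(self.W)

    @property
    def embedding_dim(self) -> int:
        return self.E0.shape[1]

    def copy(self) -> "ModelState":
        return ModelState(
            E0=self.E0.copy(),
            W=[w.copy() for w in self.W],
            m=self.m,
            n=self.n,
            layers=None if self.layers is None else [e.copy() for e in self.layers],
        )


@dataclass
class ScoreMatrix:
    """m x n matrix of predicted association scores."""

    O: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.O)):
            raise ValueError("score matrix contains non-finite entries")


def _spawn_rngs(seed: int) -> dict[str, np.random.Generator]:
    """Split a master seed into named substreams (init, sampling, cv)."""
    ss = np.random.SeedSequence(seed)
    init_ss, samp_ss, cv_ss = ss.spawn(3)
    return {
        "init": np.random.default_rng(init_ss),
        "sampling": np.random.default_rng(samp_ss),
        "cv": np.random.default_rng(cv_ss),
    }


def init_embeddings(
    m: int,
    n: int,
    hp: Hyperparameters,
    rng: np.random.Generator | None = None,
) -> ModelState:
    """Initialize layer-0 embeddings and linear transforms.

    E0 entries are i.i.d. normal with mean 0 and standard deviation
    ``hp.init_std``. Each W^k starts as identity plus small normal noise
    (std 0.01) so the untrained model approximates pure propagation, which
    keeps early training stable.
    """
    if m < 1 or n < 1 or hp.embedding_dim < 1:
        raise ValueError("m, n, and embedding_dim must be positive")
    if rng is None:
        rng = _spawn_rngs(hp.seed)["init"]
    S = hp.embedding_dim
    E0 = rng.normal(0.0, hp.init_std, size=(m + n, S))
    if hp.shared_weights:
        w = np.eye(S) + rng.normal(0.0, 0.01, size=(S, S))
        W = [w] * hp.n_layers  # shared object: one parameter
    else:
        W = [np.eye(S) + rng.normal(0.0, 0.01, size=(S, S))
             for _ in range(hp.n_layers)]
    return ModelState(E0=E0, W=W, m=m, n=n)


def propagate(
    state: ModelState,
    P: NormalizedAdjacency,
    hp: Hyperparameters | None = None,
) -> ModelState:
    """Run the K-step linear forward pass and cache every layer."""
    if P.size != state.E0.shape[0]:
        raise ValueError(
            f"operator side {P.size} != number of embedded nodes {state.E0.shape[0]}"
        )
    layers = [state.E0]
    for W_k in state.W:
        layers.append((P.P @ layers[-1]) @ W_k)
    return replace(state, layers=layers)


def _raw_score(state: ModelState, include_layer0: bool = True) -> np.ndarray:
    if state.layers is None:
        raise RuntimeError("score() requires a completed forward pass; "
                           "call propagate() first")
    start = 0 if include_layer0 else 1
    m = state.m
    O = np.zeros((state.m, state.n))
    for E_k in state.layers[start:]:
        O += E_k[:m] @ E_k[m:].T
    return O


def score(state: ModelState, include_layer0: bool = True) -> ScoreMatrix:
    """Residual score: per-layer ncRNA-drug dot products, accumulated."""
    return ScoreMatrix(_raw_score(state, include_layer0))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _log_sigmoid(x: np.ndarray) -> np.ndarray:
    # -softplus(-x), numerically stable
    return np.where(x >= 0, -np.log1p(np.exp(-x)), x - np.log1p(np.exp(x)))


def _reg_term(state: ModelState, hp: Hyperparameters) -> float:
    w_sq = (np.sum(state.W[0] ** 2) if hp.shared_weights
            else sum(np.sum(w ** 2) for w in state.W))
    return hp.reg_lambda * (float(np.sum(state.E0 ** 2)) + float(w_sq))


def bpr_loss(
    state: ModelState,
    triples: Sequence[Triple],
    hp: Hyperparameters,
) -> float:
    """Bayesian Personalized Ranking loss over (ncRNA, positive, negative) triples."""
    for a, i, j in triples:
        if i == j:
            raise ValueError(f"triple ({a}, {i}, {j}) has identical "
                             "positive and negative drug")
    O = _raw_score(state, include_layer0=hp.include_layer0)
    t = np.asarray(triples, dtype=np.int64).reshape(-1, 3)
    diff = O[t[:, 0], t[:, 1]] - O[t[:, 0], t[:, 2]]
    return float(-np.sum(_log_sigmoid(diff))) + _reg_term(state, hp)


def bpr_gradients(
    state: ModelState,
    P: NormalizedAdjacency,
    triples: Sequence[Triple],
    hp: Hyperparameters,
) -> tuple[float, np.ndarray, list[np.ndarray]]:
    """Loss and exact gradients w.r.t. E0 and each W^k.

    The forward map is linear, so backpropagation is a reverse sweep of
    matrix products through E^{k+1} = P E^k W^k plus the per-layer score
    contributions.
    """
    state = propagate(state, P, hp)
    layers = state.layers
    assert layers is not None
    m, n = state.m, state.n
    K = state.n_layers
    start = 0 if hp.include_layer0 else 1

    t = np.asarray(triples, dtype=np.int64).reshape(-1, 3)
    O = _raw_score(state, include_layer0=hp.include_layer0)
    diff = O[t[:, 0], t[:, 1]] - O[t[:, 0], t[:, 2]]
    loss = float(-np.sum(_log_sigmoid(diff))) + _reg_term(state, hp)

    # dL/dO as a dense m x n matrix; each triple adds g to (a, i), -g to (a, j)
    g = _sigmoid(diff) - 1.0
    G = np.zeros((m, n))
    np.add.at(G, (t[:, 0], t[:, 1]), g)
    np.add.at(G, (t[:, 0], t[:, 2]), -g)

    def layer_score_grad(E_k: np.ndarray) -> np.ndarray:
        # d(sum G*O)/dE_k for the direct score term of layer k
        return np.vstack([G @ E_k[m:], G.T @ E_k[:m]])

    grad_W = [np.zeros_like(w) for w in state.W]
    # backward sweep: B_k = dL/dE^k
    B = layer_score_grad(layers[K]) if K >= start else np.zeros_like(state.E0)
    for k in range(K - 1, -1, -1):
        PE_k = P.P @ layers[k]
        grad_W[k] = PE_k.T @ B
        B = P.P @ (B @ state.W[k].T)  # P symmetric
        if k >= start:
            B += layer_score_grad(layers[k])

    grad_E0 = B + 2.0 * hp.reg_lambda * state.E0
    if hp.shared_weights:
        shared = sum(grad_W) + 2.0 * hp.reg_lambda * state.W[0]
        grad_W = [shared] + [np.zeros_like(shared)] * (K - 1)
    else:
        for k in range(K):
            grad_W[k] += 2.0 * hp.reg_lambda * state.W[k]
    return loss, grad_E0, grad_W


class _Adam:
    """Adam over a flat list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, mm, vv in zip(self.params, grads, self.m, self.v):
            mm *= b1
            mm += (1 - b1) * g
            vv *= b2
            vv += (1 - b2) * g * g
            m_hat = mm / (1 - b1 ** self.t)
            v_hat = vv / (1 - b2 ** self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def sample_bpr_triples(
    ds: AssociationDataset,
    rng: np.random.Generator,
    negatives_per_positive: int = 1,
    forbidden: dict[int, set[int]] | None = None,
) -> list[Triple]:
    """One or more uniformly sampled negatives per observed positive.

    ``forbidden`` maps each ncRNA index to drug indices that may not serve
    as negatives (at minimum its own positives; during cross-validation also
    every test pair). Rejection sampling guarantees j is admissible.
    """
    n = ds.n
    if forbidden is None:
        forbidden = {}
    pos_by_ncrna: dict[int, set[int]] = {}
    for a, i in ds.pairs:
        pos_by_ncrna.setdefault(a, set()).add(i)
    triples: list[Triple] = []
    for a, i in sorted(ds.pairs):
        banned = pos_by_ncrna[a] | forbidden.get(a, set())
        if len(banned) >= n:
            continue  # no admissible negative for this ncRNA
        for _ in range(negatives_per_positive):
            j = int(rng.integers(n))
            while j in banned:
                j = int(rng.integers(n))
            triples.append((a, i, j))
    return triples


def train(
    ds: AssociationDataset,
    hp: Hyperparameters,
    negative_exclude: set[tuple[int, int]] | None = None,
    P: NormalizedAdjacency | None = None,
) -> tuple[ModelState, list[float]]:
    """Train by BPR with Adam; returns the final state and per-epoch losses.

    Each epoch resamples negatives, runs the forward pass, and updates E0
    and every W^k from exact gradients. All randomness flows from
    ``hp.seed`` split into named substreams, so runs are reproducible.
    """
    if not ds.pairs:
        raise ValueError("cannot train on a dataset with no associations")
    rngs = _spawn_rngs(hp.seed)
    if P is None:
        P = normalize(build_adjacency(ds))
    state = init_embeddings(ds.m, ds.n, hp, rng=rngs["init"])

    forbidden: dict[int, set[int]] = {}
    if negative_exclude:
        for a, j in negative_exclude:
            forbidden.setdefault(a, set()).add(j)

    if hp.shared_weights:
        params = [state.E0, state.W[0]]
    else:
        params = [state.E0] + list(state.W)
    opt = _Adam(params, lr=hp.learning_rate)

    history: list[float] = []
    for epoch in range(hp.epochs):
        triples = sample_bpr_triples(
            ds, rngs["sampling"], hp.negatives_per_positive, forbidden
        )
        loss, gE0, gW = bpr_gradients(state, P, triples, hp)
        if not np.isfinite(loss):
            raise TrainingDivergedError(
                f"non-finite loss at epoch {epoch}: {loss}"
            )
        history.append(loss)
        grads = [gE0, gW[0]] if hp.shared_weights else [gE0] + gW
        opt.step(grads)

    return propagate(state, P, hp), history


class LinearResidualGCN(BaseEstimator):
    """Linear residual graph-convolution link predictor, scikit-learn style.

    Embeds ncRNAs and drugs jointly, propagates embeddings K steps over the
    symmetrically normalized bipartite graph with per-layer linear
    transforms, scores pairs by residually accumulated per-layer dot
    products, and trains with the BPR pairwise ranking loss.

    Parameters
    ----------
    n_layers : int, default=4
        Propagation depth K.
    embedding_dim : int, default=32
        Embedding size S.
    init_std : float, default=0.1
        Std of the normal layer-0 initialization.
    reg_lambda : float, default=1e-4
        L2 regularization on E0 and the transforms.
    learning_rate : float, default=1e-3
    n_epochs : int, default=200
    negatives_per_positive : int, default=1
    include_layer0 : bool, default=True
        Include the layer-0 dot product in the residual score.
    shared_weights : bool, default=False
        Share one transform across layers.
    random_state : int, default=0

    Attributes
    ----------
    state_ : ModelState
        Trained embeddings, transforms, and the cached forward pass.
    score_matrix_ : ndarray of shape (m, n)
        Predicted association scores for every (ncRNA, drug) pair.
    loss_history_ : list of float
        Per-epoch BPR loss.
    ncrnas_, drugs_ : list of str
        Entity vocabularies in index order.

    Examples
    --------
    >>> from ncdlink import generate_synthetic, LinearResidualGCN
    >>> sim = generate_synthetic(m=30, n=10, k_blocks=2, seed=0)
    >>> model = LinearResidualGCN(n_epochs=20).fit(sim.dataset)
    >>> model.score_matrix_.shape
    (30, 10)
    """

    def __init__(
        self,
        n_layers: int = 4,
        embedding_dim: int = 32,
        init_std: float = 0.1,
        reg_lambda: float = 1e-4,
        learning_rate: float = 1e-3,
        n_epochs: int = 200,
        negatives_per_positive: int = 1,
        include_layer0: bool = True,
        shared_weights: bool = False,
        random_state: int = 0,
    ):
        self.n_layers = n_layers
        self.embedding_dim = embedding_dim
        self.init_std = init_std
        self.reg_lambda = reg_lambda
        self.learning_rate = learning_rate
        self.n_epochs = n_epochs
        self.negatives_per_positive = negatives_per_positive
        self.include_layer0 = include_layer0
        self.shared_weights = shared_weights
        self.random_state = random_state

    def _hyperparameters(self) -> Hyperparameters:
        return Hyperparameters(
            n_layers=self.n_layers,
            embedding_dim=self.embedding_dim,
            init_std=self.init_std,
            reg_lambda=self.reg_lambda,
            learning_rate=self.learning_rate,
            epochs=self.n_epochs,
            negatives_per_positive=self.negatives_per_positive,
            include_layer0=self.include_layer0,
            shared_weights=self.shared_weights,
            seed=self.random_state,
        )

    def fit(
        self,
        X: AssociationDataset,
        y=None,
        negative_exclude: set[tuple[int, int]] | None = None,
    ) -> "LinearResidualGCN":
        """Train on an :class:`AssociationDataset` of verified positives.

        ``negative_exclude`` lists extra (ncRNA, drug) index pairs that BPR
        sampling must never use as negatives (e.g. held-out test pairs).
        """
        if not isinstance(X, AssociationDataset):
            raise TypeError("X must be an AssociationDataset")
        hp = self._hyperparameters()
        state, history = train(X, hp, negative_exclude=negative_exclude)
        self.state_ = state
        self.loss_history_ = history
        self.score_matrix_ = score(state, include_layer0=hp.include_layer0).O
        self.m_, self.n_ = X.m, X.n
        self.ncrnas_ = list(X.ncrnas)
        self.drugs_ = list(X.drugs)
        return self

    def decision_function(self, pairs: Sequence[tuple[int, int]]) -> np.ndarray:
        """Raw association scores for (ncRNA index, drug index) pairs."""
        self._check_fitted()
        idx = np.asarray(list(pairs), dtype=np.int64).reshape(-1, 2)
        return self.score_matrix_[idx[:, 0], idx[:, 1]]

    def predict(self, pairs: Sequence[tuple[int, int]]) -> np.ndarray:
        """Binary predictions at the default threshold (raw score >= 0)."""
        return (self.decision_function(pairs) >= 0.0).astype(np.int64)

    def predict_scores(self) -> np.ndarray:
        """The full m x n score matrix."""
        self._check_fitted()
        return self.score_matrix_

    def _check_fitted(self) -> None:
        if not hasattr(self, "state_"):
            raise RuntimeError("model is not fitted; call fit() first")
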