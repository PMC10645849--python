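"""k-NN propagation graph, graph autoencoder, and outlier scoring.

The detector reconstructs every patient's (embedding-augmented) feature
vector through a two-weight graph autoencoder,

    Z = LeakyReLU( G · LeakyReLU( G · X · W0 − b0 ) · W1 − b1 ),

where G is the symmetrically normalized k-nearest-neighbour graph over the
patients, D^{-1/2}(A + I)D^{-1/2}. Because propagation mixes each patient
with its neighbours, patients whose risk-factor profile diverges from their
neighbourhood — the rare adverse outcomes — are reconstructed poorly; the
per-patient squared reconstruction error ‖x_i − z_i‖² is the outlier score.

Training minimizes the summed (or mean) squared reconstruction error by
full-batch gradient descent or Adam, with seeded Gaussian initialisation
scaled by 1/sqrt(fan-in). Note on defaults: a step size of 1e-9 is the
published setting and is only sensible against an *unnormalized summed*
loss on a cohort-sized matrix; convergence-sensitive work should use mean
reduction with a correspondingly larger step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .cohort import CohortTable
from .embed import (SkipGramConfig, WalkConfig, combine_embeddings, fastrp_embed,
                    node2vec_embed, patient_embedding_block)
from .kgraph import build_graph

_METHOD_FAMILIES = ("original", "fastrp", "node2vec", "combine")


class GAEError(ValueError):
    pass


class GAEDivergenceError(GAEError):
    def __init__(self, epoch: int):
        super().__init__(f"training diverged (non-finite loss) at epoch {epoch}")
        self.epoch = epoch


@dataclass
class AugmentedFeatures:
    """Standardized risk factors concatenated with the embedding block.

    ``provenance`` tags each column "feature:<name>" or "embedding:<i>".
    Row order matches the cohort table.
    """

    matrix: np.ndarray
    provenance: list[str]

    def __post_init__(self):
        if not np.all(np.isfinite(self.matrix)):
            raise GAEError("non-finite entries in augmented features")
        if self.matrix.shape[1] != len(self.provenance):
            raise GAEError("provenance length mismatch")


@dataclass
class PropagationGraph:
    k: int
    matrix: np.ndarray          # normalized D^-1/2 (A+I) D^-1/2, symmetric
    adjacency: np.ndarray       # unnormalized A + I


@dataclass
class GAEParams:
    W0: np.ndarray
    b0: np.ndarray
    W1: np.ndarray
    b1: np.ndarray
    alpha: float = 0.01

    @property
    def hidden_dim(self) -> int:
        return self.W0.shape[1]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-9
    epochs: int = 500
    optimizer: str = "gradient-descent"
    seed: int = 0
    k: int = 90
    loss_reduction: str = "sum"
    alpha: float = 0.01
    hidden_dim: int | None = None

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise GAEError("learning_rate must be > 0")
        if self.epochs < 1:
            raise GAEError("epochs must be >= 1")
        if self.optimizer not in ("gradient-descent", "adam"):
            raise GAEError(f"unknown optimizer {self.optimizer!r}")
        if self.loss_reduction not in ("sum", "mean"):
            raise GAEError(f"unknown loss_reduction {self.loss_reduction!r}")


@dataclass
class OutlierScores:
    """Per-patient reconstruction errors (higher = more outlying)."""

    errors: np.ndarray
    loss_history: list[float]
    patient_id: list[str] | None = None

    def __post_init__(self):
        if np.any(self.errors < 0):
            raise GAEError("negative reconstruction error")

    def top_quantile_flags(self, q: float = 0.9) -> np.ndarray:
        """Binary outlier calls at a score quantile (explanatory use only)."""
        thr = np.quantile(self.errors, q)
        return (self.errors >= thr).astype(int)


def standardize_features(table: CohortTable) -> np.ndarray:
    """Mean-impute missing cells, then z-score each risk-factor column.

    Constant columns stay zero rather than dividing by a zero deviation.
    """
    X = table.features.to_numpy(dtype=float).copy()
    for j in range(X.shape[1]):
        col = X[:, j]
        m = np.nanmean(col) if not np.all(np.isnan(col)) else 0.0
        col[np.isnan(col)] = m
        sd = col.std()
        X[:, j] = (col - m) / sd if sd > 0 else 0.0
    return X


def augment_features(table: CohortTable, embedding_block: np.ndarray | None = None,
                     standardize_embeddings: bool = True) -> AugmentedFeatures:
    """Concatenate standardized risk factors with a per-patient embedding block."""
    X = standardize_features(table)
    prov = [f"feature:{c}" for c in table.features.columns]
    if embedding_block is not None:
        if embedding_block.shape[0] != table.n:
            raise GAEError("embedding block row count does not match cohort")
        E = np.asarray(embedding_block, dtype=float)
        if standardize_embeddings:
            mu, sd = E.mean(axis=0), E.std(axis=0)
            sd[sd == 0] = 1.0
            E = (E - mu) / sd
        X = np.hstack([X, E])
        prov += [f"embedding:{i}" for i in range(E.shape[1])]
    return AugmentedFeatures(X, prov)


def build_knn_graph(X, k: int) -> PropagationGraph:
    """Symmetrized k-NN graph over rows of X with self-loops, normalized.

    Each row is linked to its k nearest neighbours by Euclidean distance
    (ties broken by row index); the directed graph is symmetrized by union,
    self-loops added, and normalized as D^{-1/2}(A + I)D^{-1/2}.
    """
    M = X.matrix if isinstance(X, AugmentedFeatures) else np.asarray(X, dtype=float)
    n = M.shape[0]
    if k >= n:
        raise GAEError(f"k = {k} must be smaller than n = {n}")
    sq = (M * M).sum(axis=1)
    D2 = sq[:, None] + sq[None, :] - 2.0 * (M @ M.T)
    np.fill_diagonal(D2, np.inf)  # exclude self from neighbour lists
    order = np.argsort(D2, axis=1, kind="stable")[:, :k]
    A = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k)
    A[rows, order.ravel()] = 1.0
    A = np.maximum(A, A.T)
    np.fill_diagonal(A, 1.0)
    deg = A.sum(axis=1)
    dinv = 1.0 / np.sqrt(deg)
    G = A * dinv[:, None] * dinv[None, :]
    return PropagationGraph(k=k, matrix=G, adjacency=A)


def _leaky(h, alpha):
    return np.where(h > 0, h, alpha * h)


def _leaky_grad(h, alpha):
    return np.where(h > 0, 1.0, alpha)


def gae_forward(X: np.ndarray, G: np.ndarray, params: GAEParams) -> np.ndarray:
    """Z = LeakyReLU(G · LeakyReLU(G · X · W0 − b0) · W1 − b1); same shape as X."""
    h1 = G @ X @ params.W0 - params.b0
    a1 = _leaky(h1, params.alpha)
    h2 = G @ a1 @ params.W1 - params.b1
    return _leaky(h2, params.alpha)


def reconstruction_loss(X: np.ndarray, Z: np.ndarray, reduction: str = "sum") -> float:
    if X.shape != Z.shape:
        raise GAEError(f"shape mismatch {X.shape} vs {Z.shape}")
    sq = (X - Z) ** 2
    return float(sq.sum() if reduction == "sum" else sq.mean())


def init_params(d_in: int, hidden_dim: int | None, alpha: float,
                rng: np.random.Generator) -> GAEParams:
    h = hidden_dim or math.ceil(d_in / 2)
    W0 = rng.standard_normal((d_in, h)) / math.sqrt(d_in)
    W1 = rng.standard_normal((h, d_in)) / math.sqrt(h)
    return GAEParams(W0=W0, b0=np.zeros(h), W1=W1, b1=np.zeros(d_in), alpha=alpha)


def train_gae(X, G, config: TrainConfig) -> tuple[GAEParams, OutlierScores]:
    """Full-batch training of the autoencoder on a fixed propagation graph.

    Returns the final parameters and per-patient errors e_i = ‖x_i − z_i‖²
    along with the per-epoch loss history. Raises
    :class:`GAEDivergenceError` the first epoch the loss becomes non-finite.
    """
    Xm = X.matrix if isinstance(X, AugmentedFeatures) else np.asarray(X, dtype=float)
    Gm = G.matrix if isinstance(G, PropagationGraph) else np.asarray(G, dtype=float)
    n, d_in = Xm.shape
    if n < 2:
        raise GAEError("need at least two samples")
    rng = np.random.default_rng(config.seed)
    params = init_params(d_in, config.hidden_dim, config.alpha, rng)

    scale = 1.0 if config.loss_reduction == "sum" else 1.0 / Xm.size
    lr = config.learning_rate
    adam = config.optimizer == "adam"
    if adam:
        mom = [np.zeros_like(p) for p in (params.W0, params.b0, params.W1, params.b1)]
        vel = [np.zeros_like(p) for p in (params.W0, params.b0, params.W1, params.b1)]
        beta1, beta2, eps, t = 0.9, 0.999, 1e-8, 0

    history: list[float] = []
    for epoch in range(config.epochs):
        GX = Gm @ Xm
        h1 = GX @ params.W0 - params.b0
        a1 = _leaky(h1, params.alpha)
        Ga1 = Gm @ a1
        h2 = Ga1 @ params.W1 - params.b1
        Z = _leaky(h2, params.alpha)

        loss = reconstruction_loss(Xm, Z, config.loss_reduction)
        if not np.isfinite(loss):
            raise GAEDivergenceError(epoch)
        history.append(loss)

        dZ = 2.0 * (Z - Xm) * scale
        dh2 = dZ * _leaky_grad(h2, params.alpha)
        dW1 = Ga1.T @ dh2
        db1 = -dh2.sum(axis=0)
        da1 = Gm.T @ (dh2 @ params.W1.T)
        dh1 = da1 * _leaky_grad(h1, params.alpha)
        dW0 = GX.T @ dh1
        db0 = -dh1.sum(axis=0)

        grads = (dW0, db0, dW1, db1)
        tensors = (params.W0, params.b0, params.W1, params.b1)
        if adam:
            t += 1
            for i, (p, g) in enumerate(zip(tensors, grads)):
                mom[i] = beta1 * mom[i] + (1 - beta1) * g
                vel[i] = beta2 * vel[i] + (1 - beta2) * g * g
                mhat = mom[i] / (1 - beta1 ** t)
                vhat = vel[i] / (1 - beta2 ** t)
                p -= lr * mhat / (np.sqrt(vhat) + eps)
        else:
            for p, g in zip(tensors, grads):
                p -= lr * g

    Z = gae_forward(Xm, Gm, params)
    final = reconstruction_loss(Xm, Z, config.loss_reduction)
    if not np.isfinite(final):
        raise GAEDivergenceError(config.epochs)
    history.append(final)
    errors = ((Xm - Z) ** 2).sum(axis=1)
    return params, OutlierScores(errors=errors, loss_history=history)


def parse_method_spec(method_spec: str) -> tuple[str, int | None]:
    """Split "fastrp-32" → ("fastrp", 32); "original" has no dimension."""
    if method_spec == "original":
        return "original", None
    try:
        family, d = method_spec.rsplit("-", 1)
        dim = int(d)
    except ValueError:
        raise GAEError(f"bad method spec {method_spec!r}") from None
    if family not in _METHOD_FAMILIES or family == "original":
        raise GAEError(f"unknown method family {family!r}")
    return family, dim


def compute_patient_embeddings(table: CohortTable, family: str, dim: int,
                               walk_config: WalkConfig, sg_config: SkipGramConfig,
                               include_outcome: bool = False) -> np.ndarray:
    """Knowledge graph → node embeddings → per-patient block, for one method."""
    g = build_graph(table, include_outcome=include_outcome)
    if family == "fastrp":
        em = fastrp_embed(g, dim, seed=walk_config.seed)
    elif family == "node2vec":
        em = node2vec_embed(g, walk_config, replace(sg_config, dim=dim))
    elif family == "combine":
        ef = fastrp_embed(g, dim, seed=walk_config.seed)
        en = node2vec_embed(g, walk_config, replace(sg_config, dim=dim))
        em = combine_embeddings(ef, en)
    else:
        raise GAEError(f"unknown embedding family {family!r}")
    return patient_embedding_block(em, table)


@dataclass(frozen=True)
class ScoreConfig:
    """Everything one end-to-end scoring run needs, fanned out from one seed."""

    train: TrainConfig = field(default_factory=TrainConfig)
    walk: WalkConfig = field(default_factory=WalkConfig)
    skipgram: SkipGramConfig = field(default_factory=SkipGramConfig)
    include_outcome: bool = False
    seed: int = 0

    def reseeded(self, seed: int) -> "ScoreConfig":
        """Derive per-stage seeds from one master seed (documented fan-out)."""
        ss = np.random.SeedSequence(seed)
        walk_s, sg_s, gae_s = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3))
        return ScoreConfig(
            train=replace(self.train, seed=gae_s),
            walk=replace(self.walk, seed=walk_s),
            skipgram=replace(self.skipgram, seed=sg_s),
            include_outcome=self.include_outcome,
            seed=seed,
        )


def score_outliers(table: CohortTable, method_spec: str,
                   config: ScoreConfig | None = None) -> OutlierScores:
    """End-to-end reconstruction-error scoring of one cohort.

    method_spec ∈ {original} ∪ {fastrp, node2vec, combine} × {-16, -32, -64}
    (any positive dimension is accepted). "original" skips the graph and
    embeds nothing: the autoencoder sees the standardized risk factors only.
    """
    config = (config or ScoreConfig()).reseeded((config or ScoreConfig()).seed)
    family, dim = parse_method_spec(method_spec)
    if family == "original":
        block = None
    else:
        block = compute_patient_embeddings(table, family, dim, config.walk,
                                           config.skipgram, config.include_outcome)
    X = augment_features(table, block)
    k = min(config.train.k, table.n - 1)
    G = build_knn_graph(X, k)
    _, scores = train_gae(X, G, config.train)
    scores.patient_id = list(table.patient_id)
    return scores
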