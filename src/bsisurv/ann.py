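"""Ensembles of small neural networks trained to maximize the C-index.

Each ensemble member is a one-hidden-layer perceptron (default 3 tanh
units, linear output) producing a scalar prognostic index. Members are
trained on bootstrap bags of the training set (bagging) to directly
maximize Harrell's C on the bag. Because the exact C-index is a step
function of the weights, the default optimizer ascends a pairwise
sigmoid-smoothed surrogate,

    L = mean over usable pairs (i, j) of sigmoid((s_i - s_j) / tau),

with Adam, while the exact bag C-index — evaluated at checkpoints — picks
the weights that are finally kept. A seeded evolution-strategy backend
that climbs the exact C directly is available as an alternative. The
ensemble's prognostic index is the mean of member outputs; its only
contract is the ordering of patients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .concordance import ConcordanceUndefined, c_index
from .normalize import NormalizationParams, apply_normalizer, fit_normalizer


@dataclass(frozen=True)
class AnnConfig:
    """Hyperparameters of the ensemble trainer."""

    members: int = 15
    hidden: int = 3
    tau: float = 0.1
    iterations: int = 500
    learning_rate: float = 0.05
    max_pairs: int = 10_000
    eval_every: int = 10
    backend: str = "gradient"  # or "evolution"
    es_population: int = 12
    es_sigma: float = 0.2
    init_scale: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backend not in ("gradient", "evolution"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.members < 1 or self.hidden < 1:
            raise ValueError("members and hidden must be >= 1")


@dataclass
class AnnMember:
    """One trained network: weights, its bootstrap bag, and the search trace."""

    W1: np.ndarray  # (p, hidden)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (hidden,)
    b2: float
    bag_indices: np.ndarray
    trace: np.ndarray  # best-so-far exact bag C at each checkpoint

    @property
    def input_dim(self) -> int:
        return self.W1.shape[0]

    def scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[1] != self.input_dim:
            raise ValueError(f"expected {self.input_dim} columns, got {X.shape[1]}")
        return np.tanh(X @ self.W1 + self.b1) @ self.w2 + self.b2


@dataclass
class EnsembleModel:
    """A bag-trained ensemble with its stored normalization."""

    members: list[AnnMember]
    config: AnnConfig
    normalization: NormalizationParams | None = None
    aggregation: str = "mean"

    @property
    def input_dim(self) -> int:
        return self.members[0].input_dim


def _usable_pairs(time: np.ndarray, event: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices (i, j) with time_i < time_j and event_i = 1."""
    lt = time[:, None] < time[None, :]
    usable = lt & (event[:, None] == 1)
    return np.nonzero(usable)


def _pack(W1, b1, w2, b2) -> np.ndarray:
    return np.concatenate([W1.ravel(), b1, w2, [b2]])


def _unpack(theta: np.ndarray, p: int, h: int):
    W1 = theta[: p * h].reshape(p, h)
    b1 = theta[p * h : p * h + h]
    w2 = theta[p * h + h : p * h + 2 * h]
    b2 = float(theta[-1])
    return W1, b1, w2, b2


def _scores(theta: np.ndarray, X: np.ndarray, p: int, h: int) -> np.ndarray:
    W1, b1, w2, b2 = _unpack(theta, p, h)
    return np.tanh(X @ W1 + b1) @ w2 + b2


def _exact_c(theta, X, time, event, p, h) -> float:
    try:
        return c_index(_scores(theta, X, p, h), time, event).value
    except ConcordanceUndefined:
        return 0.5


def train_member(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    rng: np.random.Generator,
    config: AnnConfig | None = None,
) -> AnnMember:
    """Train one member on a fresh bootstrap bag.

    ``X`` must already be standardized (the ensemble trainer handles
    that). Degenerate bags (fewer than 2 events, no usable pair) are
    redrawn a bounded number of times.
    """
    config = config or AnnConfig()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    time = np.asarray(time, dtype=float).ravel()
    event = np.asarray(event).astype(int).ravel()
    n, p = X.shape
    h = config.hidden

    bag = None
    for _ in range(20):
        cand = rng.integers(0, n, size=n)
        tb, eb = time[cand], event[cand]
        if eb.sum() >= 2:
            ii, jj = _usable_pairs(tb, eb)
            if ii.size > 0:
                bag = cand
                break
    if bag is None:
        raise ValueError("could not draw a bag with >= 2 events and a usable pair")
    Xb, tb, eb = X[bag], time[bag], event[bag]

    if ii.size > config.max_pairs:
        keep = rng.choice(ii.size, size=config.max_pairs, replace=False)
        ii, jj = ii[keep], jj[keep]

    theta = rng.uniform(-config.init_scale, config.init_scale, size=p * h + 2 * h + 1)
    best_theta = theta.copy()
    best_c = _exact_c(theta, Xb, tb, eb, p, h)
    trace = [best_c]

    if config.backend == "gradient":
        m = np.zeros_like(theta)
        v = np.zeros_like(theta)
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        P = ii.size
        for it in range(1, config.iterations + 1):
            W1, b1, w2, b2 = _unpack(theta, p, h)
            A = Xb @ W1 + b1
            H = np.tanh(A)
            s = H @ w2 + b2
            d = (s[ii] - s[jj]) / config.tau
            sig = 1.0 / (1.0 + np.exp(-np.clip(d, -60, 60)))
            g_pair = sig * (1.0 - sig) / (config.tau * P)
            ds = np.bincount(ii, weights=g_pair, minlength=n) - np.bincount(
                jj, weights=g_pair, minlength=n
            )
            dw2 = H.T @ ds
            db2 = ds.sum()
            dA = (ds[:, None] * w2) * (1.0 - H**2)
            dW1 = Xb.T @ dA
            db1 = dA.sum(axis=0)
            grad = _pack(dW1, db1, dw2, db2)
            # Adam ascent
            m = beta1 * m + (1 - beta1) * grad
            v = beta2 * v + (1 - beta2) * grad**2
            mh = m / (1 - beta1**it)
            vh = v / (1 - beta2**it)
            theta = theta + config.learning_rate * mh / (np.sqrt(vh) + eps)
            if it % config.eval_every == 0 or it == config.iterations:
                c = _exact_c(theta, Xb, tb, eb, p, h)
                if c > best_c:
                    best_c = c
                    best_theta = theta.copy()
                trace.append(best_c)
    else:  # evolution strategy on the exact bag C-index
        generations = max(1, config.iterations // 10)
        for _ in range(generations):
            cands = best_theta + config.es_sigma * rng.standard_normal(
                (config.es_population, theta.shape[0])
            )
            cs = [_exact_c(cand, Xb, tb, eb, p, h) for cand in cands]
            k = int(np.argmax(cs))
            if cs[k] > best_c:
                best_c = cs[k]
                best_theta = cands[k].copy()
            trace.append(best_c)

    W1, b1, w2, b2 = _unpack(best_theta, p, h)
    return AnnMember(
        W1=W1, b1=b1, w2=w2, b2=b2, bag_indices=bag, trace=np.asarray(trace, dtype=float)
    )


def train_ensemble(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    config: AnnConfig | None = None,
    *,
    normalize: bool = True,
) -> EnsembleModel:
    """Train the full ensemble from a seeded member stream.

    With ``normalize=True`` covariates are standardized internally and the
    parameters stored on the model for re-application at prediction time.
    """
    config = config or AnnConfig()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    norm = None
    if normalize:
        norm = fit_normalizer(X)
        X = apply_normalizer(norm, X)
    seeds = np.random.SeedSequence(config.seed).spawn(config.members)
    members = [
        train_member(X, time, event, np.random.default_rng(s), config) for s in seeds
    ]
    return EnsembleModel(members=members, config=config, normalization=norm)


def predict_index(model: EnsembleModel, X: np.ndarray) -> np.ndarray:
    """Ensemble prognostic index: mean of member outputs (higher = worse)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != model.input_dim:
        raise ValueError(f"expected {model.input_dim} columns, got {X.shape[1]}")
    if model.normalization is not None:
        X = apply_normalizer(model.normalization, X)
    return np.mean([m.scores(X) for m in model.members], axis=0)


def knockout_importance(
    model: EnsembleModel,
    X_val: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
) -> np.ndarray:
    """Per-covariate drop in validation C when that input is neutralized.

    Each column in turn is replaced by the training mean (zero after
    standardization) with no retraining; the importance is
    ``C(full) - C(knocked out)``.
    """
    X_val = np.asarray(X_val, dtype=float)
    if X_val.ndim == 1:
        X_val = X_val[:, None]
    full = c_index(predict_index(model, X_val), time, event).value
    drops = np.empty(X_val.shape[1])
    for j in range(X_val.shape[1]):
        Xk = X_val.copy()
        Xk[:, j] = model.normalization.mean[j] if model.normalization is not None else 0.0
        try:
            ck = c_index(predict_index(model, Xk), time, event).value
        except ConcordanceUndefined:
            ck = 0.5
        drops[j] = full - ck
    return drops
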