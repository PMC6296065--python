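"""Cost-sensitive training of the masked network.

Each epoch (i) draws a random sub-network by dropping pathway- and
hidden-layer nodes, (ii) takes one full-batch optimizer step on the
sub-network's parameters using the Mean False Error (MFE) objective —
cross-entropy averaged *within* each class and summed across classes, so
a rare class contributes as much gradient as a common one — and then
(iii) re-optimizes the sparsity masks of the pathway→hidden and
hidden→output layers.  The loop stops at ``max_epochs`` or when the
monitored full-network training loss stops improving for ``patience``
epochs.

PASNet's update rule is described both as a plain gradient step with
multiplicative ``(1 − ηλ)`` weight decay and as Adam with an additive
``λW`` L2 gradient term.  Both are implemented behind
``TrainConfig.optimizer`` (``"sgd_decay"`` / ``"adam"``); Adam is the
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import sparse_coding
from .network import NetworkState, forward, initialize, sigmoid, softmax
from .pathways import BiadjacencyMatrix

__all__ = [
    "ClassPartitionedCost",
    "TrainConfig",
    "mfe_cost",
    "per_class_gradients",
    "select_subnetwork",
    "fit",
]

_EPS = 1e-12  # clamp for log(posterior)


@dataclass
class ClassPartitionedCost:
    """MFE cost split by class: L = Σ_k C_k + (λ/2)·Σ active w²."""

    per_class_costs: np.ndarray
    class_sizes: np.ndarray
    l2: float
    total: float


@dataclass
class TrainConfig:
    """Training hyper-parameters.

    Defaults are PASNet's published values: learning rate η = 1e-4, L2
    strength λ = 3e-4, node drop rates 0.8 (pathway layer) and 0.7
    (hidden layer), Adam optimizer, full-batch epochs, sparse coding
    re-run on layers 1 and 2 after every epoch.
    """

    learning_rate: float = 1e-4
    l2: float = 3e-4
    drop_rates: tuple[float, float] = (0.8, 0.7)
    max_epochs: int = 5000
    patience: int = 100
    min_improvement: float = 0.0
    sparsity_grid: tuple[float, ...] = sparse_coding.DEFAULT_GRID
    fine_step: float = 0.5
    sparsity_warmup: int = 0  # epochs of dense training before sparse coding
    seed: int = 0
    optimizer: str = "adam"  # "adam" | "sgd_decay"
    loss: str = "mfe"  # "mfe" | "pooled"
    hidden_size: int = 100
    adam_betas: tuple[float, float] = (0.9, 0.999)
    adam_eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.l2 < 0:
            raise ValueError("l2 must be non-negative")
        if not all(0.0 <= r < 1.0 for r in self.drop_rates):
            raise ValueError("drop rates must lie in [0, 1)")
        if self.optimizer not in ("adam", "sgd_decay"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.loss not in ("mfe", "pooled"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if any(not 0 <= s <= 100 for s in self.sparsity_grid):
            raise ValueError("sparsity grid levels must lie in [0, 100]")


def _one_hot(y: np.ndarray, K: int) -> np.ndarray:
    Y = np.zeros((len(y), K))
    Y[np.arange(len(y)), y] = 1.0
    return Y


def _sample_weights(y: np.ndarray, K: int, scheme: str) -> np.ndarray:
    """Per-sample weights making Σ_i w_i·CE_i equal Σ_k C_k (mfe) or the
    pooled mean cross-entropy (pooled)."""
    if scheme == "pooled":
        return np.full(len(y), 1.0 / len(y))
    w = np.empty(len(y))
    for k in range(K):
        in_k = y == k
        n_k = int(in_k.sum())
        if n_k:
            w[in_k] = 1.0 / n_k
    return w


def _l2_penalty(state: NetworkState, lam: float) -> float:
    # the regularizer ranges over active (unmasked) weights only
    return 0.5 * lam * sum(float((W * M).__pow__(2).sum())
                           for W, M in zip(state.weights, state.masks))


def mfe_cost(
    posteriors: np.ndarray,
    y: np.ndarray,
    state: NetworkState | None = None,
    lam: float = 0.0,
) -> ClassPartitionedCost:
    """Mean-false-error cost: per-class mean cross-entropy, summed.

    ``C_k`` is the mean cross-entropy over samples of class ``k`` (one-hot
    targets against the softmax posterior); the total adds the L2 penalty
    over the network's active weights when ``state`` and ``lam`` are given.
    """
    posteriors = np.asarray(posteriors, dtype=float)
    y = np.asarray(y, dtype=int)
    K = posteriors.shape[1]
    ce = -np.log(np.clip(posteriors[np.arange(len(y)), y], _EPS, None))
    costs = np.zeros(K)
    sizes = np.zeros(K, dtype=int)
    for k in range(K):
        in_k = y == k
        sizes[k] = int(in_k.sum())
        if sizes[k]:
            costs[k] = float(ce[in_k].mean())
    l2 = _l2_penalty(state, lam) if (state is not None and lam > 0) else 0.0
    return ClassPartitionedCost(costs, sizes, l2, float(costs.sum() + l2))


def select_subnetwork(
    n_pathways: int,
    n_hidden: int,
    drop_rates: tuple[float, float],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw node keep-indicators for the two intermediate layers.

    Independent Bernoulli(1 − rate) per node; a layer with every node
    dropped is redrawn so the sub-network is never empty.
    """
    keeps = []
    for size, rate in zip((n_pathways, n_hidden), drop_rates):
        keep = (rng.random(size) >= rate).astype(float)
        while keep.sum() == 0:
            keep = (rng.random(size) >= rate).astype(float)
        keeps.append(keep)
    return keeps[0], keeps[1]


def per_class_gradients(
    X: np.ndarray,
    y: np.ndarray,
    state: NetworkState,
    dropout_masks: tuple[np.ndarray, np.ndarray] | None = None,
    drop_rates: tuple[float, float] = (0.0, 0.0),
    lam: float = 0.0,
    loss: str = "mfe",
    include_l2: bool = True,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Analytic gradients of Σ_k ∂C_k/∂θ via backpropagation.

    Each sample is weighted by the reciprocal of its class size, so the
    result is the gradient of the class-partitioned (MFE) objective.
    Masked connections and dropout-dropped nodes receive exactly zero
    gradient.  With ``include_l2`` the additive ``λ·(W⋆M)`` term is added
    (the Adam convention); ``sgd_decay`` applies decay multiplicatively in
    the update instead and calls this with ``include_l2=False``.
    """
    y = np.asarray(y, dtype=int)
    K = state.n_classes
    trace = forward(X, state, dropout_masks, drop_rates)
    _, h1, h2, P = trace.layer_outputs
    Y = _one_hot(y, K)
    w = _sample_weights(y, K, loss)

    W0a, W1a, W2a = state.active_weights()
    M0, M1, M2 = state.masks

    delta3 = (P - Y) * w[:, None]                      # d(ΣC_k)/d logits
    gW2 = (delta3.T @ h2) * M2
    gb2 = delta3.sum(axis=0)

    d_h2 = delta3 @ W2a
    if dropout_masks is not None:
        d_h2 = d_h2 * dropout_masks[1] / (1.0 - drop_rates[1])
        h2_raw = h2 * np.where(dropout_masks[1] > 0, 1.0 - drop_rates[1], 1.0)
    else:
        h2_raw = h2
    delta2 = d_h2 * h2_raw * (1.0 - h2_raw)
    gW1 = (delta2.T @ h1) * M1
    gb1 = delta2.sum(axis=0)

    d_h1 = delta2 @ W1a
    if dropout_masks is not None:
        d_h1 = d_h1 * dropout_masks[0] / (1.0 - drop_rates[0])
        h1_raw = h1 * np.where(dropout_masks[0] > 0, 1.0 - drop_rates[0], 1.0)
    else:
        h1_raw = h1
    delta1 = d_h1 * h1_raw * (1.0 - h1_raw)
    gW0 = (delta1.T @ X) * M0
    gb0 = delta1.sum(axis=0)

    gW = [gW0, gW1, gW2]
    gb = [gb0, gb1, gb2]
    if include_l2 and lam > 0:
        for g, W, M in zip(gW, state.weights, state.masks):
            g += lam * W * M
    for i, g in enumerate(gW + gb):
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite gradient in layer {i % 3}")
    return gW, gb


def _update_allow(
    state: NetworkState, keep_p: np.ndarray, keep_h: np.ndarray
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Binary masks of parameters belonging to the current sub-network."""
    M0, M1, M2 = state.masks
    aW = [
        M0 * keep_p[:, None],
        M1 * keep_h[:, None] * keep_p[None, :],
        M2 * keep_h[None, :],
    ]
    ab = [keep_p, keep_h, np.ones(state.n_classes)]
    return aW, ab


class _Adam:
    """Elementwise Adam with moments touched only inside the sub-network."""

    def __init__(self, shapes_W, shapes_b, betas, eps):
        self.mW = [np.zeros(s) for s in shapes_W]
        self.vW = [np.zeros(s) for s in shapes_W]
        self.mb = [np.zeros(s) for s in shapes_b]
        self.vb = [np.zeros(s) for s in shapes_b]
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0

    def step(self, state, gW, gb, allowW, allowb, lr):
        self.t += 1
        c1 = 1.0 - self.b1 ** self.t
        c2 = 1.0 - self.b2 ** self.t
        for W, g, a, m, v in zip(state.weights, gW, allowW, self.mW, self.vW):
            m[a > 0] = self.b1 * m[a > 0] + (1 - self.b1) * g[a > 0]
            v[a > 0] = self.b2 * v[a > 0] + (1 - self.b2) * g[a > 0] ** 2
            W[a > 0] -= lr * (m[a > 0] / c1) / (np.sqrt(v[a > 0] / c2) + self.eps)
        for b, g, a, m, v in zip(state.biases, gb, allowb, self.mb, self.vb):
            m[a > 0] = self.b1 * m[a > 0] + (1 - self.b1) * g[a > 0]
            v[a > 0] = self.b2 * v[a > 0] + (1 - self.b2) * g[a > 0] ** 2
            b[a > 0] -= lr * (m[a > 0] / c1) / (np.sqrt(v[a > 0] / c2) + self.eps)


def _constant_floor(y: np.ndarray, K: int, scheme: str) -> float:
    """Best achievable data cost of a constant-posterior classifier."""
    if scheme == "pooled":
        pri = np.bincount(y, minlength=K) / len(y)
        pri = pri[pri > 0]
        return float(-(pri * np.log(pri)).sum())
    return K * np.log(K)


def _monitor_loss(X, y, state, lam, loss) -> tuple[float, float, np.ndarray]:
    """Full-network (dropout-free) loss: total, data term, per-class costs."""
    trace = forward(X, state)
    cost = mfe_cost(trace.posterior, y, state, lam)
    if loss == "pooled":
        w = _sample_weights(y, len(cost.per_class_costs), "pooled")
        ce = -np.log(np.clip(trace.posterior[np.arange(len(y)), y], _EPS, None))
        data = float((w * ce).sum())
    else:
        data = float(cost.per_class_costs.sum())
    return data + cost.l2, data, cost.per_class_costs


def fit(
    X: np.ndarray,
    y: np.ndarray,
    A: BiadjacencyMatrix | np.ndarray,
    config: TrainConfig | None = None,
) -> tuple[NetworkState, pd.DataFrame]:
    """Train the network with alternating sub-network steps and sparse coding.

    Returns the trained state and a per-epoch log (monitored loss, the
    per-layer optimal sparsity levels ``S*``, and the per-class costs).
    The gene→pathway mask is the biadjacency matrix throughout.
    """
    config = config or TrainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training requires at least two classes")
    K = int(classes.max()) + 1

    rng = np.random.default_rng(config.seed)
    state = initialize(A, config.hidden_size, K, rng)
    records: list[dict] = []
    best = np.inf
    stale = 0
    floor = _constant_floor(y, K, config.loss)
    prev_data_cost = np.inf

    for epoch in range(config.max_epochs):
        keep_p, keep_h = select_subnetwork(
            state.n_pathways, state.hidden_size, config.drop_rates, rng
        )
        dropout_masks = (keep_p, keep_h)
        allowW, allowb = _update_allow(state, keep_p, keep_h)

        if config.optimizer == "adam":
            if epoch == 0:
                opt = _Adam(
                    [W.shape for W in state.weights],
                    [b.shape for b in state.biases],
                    config.adam_betas,
                    config.adam_eps,
                )
            gW, gb = per_class_gradients(
                X, y, state, dropout_masks, config.drop_rates,
                config.l2, config.loss, include_l2=True,
            )
            gW = [g * a for g, a in zip(gW, allowW)]
            gb = [g * a for g, a in zip(gb, allowb)]
            opt.step(state, gW, gb, allowW, allowb, config.learning_rate)
        else:  # plain gradient step with multiplicative (1 − ηλ) decay
            gW, gb = per_class_gradients(
                X, y, state, dropout_masks, config.drop_rates,
                config.l2, config.loss, include_l2=False,
            )
            eta, lam = config.learning_rate, config.l2
            for W, g, a in zip(state.weights, gW, allowW):
                W[a > 0] = (1 - eta * lam) * W[a > 0] - eta * g[a > 0]
            for b, g, a in zip(state.biases, gb, allowb):
                b[a > 0] -= eta * g[a > 0]

        # per-layer sparsity re-optimization on the sub-network; pathway
        # activations do not depend on the upper-layer masks, so they are
        # computed once per epoch and reused across candidate levels
        optima = {1: np.nan, 2: np.nan}
        rp, rh = config.drop_rates
        # Sparse coding is applied once the network beats the best
        # constant-posterior classifier: while the training cost still
        # exceeds that floor, "connections that do not contribute to
        # minimizing the loss" is ill-defined (dropping every connection
        # reaches the floor too, so the search collapses to S* = 100 and
        # severs the network before it has learned anything).
        if epoch >= config.sparsity_warmup and prev_data_cost < floor:
            W0, W1, W2 = state.weights
            b0, b1, b2 = state.biases
            h1c = sigmoid(X @ (W0 * state.masks[0]).T + b0) * keep_p / (1.0 - rp)

            def data_cost(P: np.ndarray) -> float:
                ce = -np.log(np.clip(P[np.arange(len(y)), y], _EPS, None))
                return float((_sample_weights(y, K, config.loss) * ce).sum())

            def cost_layer1(S: float) -> float:
                M1c = sparse_coding.build_mask(W1, S)
                h2 = sigmoid(h1c @ (W1 * M1c).T + b1) * keep_h / (1.0 - rh)
                return data_cost(softmax(h2 @ (W2 * state.masks[2]).T + b2))

            res1 = sparse_coding.apply(
                state, 1, cost_layer1, config.sparsity_grid, config.fine_step
            )
            optima[1] = res1.optimum

            h2c = sigmoid(h1c @ (W1 * state.masks[1]).T + b1) * keep_h / (1.0 - rh)

            def cost_layer2(S: float) -> float:
                M2c = sparse_coding.build_mask(W2, S)
                return data_cost(softmax(h2c @ (W2 * M2c).T + b2))

            res2 = sparse_coding.apply(
                state, 2, cost_layer2, config.sparsity_grid, config.fine_step
            )
            optima[2] = res2.optimum
        else:
            # below the floor the upper layers stay fully connected, as
            # at initialization; this also undoes a severing S* = 100
            # picked on an essentially flat cost curve, which would
            # otherwise block gradient flow permanently
            state.masks[1] = np.ones_like(state.weights[1])
            state.masks[2] = np.ones_like(state.weights[2])

        loss, prev_data_cost, per_class = _monitor_loss(
            X, y, state, config.l2, config.loss
        )
        if not np.isfinite(loss):
            raise RuntimeError(f"training diverged at epoch {epoch}")
        records.append(
            {
                "epoch": epoch,
                "loss": loss,
                "S1": optima[1],
                "S2": optima[2],
                **{f"C_{k}": per_class[k] for k in range(K)},
            }
        )
        if loss < best - config.min_improvement:
            best = loss
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break

    return state, pd.DataFrame.from_records(records)
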