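"""Masked four-layer network: gene → pathway → hidden → output.

Every layer computes ``h_next = a((W ⋆ M) h + b)`` where ``⋆`` is the
elementwise product with a binary mask.  The gene→pathway mask ``M(0)``
is the pathway biadjacency matrix ``A`` and never changes; the other
masks start fully connected and are rewritten by sparse coding during
training.  Intermediate activations are sigmoids; the output layer is a
softmax over the clinical outcome classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from os import PathLike

import numpy as np

from .pathways import BiadjacencyMatrix

__all__ = ["NetworkState", "ForwardTrace", "initialize", "forward", "sigmoid", "softmax"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    # piecewise form avoids overflow in exp for large |z|
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class NetworkState:
    """Weights, biases and masks of the three connection layers.

    Shapes: ``W[0]`` n_pathways × n_genes, ``W[1]`` hidden × n_pathways,
    ``W[2]`` n_classes × hidden; masks are congruent binary matrices with
    ``masks[0]`` pinned to the biadjacency matrix ``A``.
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    masks: list[np.ndarray]
    pathway_names: list[str] = field(default_factory=list)
    gene_names: list[str] = field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return self.weights[0].shape[1]

    @property
    def n_pathways(self) -> int:
        return self.weights[0].shape[0]

    @property
    def hidden_size(self) -> int:
        return self.weights[1].shape[0]

    @property
    def n_classes(self) -> int:
        return self.weights[2].shape[0]

    def active_weights(self) -> list[np.ndarray]:
        """Masked (effective) weight matrices ``W ⋆ M``."""
        return [W * M for W, M in zip(self.weights, self.masks)]

    def copy(self) -> "NetworkState":
        return NetworkState(
            [W.copy() for W in self.weights],
            [b.copy() for b in self.biases],
            [M.copy() for M in self.masks],
            list(self.pathway_names),
            list(self.gene_names),
        )

    def save(self, path: str | PathLike) -> None:
        """Serialize to an .npz checkpoint (weights, biases, masks, names)."""
        np.savez(
            path,
            **{f"W{i}": W for i, W in enumerate(self.weights)},
            **{f"b{i}": b for i, b in enumerate(self.biases)},
            **{f"M{i}": M for i, M in enumerate(self.masks)},
            pathway_names=np.array(self.pathway_names, dtype=object),
            gene_names=np.array(self.gene_names, dtype=object),
        )

    @classmethod
    def load(cls, path: str | PathLike) -> "NetworkState":
        z = np.load(path, allow_pickle=True)
        return cls(
            [z[f"W{i}"] for i in range(3)],
            [z[f"b{i}"] for i in range(3)],
            [z[f"M{i}"] for i in range(3)],
            list(z["pathway_names"]),
            list(z["gene_names"]),
        )


@dataclass
class ForwardTrace:
    """Per-layer outputs of a forward pass.

    ``layer_outputs[0]`` is the input, [1] pathway activations, [2]
    hidden activations, [3] the softmax posterior (rows sum to one).
    """

    layer_outputs: list[np.ndarray]

    @property
    def posterior(self) -> np.ndarray:
        return self.layer_outputs[3]


def initialize(
    A: BiadjacencyMatrix | np.ndarray,
    hidden_size: int,
    n_classes: int = 2,
    seed: int | np.random.Generator = 0,
) -> NetworkState:
    """Random normal initialization respecting the pathway mask.

    Weights are standard-normal draws scaled by 1/√fan-in — for a
    pathway node the fan-in is its number of member genes, for hidden
    and output nodes the previous layer's width — so pre-activations
    start at unit scale instead of saturating the sigmoids.  Biases are
    standard normal.  Gene→pathway weights where ``A`` is zero are set
    to exactly zero; the pathway→hidden and hidden→output layers start
    fully connected (all-ones masks).
    """
    if hidden_size < 1:
        raise ValueError("hidden_size must be >= 1")
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if isinstance(A, BiadjacencyMatrix):
        pathway_names, gene_names = A.pathway_names, A.gene_names
        A = A.matrix
    else:
        A = np.asarray(A)
        pathway_names, gene_names = [], []
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n, m = A.shape
    A01 = (A != 0).astype(float)
    fan0 = np.maximum(A01.sum(axis=1, keepdims=True), 1.0)
    W0 = rng.standard_normal((n, m)) * A01 / np.sqrt(fan0)
    W1 = rng.standard_normal((hidden_size, n)) / np.sqrt(n)
    W2 = rng.standard_normal((n_classes, hidden_size)) / np.sqrt(hidden_size)
    biases = [rng.standard_normal(n), rng.standard_normal(hidden_size),
              rng.standard_normal(n_classes)]
    masks = [A01, np.ones_like(W1), np.ones_like(W2)]
    return NetworkState([W0, W1, W2], biases, masks, list(pathway_names), list(gene_names))


def forward(
    X: np.ndarray,
    state: NetworkState,
    dropout_masks: tuple[np.ndarray, np.ndarray] | None = None,
    drop_rates: tuple[float, float] = (0.0, 0.0),
) -> ForwardTrace:
    """Forward pass over a batch (rows are samples).

    When ``dropout_masks`` (pathway-node and hidden-node keep indicator
    vectors) are given, dropped nodes output zero and survivors are
    scaled by 1/(1 − drop_rate) — inverted dropout, so no rescaling is
    needed at prediction time.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != state.n_genes:
        raise ValueError(
            f"X must be 2-D with {state.n_genes} gene columns, got {X.shape}"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in input")

    W0a, W1a, W2a = state.active_weights()
    b0, b1, b2 = state.biases

    h1 = sigmoid(X @ W0a.T + b0)
    if dropout_masks is not None:
        h1 = h1 * dropout_masks[0] / (1.0 - drop_rates[0])
    h2 = sigmoid(h1 @ W1a.T + b1)
    if dropout_masks is not None:
        h2 = h2 * dropout_masks[1] / (1.0 - drop_rates[1])
    posterior = softmax(h2 @ W2a.T + b2)
    return ForwardTrace([X, h1, h2, posterior])
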