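"""Scikit-learn estimator wrapping the pathway-guided sparse network."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .network import forward
from .pathways import BiadjacencyMatrix
from .training import TrainConfig, fit as _fit

__all__ = ["PASNetClassifier"]


class PASNetClassifier(ClassifierMixin, BaseEstimator):
    """Pathway-guided sparse neural network classifier.

    A four-layer network (gene → pathway → hidden → output) whose
    gene→pathway connections are fixed by a pathway-membership
    biadjacency matrix, trained full-batch with randomly drawn dropout
    sub-networks, per-layer percentile sparse coding, and a
    class-partitioned (mean-false-error) cross-entropy that keeps a rare
    outcome class from being drowned out by the majority.

    Parameters
    ----------
    adjacency : BiadjacencyMatrix or binary array (pathways × genes)
        Fixes which gene→pathway weights may be nonzero.  Columns of
        ``X`` passed to :meth:`fit` must follow its gene order.
    hidden_size : int, default 100
        Number of hidden nodes between the pathway and output layers.
    learning_rate, l2 : float
        Optimizer step size η and L2 strength λ (defaults 1e-4, 3e-4).
    drop_pathway, drop_hidden : float
        Node drop probabilities of the two intermediate layers
        (defaults 0.8, 0.7).
    sparsity_grid : sequence of levels in [0, 100]
        Grid scored when re-optimizing each layer's sparsity.
    max_epochs, patience : int
        Epoch budget and early-stopping patience on the training loss.
    loss : {"mfe", "pooled"}
        Class-partitioned cost (default) or plain pooled cross-entropy.
    optimizer : {"adam", "sgd_decay"}
        Adam with additive λW, or a plain gradient step with
        multiplicative (1 − ηλ) decay.

    Attributes
    ----------
    state_ : NetworkState
        Trained weights, biases and masks.
    log_ : pandas.DataFrame
        Per-epoch monitored loss and per-layer optimal sparsity levels.
    classes_ : ndarray
        Class labels; the second one is treated as the positive class
        by :meth:`decision_function`.
    """

    def __init__(
        self,
        adjacency=None,
        hidden_size: int = 100,
        learning_rate: float = 1e-4,
        l2: float = 3e-4,
        drop_pathway: float = 0.8,
        drop_hidden: float = 0.7,
        sparsity_grid: tuple = (0.0, 20.0, 40.0, 60.0, 80.0, 100.0),
        fine_step: float = 0.5,
        max_epochs: int = 5000,
        patience: int = 100,
        loss: str = "mfe",
        optimizer: str = "adam",
        random_state: int = 0,
    ):
        self.adjacency = adjacency
        self.hidden_size = hidden_size
        self.learning_rate = learning_rate
        self.l2 = l2
        self.drop_pathway = drop_pathway
        self.drop_hidden = drop_hidden
        self.sparsity_grid = sparsity_grid
        self.fine_step = fine_step
        self.max_epochs = max_epochs
        self.patience = patience
        self.loss = loss
        self.optimizer = optimizer
        self.random_state = random_state

    def _config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate,
            l2=self.l2,
            drop_rates=(self.drop_pathway, self.drop_hidden),
            max_epochs=self.max_epochs,
            patience=self.patience,
            sparsity_grid=tuple(self.sparsity_grid),
            fine_step=self.fine_step,
            seed=self.random_state,
            optimizer=self.optimizer,
            loss=self.loss,
            hidden_size=self.hidden_size,
        )

    def fit(self, X, y):
        if self.adjacency is None:
            raise ValueError("adjacency (pathway × gene matrix) is required")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        n_genes = (
            self.adjacency.n_genes
            if isinstance(self.adjacency, BiadjacencyMatrix)
            else np.asarray(self.adjacency).shape[1]
        )
        if X.shape[1] != n_genes:
            raise ValueError(
                f"X has {X.shape[1]} genes but adjacency expects {n_genes}"
            )
        self.state_, self.log_ = _fit(X, y_idx, self.adjacency, self._config())
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "state_")
        return forward(np.asarray(X, dtype=float), self.state_).posterior

    def decision_function(self, X):
        """Posterior probability of the positive (second) class."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]
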