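"""The graph classifier: shared-weight multi-layer GCN with layer
concatenation, mean pooling and a logistic-regression head.

Training makes full use of node-level information: every node inherits the
class label of its graph, and the GCN layer weights W(1..L) together with a
linear classification matrix Theta over the concatenated per-node features
are optimized by Adam against the node-level multi-class cross-entropy.
After GCN training the final head is a logistic-regression classifier refit
on the mean-pooled whole-graph embeddings, which is what prediction uses.

The estimator follows the scikit-learn protocol (``fit`` / ``predict`` /
``predict_proba`` / ``get_params``); X is a list of
:class:`~hbgraph.graph.MolecularGraph`.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

from .gcn import (
    GCNParams,
    concat_layers,
    gcn_forward,
    mean_pool,
    normalize_adjacency,
    one_hot_node_features,
)
from .graph import MolecularGraph


class _Adam:
    """Adam with the standard first/second-moment decay defaults."""

    def __init__(self, shapes, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class HBCompareClassifier(ClassifierMixin, BaseEstimator):
    """Classify molecular graphs by hydrogen-bond topology.

    Parameters
    ----------
    n_layers : GCN depth L (default 3).
    hidden_dim : width of every GCN layer (default 64).
    lr : Adam learning rate (default 1e-3).
    batch_size : graphs per Adam step (default 4).
    epochs : full passes over the training graphs (default 50).
    concat : pool the concatenation of all layer outputs (True) or the last
        layer only (False, the ablation mode).
    activation : nonlinearity name ('relu', 'tanh', 'identity').
    head_C : inverse L2 regularization strength of the logistic-regression
        head (default 1.0).
    random_state : seed for weight initialization and batch shuffling.

    Attributes (after fit)
    ----------------------
    classes_ : sorted class labels.
    gcn_params_ : trained shared GCN weights.
    theta_ : node-level linear classification matrix used during training.
    head_ : the refit logistic-regression classifier over graph embeddings.
    loss_history_ : mean node-level cross-entropy per epoch.
    """

    def __init__(
        self,
        n_layers: int = 3,
        hidden_dim: int = 64,
        lr: float = 1e-3,
        batch_size: int = 4,
        epochs: int = 50,
        concat: bool = True,
        activation: str = "relu",
        head_C: float = 1.0,
        random_state: int | None = 0,
    ):
        self.n_layers = n_layers
        self.hidden_dim = hidden_dim
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.concat = concat
        self.activation = activation
        self.head_C = head_C
        self.random_state = random_state

    # -- internal ----------------------------------------------------------

    def _prepare(self, graphs: list[MolecularGraph]):
        prepared = []
        for k, g in enumerate(graphs):
            if g.n_nodes == 0:
                raise ValueError(f"graph {k} has zero nodes and cannot be embedded")
            prepared.append((normalize_adjacency(g.adjacency), one_hot_node_features(g)))
        return prepared

    def _forward_nodes(self, A_hat, X0):
        """Layer activations plus cached aggregation inputs for backprop."""
        sigma = self.activation
        X = X0
        caches = []
        for W in self.gcn_params_.weights:
            M = A_hat @ X
            Z = M @ W
            if sigma == "relu":
                X = np.maximum(Z, 0.0)
            elif sigma == "tanh":
                X = np.tanh(Z)
            else:
                X = Z
            caches.append((M, Z, X))
        return caches

    def _backward_graph(self, A_hat, X0, caches, y_index, theta):
        """Gradients of the node-level cross-entropy for one graph."""
        L = len(caches)
        Xs = [c[2] for c in caches]
        X_all = np.concatenate(Xs, axis=1) if self.concat else Xs[-1]
        n = X_all.shape[0]
        P = _softmax(X_all @ theta)
        dlogits = P.copy()
        dlogits[:, y_index] -= 1.0
        dlogits /= n
        d_theta = X_all.T @ dlogits
        dX_all = dlogits @ theta.T

        dXs = [np.zeros_like(X) for X in Xs]
        if self.concat:
            offset = 0
            for l, X in enumerate(Xs):
                w = X.shape[1]
                dXs[l] += dX_all[:, offset : offset + w]
                offset += w
        else:
            dXs[-1] += dX_all

        d_weights = [np.zeros_like(W) for W in self.gcn_params_.weights]
        loss = float(-np.log(np.clip(P[:, y_index], 1e-12, None)).mean())
        grad_next = None
        for l in range(L - 1, -1, -1):
            M, Z, X = caches[l]
            dX = dXs[l] if grad_next is None else dXs[l] + grad_next
            if self.activation == "relu":
                dZ = dX * (Z > 0)
            elif self.activation == "tanh":
                dZ = dX * (1.0 - X * X)
            else:
                dZ = dX
            d_weights[l] = M.T @ dZ
            if l > 0:
                # A_hat is symmetric, so the aggregation backprop reuses it
                grad_next = A_hat @ (dZ @ self.gcn_params_.weights[l].T)
        return d_weights, d_theta, loss

    # -- sklearn api -------------------------------------------------------

    def fit(self, X: list[MolecularGraph], y):
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        prepared = self._prepare(X)

        rng = np.random.default_rng(self.random_state)
        self.gcn_params_ = GCNParams.init(
            n_layers=self.n_layers,
            hidden_dim=self.hidden_dim,
            activation=self.activation,
            rng=rng,
        )
        out_dim = self.gcn_params_.output_dim if self.concat else self.hidden_dim
        n_classes = len(self.classes_)
        theta = rng.normal(0.0, 0.01, size=(out_dim, n_classes))

        opt = _Adam([W.shape for W in self.gcn_params_.weights] + [theta.shape], lr=self.lr)
        n = len(prepared)
        self.loss_history_ = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                batch = order[start : start + self.batch_size]
                g_w = [np.zeros_like(W) for W in self.gcn_params_.weights]
                g_t = np.zeros_like(theta)
                for k in batch:
                    A_hat, X0 = prepared[k]
                    caches = self._forward_nodes(A_hat, X0)
                    dw, dt, loss = self._backward_graph(A_hat, X0, caches, y_idx[k], theta)
                    for a, b in zip(g_w, dw):
                        a += b
                    g_t += dt
                    epoch_loss += loss
                scale = 1.0 / len(batch)
                opt.step(
                    self.gcn_params_.weights + [theta],
                    [g * scale for g in g_w] + [g_t * scale],
                )
            self.loss_history_.append(epoch_loss / n)

        self.theta_ = theta
        embeddings = np.array([self._embed_prepared(p) for p in prepared])
        # L2-penalized multinomial logistic regression, deterministic solver
        self.head_ = LogisticRegression(C=self.head_C, solver="lbfgs", max_iter=2000)
        self.head_.fit(embeddings, y_idx)
        return self

    def _embed_prepared(self, prepared) -> np.ndarray:
        A_hat, X0 = prepared
        layers = gcn_forward(A_hat, X0, self.gcn_params_)
        return mean_pool(concat_layers(layers, concat=self.concat))

    def embed(self, X: list[MolecularGraph]) -> np.ndarray:
        """Mean-pooled whole-graph embeddings, one row per graph."""
        check_is_fitted(self, "gcn_params_")
        return np.array([self._embed_prepared(p) for p in self._prepare(X)])

    def predict_proba(self, X: list[MolecularGraph]) -> np.ndarray:
        check_is_fitted(self, "head_")
        return self.head_.predict_proba(self.embed(X))

    def predict(self, X: list[MolecularGraph]) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def score(self, X, y, sample_weight=None) -> float:
        from sklearn.metrics import accuracy_score

        return accuracy_score(y, self.predict(X), sample_weight=sample_weight)

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.input_tags.two_d_array = False
        tags.target_tags.required = True
        return tags
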