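"""Graph convolutional embedding of molecular graphs.

Every layer applies the propagation rule

    X(l) = sigma( A_hat X(l-1) W(l) ),   A_hat = D^(-1/2) (A + I) D^(-1/2)

factored as feature aggregation (multiply by the self-looped, symmetrically
normalized adjacency) followed by feature transformation (shared linear map
plus nonlinearity). The same weights W(1..L) are applied to every graph, so
graphs of different sizes and node orders land in a common feature space.
Layer outputs are concatenated per node and mean-pooled into a graph
embedding that is invariant to node order and graph size.

Input node features are the one-hot role encoding (donor, acceptor, both),
so X(0) is N x 3.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .graph import MolecularGraph
from .roles import ACCEPTOR, BOTH, DONOR

#: fixed one-hot column order for node roles
ROLE_COLUMNS = (DONOR, ACCEPTOR, BOTH)
N_INPUT_FEATURES = len(ROLE_COLUMNS)

_ACTIVATIONS = {
    "relu": lambda x: np.maximum(x, 0.0),
    "identity": lambda x: x,
    "tanh": np.tanh,
}

CHECKPOINT_VERSION = 1


def one_hot_node_features(g: MolecularGraph) -> np.ndarray:
    """N x 3 one-hot role matrix, columns ordered (donor, acceptor, both)."""
    col = {role: k for k, role in enumerate(ROLE_COLUMNS)}
    X = np.zeros((g.n_nodes, N_INPUT_FEATURES))
    for i, role in enumerate(g.roles):
        try:
            X[i, col[role]] = 1.0
        except KeyError:
            raise ValueError(f"node {i} has unknown role {role!r}") from None
    return X


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Self-looped symmetric normalization D^(-1/2) (A + I) D^(-1/2).

    D is the diagonal row-sum (degree) matrix of A + I; a singleton node has
    degree 1 after the self-loop, so the operator is always well defined.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {A.shape}")
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    A_tilde = A + np.eye(A.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(A_tilde.sum(axis=1))
    return A_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


@dataclass
class GCNParams:
    """Per-layer weight matrices shared across all graphs."""

    weights: list[np.ndarray]
    activation: str = "relu"

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    @property
    def dims(self) -> list[int]:
        return [W.shape[1] for W in self.weights]

    @property
    def output_dim(self) -> int:
        return sum(self.dims)

    @classmethod
    def init(
        cls,
        n_layers: int = 3,
        hidden_dim: int = 64,
        n_input: int = N_INPUT_FEATURES,
        activation: str = "relu",
        rng: np.random.Generator | None = None,
    ) -> "GCNParams":
        """Glorot-uniform initialization."""
        rng = rng or np.random.default_rng()
        weights = []
        d_in = n_input
        for _ in range(n_layers):
            limit = np.sqrt(6.0 / (d_in + hidden_dim))
            weights.append(rng.uniform(-limit, limit, size=(d_in, hidden_dim)))
            d_in = hidden_dim
        return cls(weights=weights, activation=activation)


def gcn_forward(
    A_hat: np.ndarray, X0: np.ndarray, params: GCNParams
) -> list[np.ndarray]:
    """Layer outputs X(1)..X(L): aggregation by A_hat, then transformation."""
    sigma = _ACTIVATIONS[params.activation]
    X = X0
    layers = []
    for l, W in enumerate(params.weights, start=1):
        if X.shape[1] != W.shape[0]:
            raise ValueError(
                f"layer {l}: input has {X.shape[1]} features but W({l}) expects {W.shape[0]}"
            )
        X_agg = A_hat @ X  # feature aggregation
        X = sigma(X_agg @ W)  # feature transformation
        layers.append(X)
    return layers


def concat_layers(layers: list[np.ndarray], concat: bool = True) -> np.ndarray:
    """Per-node feature matrix: all layers side by side, or the last alone.

    ``concat=False`` is the last-layer ablation mode.
    """
    if not layers:
        raise ValueError("no layers to concatenate")
    n = layers[0].shape[0]
    if any(X.shape[0] != n for X in layers):
        raise ValueError("layers disagree on node count")
    if not concat:
        return layers[-1]
    return np.concatenate(layers, axis=1)


def mean_pool(X_all: np.ndarray) -> np.ndarray:
    """Average node rows into a node-order- and size-independent embedding."""
    if X_all.shape[0] == 0:
        raise ValueError("cannot pool an empty graph (no nodes)")
    return X_all.mean(axis=0)


def embed_graph(g: MolecularGraph, params: GCNParams, concat: bool = True) -> np.ndarray:
    """Whole-graph embedding: one-hot roles -> GCN layers -> concat -> mean pool."""
    A_hat = normalize_adjacency(g.adjacency)
    X0 = one_hot_node_features(g)
    layers = gcn_forward(A_hat, X0, params)
    return mean_pool(concat_layers(layers, concat=concat))


# --- checkpoint io ---------------------------------------------------------


def save_checkpoint(path: str, params: GCNParams, head: dict | None = None) -> None:
    """Single-file checkpoint: layer dims, activation, weight arrays."""
    arrays = {f"W{l}": W for l, W in enumerate(params.weights, start=1)}
    meta = {
        "checkpoint_version": CHECKPOINT_VERSION,
        "activation": params.activation,
        "dims": params.dims,
        "n_layers": params.n_layers,
        "head": head or {},
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str) -> tuple[GCNParams, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("checkpoint_version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('checkpoint_version')}")
        weights = [np.array(data[f"W{l}"]) for l in range(1, meta["n_layers"] + 1)]
    return GCNParams(weights=weights, activation=meta["activation"]), meta.get("head", {})
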