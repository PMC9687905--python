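"""GCN embedding: normalization closed forms, equivariance, pooling."""

import numpy as np
import pytest

from hbgraph import (
    COORDINATE_FREE,
    GCNParams,
    MolecularGraph,
    concat_layers,
    embed_graph,
    gcn_forward,
    mean_pool,
    normalize_adjacency,
    one_hot_node_features,
)


def random_graph(rng, n=12, p=0.25, mode=COORDINATE_FREE):
    roles = [("donor", "acceptor", "both")[k] for k in rng.integers(0, 3, size=n)]
    A = np.triu((rng.random((n, n)) < p).astype(float), k=1)
    if mode != COORDINATE_FREE:
        A *= rng.uniform(2.5, 3.9, size=(n, n))
    A = A + A.T
    return MolecularGraph(roles=roles, adjacency=A, mode=mode)


def test_one_hot_columns_follow_role_order():
    g = MolecularGraph(roles=["donor", "acceptor", "both"], adjacency=np.zeros((3, 3)))
    X = one_hot_node_features(g)
    assert X.shape == (3, 3)
    assert np.array_equal(X, np.eye(3))
    assert np.all(X.sum(axis=1) == 1.0)


def test_one_hot_empty_graph_and_bad_role():
    g = MolecularGraph(roles=[], adjacency=np.zeros((0, 0)))
    assert one_hot_node_features(g).shape == (0, 3)
    bad = MolecularGraph(roles=["mystery"], adjacency=np.zeros((1, 1)))
    with pytest.raises(ValueError, match="mystery"):
        one_hot_node_features(bad)


def test_normalization_closed_forms():
    assert np.allclose(normalize_adjacency(np.zeros((4, 4))), np.eye(4))
    one_edge = np.array([[0.0, 1.0], [1.0, 0.0]])
    assert np.allclose(normalize_adjacency(one_edge), np.full((2, 2), 0.5))
    k3 = np.ones((3, 3)) - np.eye(3)
    assert np.allclose(normalize_adjacency(k3), np.full((3, 3), 1.0 / 3.0))


def test_normalization_rejects_asymmetric():
    with pytest.raises(ValueError, match="symmetric"):
        normalize_adjacency(np.array([[0.0, 1.0], [0.0, 0.0]]))


def test_normalized_spectrum_in_unit_interval(rng):
    """Symmetry and eigenvalues within [-1, 1] for random binary graphs."""
    for _ in range(50):
        n = int(rng.integers(2, 15))
        A = np.triu((rng.random((n, n)) < 0.3).astype(float), 1)
        A = A + A.T
        A_hat = normalize_adjacency(A)
        assert np.allclose(A_hat, A_hat.T)
        eig = np.linalg.eigvalsh(A_hat)
        assert eig.min() >= -1.0 - 1e-10 and eig.max() <= 1.0 + 1e-10


def test_forward_zero_weights_gives_zero():
    params = GCNParams(weights=[np.zeros((3, 4)), np.zeros((4, 4))])
    A_hat = normalize_adjacency(np.zeros((5, 5)))
    X0 = np.ones((5, 3))
    layers = gcn_forward(A_hat, X0, params)
    assert all(not X.any() for X in layers)


def test_forward_edgeless_identity_weights():
    W = np.eye(3)
    params = GCNParams(weights=[W], activation="identity")
    X0 = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
    (X1,) = gcn_forward(normalize_adjacency(np.zeros((2, 2))), X0, params)
    assert np.allclose(X1, X0)


def test_forward_shape_error_names_layer():
    params = GCNParams(weights=[np.zeros((4, 4))])
    with pytest.raises(ValueError, match="layer 1"):
        gcn_forward(np.eye(2), np.zeros((2, 3)), params)


def test_regular_graph_constant_features_closed_form(rng):
    """On a k-regular graph with constant rows, aggregation is the identity."""
    # ring graph: 2-regular
    n = 8
    A = np.zeros((n, n))
    for i in range(n):
        A[i, (i + 1) % n] = A[(i + 1) % n, i] = 1.0
    A_hat = normalize_adjacency(A)
    X0 = np.tile([0.2, 0.5, 0.3], (n, 1))
    assert np.allclose(A_hat @ X0, X0)
    W = rng.normal(size=(3, 6))
    params = GCNParams(weights=[W], activation="identity")
    (X1,) = gcn_forward(A_hat, X0, params)
    assert np.allclose(X1, X0 @ W)


def test_layer_equivariance_under_permutation(rng):
    g = random_graph(rng)
    params = GCNParams.init(n_layers=3, hidden_dim=8, rng=rng)
    layers = gcn_forward(normalize_adjacency(g.adjacency), one_hot_node_features(g), params)
    perm = rng.permutation(g.n_nodes)
    gp = g.permuted(perm)
    layers_p = gcn_forward(normalize_adjacency(gp.adjacency), one_hot_node_features(gp), params)
    for X, Xp in zip(layers, layers_p):
        assert np.allclose(Xp, X[perm], atol=1e-12)


def test_concat_dimensions_and_ablation(rng):
    layers = [rng.normal(size=(5, 64)) for _ in range(3)]
    X_all = concat_layers(layers)
    assert X_all.shape == (5, 192)
    assert np.allclose(concat_layers(layers[:1]), layers[0])
    assert np.allclose(concat_layers(layers, concat=False), layers[2])
    with pytest.raises(ValueError, match="node count"):
        concat_layers([layers[0], rng.normal(size=(4, 64))])


def test_mean_pool_properties(rng):
    u = rng.normal(size=7)
    assert np.allclose(mean_pool(np.tile(u, (4, 1))), u)
    assert np.allclose(mean_pool(np.vstack([u, -u])), 0.0)
    X = rng.normal(size=(6, 7))
    assert np.allclose(mean_pool(X[rng.permutation(6)]), mean_pool(X))
    with pytest.raises(ValueError, match="empty"):
        mean_pool(np.zeros((0, 7)))


@pytest.mark.parametrize("mode_p", [0.2, 0.5])
def test_embedding_permutation_invariance(rng, mode_p):
    """End-to-end: 20 random graphs x 100 permutations, max diff < 1e-6."""
    params = GCNParams.init(n_layers=3, hidden_dim=16, rng=rng)
    for _ in range(10):
        g = random_graph(rng, n=int(rng.integers(5, 20)), p=mode_p)
        e = embed_graph(g, params)
        for _ in range(50):
            perm = rng.permutation(g.n_nodes)
            ep = embed_graph(g.permuted(perm), params)
            assert np.abs(ep - e).max() < 1e-6


def test_coordinate_based_graphs_share_the_code_path(rng):
    g = random_graph(rng, mode="coordinate_based")
    params = GCNParams.init(rng=rng)
    e = embed_graph(g, params)
    assert e.shape == (params.output_dim,)
    assert np.isfinite(e).all()


def test_checkpoint_round_trip(tmp_path, rng):
    from hbgraph import load_checkpoint, save_checkpoint

    params = GCNParams.init(n_layers=2, hidden_dim=5, rng=rng)
    path = tmp_path / "model.npz"
    save_checkpoint(str(path), params, head={"classes": ["a", "b"]})
    loaded, head = load_checkpoint(str(path))
    assert loaded.activation == params.activation
    assert head["classes"] == ["a", "b"]
    for W, W2 in zip(params.weights, loaded.weights):
        assert np.array_equal(W, W2)
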