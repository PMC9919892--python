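import numpy as np
import pytest
from numpy.polynomial import chebyshev as C

from fgcn import (
    ChebGCNClassifier,
    FeatureBatch,
    build_spectral_operator,
    cheb_polynomials,
    cross_entropy_loss,
    evaluate,
    normalize_rows,
    select_band,
    spectral_graph_conv,
)
from fgcn.exceptions import EstimationError, IsolatedNodeError, ParameterError
from fgcn.fusion import FusedGraph, fuse


def random_fused(rng, n=8):
    parts = [normalize_rows(rng.random((n, n))) for _ in range(3)]
    return fuse(parts, "add")


# --------------------------------------------------------------------- #
# spectral operator


class TestSpectralOperator:
    def test_identity_adjacency_uses_lambda_fallback(self):
        op = build_spectral_operator(np.eye(5))
        np.testing.assert_allclose(op.r_fuse, 0.0, atol=1e-15)
        assert op.lambda_max == 2.0
        np.testing.assert_allclose(op.r_scaled, -np.eye(5), atol=1e-15)

    def test_two_node_closed_form(self):
        # unit self-loops and a unit edge: degrees 2, R = I - H/2
        h = np.array([[1.0, 1.0], [1.0, 1.0]])
        op = build_spectral_operator(h)
        expected_r = np.array([[0.5, -0.5], [-0.5, 0.5]])
        np.testing.assert_allclose(op.r_fuse, expected_r, atol=1e-14)
        eigs = np.linalg.eigvalsh(op.r_fuse)
        np.testing.assert_allclose(eigs, [0.0, 1.0], atol=1e-14)
        assert op.lambda_max == pytest.approx(1.0)

    def test_scaled_eigenvalues_contained(self, rng):
        for _ in range(10):
            op = build_spectral_operator(random_fused(rng))
            eigs = np.linalg.eigvalsh(op.r_scaled)
            assert eigs.min() >= -1.0 - 1e-9
            assert eigs.max() <= 1.0 + 1e-9

    def test_directed_input_is_symmetrized(self, rng):
        h = rng.random((6, 6))
        op = build_spectral_operator(h)
        np.testing.assert_allclose(op.h_fuse, (h + h.T) / 2.0)
        np.testing.assert_allclose(op.r_fuse, op.r_fuse.T)

    def test_isolated_node_error_names_channel(self):
        h = np.eye(3) * 0.0
        h[0, 1] = h[1, 0] = 1.0
        fused = FusedGraph(
            weights=h, strategy="add", components=("topological",),
            channel_names=("a", "b", "c"),
        )
        with pytest.raises(IsolatedNodeError, match="c"):
            build_spectral_operator(fused)

    def test_negative_adjacency_rejected(self):
        with pytest.raises(ParameterError):
            build_spectral_operator(np.array([[1.0, -0.5], [-0.5, 1.0]]))

    def test_power_iteration_matches_dense_eigensolver(self, rng):
        # above the dense-solver size cutoff the power iteration takes over
        h = rng.random((150, 150))
        op = build_spectral_operator(h)
        dense = np.linalg.eigvalsh(op.r_fuse)[-1]
        assert op.lambda_max == pytest.approx(dense, abs=1e-6)


# --------------------------------------------------------------------- #
# Chebyshev polynomials and the graph filter


class TestChebPolynomials:
    def test_order_zero_is_identity(self, rng):
        op = build_spectral_operator(random_fused(rng))
        terms = cheb_polynomials(op, 0)
        assert len(terms) == 1
        np.testing.assert_array_equal(terms[0], np.eye(op.n_channels))

    def test_scalar_identity_on_diagonal_operator(self):
        r = np.diag([0.3, -0.7, 0.5])
        terms = cheb_polynomials(r, 2)
        np.testing.assert_allclose(
            np.diag(terms[2]), 2.0 * np.diag(r) ** 2 - 1.0, atol=1e-14
        )

    def test_matches_spectral_domain_evaluation(self, rng):
        op = build_spectral_operator(random_fused(rng))
        u, s = np.linalg.eigh(op.r_scaled)[1], np.linalg.eigvalsh(op.r_scaled)
        terms = cheb_polynomials(op, 5)
        for i, t in enumerate(terms):
            coef = np.zeros(i + 1)
            coef[i] = 1.0
            expected = u @ np.diag(C.chebval(s, coef)) @ u.T
            np.testing.assert_allclose(t, expected, atol=1e-8)

    def test_negative_order_rejected(self, rng):
        op = build_spectral_operator(random_fused(rng))
        with pytest.raises(ParameterError):
            cheb_polynomials(op, -1)


class TestSpectralGraphConv:
    def test_identity_filter(self, rng):
        op = build_spectral_operator(random_fused(rng))
        terms = cheb_polynomials(op, 3)
        x = rng.normal(size=(4, 8, 2))
        out = spectral_graph_conv(x, terms, np.array([1.0, 0.0, 0.0, 0.0]))
        np.testing.assert_allclose(out, x, atol=1e-12)

    def test_linear_in_coefficients(self, rng):
        op = build_spectral_operator(random_fused(rng))
        terms = cheb_polynomials(op, 3)
        x = rng.normal(size=(3, 8, 2))
        theta = rng.normal(size=4)
        out1 = spectral_graph_conv(x, terms, theta)
        out2 = spectral_graph_conv(x, terms, 2.0 * theta)
        np.testing.assert_allclose(out2, 2.0 * out1, atol=1e-10)

    def test_matches_dense_spectral_filtering(self, rng):
        """Polynomial-in-operator equals polynomial-on-eigenvalues."""
        op = build_spectral_operator(random_fused(rng))
        s, u = np.linalg.eigh(op.r_scaled)
        terms = cheb_polynomials(op, 3)
        x = rng.normal(size=(8, 2))
        theta = rng.normal(size=4)
        out = spectral_graph_conv(x, terms, theta)
        filt = sum(
            theta[i] * C.chebval(s, np.eye(4)[i]) for i in range(4)
        )
        expected = u @ np.diag(filt) @ u.T @ x
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_node_permutation_equivariance(self, rng):
        fused = random_fused(rng)
        perm = rng.permutation(8)
        x = rng.normal(size=(8, 3))
        theta = rng.normal(size=4)
        out = spectral_graph_conv(
            x, cheb_polynomials(build_spectral_operator(fused), 3), theta
        )
        fused_p = FusedGraph(
            weights=fused.weights[np.ix_(perm, perm)],
            strategy="add", components=fused.components,
        )
        out_p = spectral_graph_conv(
            x[perm], cheb_polynomials(build_spectral_operator(fused_p), 3), theta
        )
        np.testing.assert_allclose(out_p, out[perm], atol=1e-8)

    def test_dimension_mismatch_rejected(self, rng):
        op = build_spectral_operator(random_fused(rng))
        terms = cheb_polynomials(op, 2)
        with pytest.raises(ParameterError):
            spectral_graph_conv(rng.normal(size=(2, 9, 1)), terms, np.ones(3))


# --------------------------------------------------------------------- #
# loss


class TestCrossEntropy:
    def test_perfect_prediction_gives_zero(self):
        probs = np.eye(4)
        assert cross_entropy_loss(probs, np.arange(4)) == pytest.approx(0.0)

    def test_uniform_three_class_gives_ln3(self):
        probs = np.full((5, 3), 1.0 / 3.0)
        loss = cross_entropy_loss(probs, np.zeros(5, dtype=int))
        assert loss == pytest.approx(np.log(3.0), abs=1e-12)

    def test_direct_evaluation(self):
        loss = cross_entropy_loss(np.array([[0.7, 0.2, 0.1]]), np.array([0]))
        assert loss == pytest.approx(-np.log(0.7), abs=1e-12)

    def test_sum_reduction(self):
        probs = np.full((4, 2), 0.5)
        labels = np.zeros(4, dtype=int)
        assert cross_entropy_loss(probs, labels, "sum") == pytest.approx(
            4.0 * np.log(2.0)
        )

    def test_zero_probability_clamped_and_logged(self, caplog):
        probs = np.array([[0.0, 1.0]])
        with caplog.at_level("WARNING"):
            loss = cross_entropy_loss(probs, np.array([0]))
        assert np.isfinite(loss) and loss > 20
        assert "clamping" in caplog.text

    def test_label_range_validated(self):
        with pytest.raises(ParameterError):
            cross_entropy_loss(np.full((2, 2), 0.5), np.array([0, 2]))


# --------------------------------------------------------------------- #
# classifier


def separable_batch(rng, n=60, nodes=6, m=2):
    y = rng.integers(0, m, size=n)
    x = rng.normal(0.0, 0.3, size=(n, nodes, 1))
    x[:, 0, 0] += 3.0 * y
    return x, y


class TestChebGCNClassifier:
    def test_probabilities_sum_to_one_and_shape(self, rng):
        x, _ = separable_batch(rng, n=20, m=3)
        y = rng.integers(0, 3, size=20)
        clf = ChebGCNClassifier(n_epochs=3).fit(x, y)
        probs = clf.predict_proba(x[:4])
        assert probs.shape == (4, 3)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert probs.min() >= 0.0

    def test_linearly_separable_classes_reach_full_training_accuracy(self, rng):
        x, y = separable_batch(rng)
        clf = ChebGCNClassifier(n_epochs=150, adjacency=None).fit(x, y)
        assert clf.score(x, y) == 1.0
        assert np.all(np.isfinite(clf.loss_curve_))
        assert clf.loss_curve_[-1] < clf.loss_curve_[0]

    def test_same_seed_reproduces_training_exactly(self, rng):
        x, y = separable_batch(rng, n=40)
        a = ChebGCNClassifier(n_epochs=20, random_state=3).fit(x, y)
        b = ChebGCNClassifier(n_epochs=20, random_state=3).fit(x, y)
        assert a.loss_curve_ == b.loss_curve_
        np.testing.assert_array_equal(a.predict_proba(x), b.predict_proba(x))

    def test_different_seeds_differ(self, rng):
        x, y = separable_batch(rng, n=40)
        a = ChebGCNClassifier(n_epochs=5, random_state=0).fit(x, y)
        b = ChebGCNClassifier(n_epochs=5, random_state=1).fit(x, y)
        assert a.loss_curve_ != b.loss_curve_

    def test_fused_graph_adjacency_accepted(self, rng):
        fused = random_fused(rng, n=6)
        x, y = separable_batch(rng, n=30)
        clf = ChebGCNClassifier(adjacency=fused, n_epochs=5).fit(x, y)
        assert clf.operator_.n_channels == 6

    def test_grid_depthwise_layout(self, rng):
        nodes = 6
        grid_index = np.array([[0, 0], [0, 1], [1, 0], [1, 1], [2, 0], [2, 1]])
        x, y = separable_batch(rng, n=40, nodes=nodes)
        clf = ChebGCNClassifier(
            depthwise_layout="grid", grid_index=grid_index, n_epochs=10
        ).fit(x, y)
        assert clf.predict(x).shape == (40,)
        with pytest.raises(ParameterError):
            ChebGCNClassifier(depthwise_layout="grid").fit(x, y)

    def test_sklearn_param_protocol(self):
        clf = ChebGCNClassifier(cheb_order=4)
        assert clf.get_params()["cheb_order"] == 4
        clf.set_params(n_epochs=7)
        assert clf.n_epochs == 7

    def test_channel_mismatch_rejected(self, rng):
        x, y = separable_batch(rng, n=20, nodes=6)
        clf = ChebGCNClassifier(adjacency=np.eye(5))
        with pytest.raises(ParameterError):
            clf.fit(x, y)

    def test_divergence_detected(self, rng):
        x, y = separable_batch(rng, n=20)
        # an absurd step size blows the weights up until the loss is NaN
        clf = ChebGCNClassifier(n_epochs=3, learning_rate=1e120)
        with pytest.raises(EstimationError, match="diverged"):
            with np.errstate(all="ignore"):
                clf.fit(x, y)


class TestEvaluate:
    def test_perfect_and_conservation(self, rng):
        x, y = separable_batch(rng)
        clf = ChebGCNClassifier(n_epochs=150).fit(x, y)
        res = evaluate(clf, x, y)
        assert res["accuracy"] == 1.0
        conf = res["confusion"]
        assert conf.sum() == len(y)
        np.testing.assert_array_equal(
            conf.sum(axis=1), np.bincount(y, minlength=2)
        )

    def test_uninformative_labels_score_near_chance(self, rng):
        n, m = 300, 3
        x = rng.normal(size=(n, 5, 1))
        y = rng.integers(0, m, size=n)
        clf = ChebGCNClassifier(n_epochs=10).fit(x, y)
        x_new = rng.normal(size=(n, 5, 1))
        y_new = rng.integers(0, m, size=n)
        res = evaluate(clf, x_new, y_new)
        # binomial around 1/3 at n=300 (sd ~ 0.027); allow 5 sigma
        assert abs(res["accuracy"] - 1.0 / m) < 0.14

    def test_empty_test_set_rejected(self, rng):
        x, y = separable_batch(rng, n=20)
        clf = ChebGCNClassifier(n_epochs=2).fit(x, y)
        with pytest.raises(ParameterError):
            evaluate(clf, x[:0], y[:0])


def test_select_band_slices_five_band_features(rng):
    x = rng.normal(size=(10, 4, 5))
    batch = FeatureBatch(x=x, y=np.zeros(10, dtype=int))
    beta = select_band(batch, "beta")
    assert beta.n_bands == 1
    np.testing.assert_array_equal(beta.x[..., 0], x[..., 3])
    assert select_band(batch, "total") is batch
    with pytest.raises(ParameterError):
        select_band(batch, "mu")
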