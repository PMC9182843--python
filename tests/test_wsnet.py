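"""GAP, localized classification, Fisher weighting, fusion, classifier."""

import numpy as np
import pytest

from msgait.backbone import ScaleFeatureMap
from msgait.wsnet import (FisherWeights, classify, fisher_weights, fuse,
                          global_average_pool, localized_scores,
                          reweight_features, scatter_matrices, softmax)


def oracle_fisher(scores, labels, n_prime, ridge_factor=1e-6):
    """Independent dense route: eig of inv(Sw + ridge) @ Sb via numpy.

    Scatters are accumulated with explicit loops so the oracle shares no code
    path with the implementation.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    d = scores.shape[1]
    m = scores.mean(axis=0)
    sw = np.zeros((d, d))
    sb = np.zeros((d, d))
    for c in np.unique(labels):
        xc = scores[labels == c]
        mc = xc.mean(axis=0)
        for row in xc:
            sw += np.outer(row - mc, row - mc)
        sb += np.outer(mc - m, mc - m)
    eps = ridge_factor * (np.trace(sw) / d if np.trace(sw) > 0 else 1.0)
    evals = np.linalg.eigvals(np.linalg.solve(sw + eps * np.eye(d), sb))
    evals = np.sort(np.real(evals))[::-1]
    return np.clip(evals[:n_prime], 0.0, None)


class TestGap:
    def test_constant_map(self):
        fmap = ScaleFeatureMap(np.full((7, 3), 2.5))
        assert np.allclose(global_average_pool(fmap).values, 2.5)

    def test_small_arithmetic(self):
        fmap = ScaleFeatureMap(np.array([[1.0, 3.0], [5.0, 7.0]]))
        assert np.array_equal(global_average_pool(fmap).values, [3.0, 5.0])

    def test_matches_loop_oracle(self, rng):
        v = rng.normal(size=(21, 128))
        expected = np.array([sum(v[i, k] for i in range(21)) / 21
                             for k in range(128)])
        assert np.allclose(global_average_pool(ScaleFeatureMap(v)).values,
                           expected, atol=1e-12)

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            global_average_pool(ScaleFeatureMap(np.zeros((0, 4))))


class TestLocalizedScores:
    def test_ones_column_sums_channels(self, rng):
        v = rng.normal(size=(5, 4))
        s = localized_scores(ScaleFeatureMap(v), np.ones((4, 1)))
        assert np.allclose(s.scores[:, 0], v.sum(axis=1))

    def test_zero_map_zero_scores(self):
        s = localized_scores(ScaleFeatureMap(np.zeros((5, 4))),
                             np.ones((4, 3)))
        assert np.array_equal(s.scores, np.zeros((5, 3)))

    def test_matches_matrix_product(self, rng):
        v = rng.normal(size=(5, 4))
        W = rng.normal(size=(4, 3))
        s = localized_scores(ScaleFeatureMap(v), W).scores
        expected = np.array([[sum(v[i, k] * W[k, c] for k in range(4))
                              for c in range(3)] for i in range(5)])
        assert np.allclose(s, expected, atol=1e-12)

    def test_dim_mismatch(self, rng):
        with pytest.raises(ValueError, match="channel mismatch"):
            localized_scores(ScaleFeatureMap(rng.normal(size=(5, 4))),
                             rng.normal(size=(5, 3)))


class TestFisherWeights:
    def test_identical_class_means_give_zero(self, rng):
        a = rng.normal(size=(40, 3))
        scores = np.concatenate([a, a])        # class means coincide exactly
        labels = np.repeat([0, 1], 40)
        fw = fisher_weights(scores, labels, 1)
        assert np.allclose(fw.lambda_, 0.0, atol=1e-8)

    def test_scalar_two_class_case(self):
        """1-D, zero within-variance: lambda equals the scalar ridge formula."""
        scores = np.array([[0.0], [0.0], [2.0], [2.0]])
        labels = np.array([0, 0, 1, 1])
        fw = fisher_weights(scores, labels, 1)
        # Sw = 0 -> ridge eps = 1e-6 (unit fallback); Sb = 2*(1)^2 = 2
        assert fw.lambda_[0] == pytest.approx(2.0 / 1e-6, rel=1e-6)

    @pytest.mark.parametrize("n_classes", [2, 3, 5])
    def test_matches_independent_eigensolver(self, n_classes, rng):
        n, d = 50, 3
        scores = rng.normal(size=(n, d)) + rng.normal(
            size=(n_classes, d))[rng.integers(0, n_classes, n)]
        labels = rng.integers(0, n_classes, n)
        if len(np.unique(labels)) < n_classes:
            labels[:n_classes] = np.arange(n_classes)
        n_prime = n_classes - 1
        fw = fisher_weights(scores, labels, n_prime)
        assert np.allclose(fw.lambda_, oracle_fisher(scores, labels, n_prime),
                           rtol=1e-8, atol=1e-8)

    def test_invariance_under_invertible_maps(self, rng):
        scores = rng.normal(size=(60, 4))
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        A = rng.normal(size=(4, 4)) + 4 * np.eye(4)
        lam0 = fisher_weights(scores, labels, 1).lambda_
        lam1 = fisher_weights(scores @ A, labels, 1).lambda_
        assert np.allclose(lam0, lam1, rtol=1e-6)

    def test_top_eigenvalue_monotone_in_mean_separation(self, rng):
        base = rng.normal(size=(30, 2))
        labels = np.repeat([0, 1], 15)
        tops = []
        for sep in (0.5, 1.5, 3.0):
            shifted = base + sep * np.outer(labels, np.ones(2))
            tops.append(fisher_weights(shifted, labels, 1).lambda_[0])
        assert tops[0] <= tops[1] <= tops[2]

    def test_single_class_warns_zero(self, rng):
        with pytest.warns(UserWarning, match="single class"):
            fw = fisher_weights(rng.normal(size=(10, 3)), np.zeros(10), 2)
        assert np.array_equal(fw.lambda_, np.zeros(2))

    def test_n_prime_bound_enforced(self, rng):
        with pytest.raises(ValueError, match="n_prime"):
            fisher_weights(rng.normal(size=(10, 3)),
                           np.repeat([0, 1], 5), 2)


class TestReweight:
    def _fw(self, lam, proj):
        return FisherWeights(np.asarray(lam, float), np.asarray(proj, float),
                             np.asarray(proj, float))

    def test_unit_weights_are_plain_projection(self, rng):
        proj = np.linalg.qr(rng.normal(size=(5, 2)))[0]
        g = rng.normal(size=5)
        assert np.allclose(reweight_features(g, self._fw([1.0, 1.0], proj)),
                           g @ proj)

    def test_zero_eigenvalue_annihilates_component(self, rng):
        proj = np.eye(3)[:, :2]
        out = reweight_features(np.array([1.0, 2.0, 3.0]),
                                self._fw([1.0, 0.0], proj))
        assert np.array_equal(out, [1.0, 0.0])

    def test_norm_bounded_by_plain_projection(self, rng):
        proj = np.linalg.qr(rng.normal(size=(6, 3)))[0]
        lam = np.sort(rng.uniform(0.1, 2.0, 3))[::-1]
        g = rng.normal(size=6)
        out = reweight_features(g, self._fw(lam, proj))
        assert np.linalg.norm(out) <= np.linalg.norm(g @ proj) + 1e-12

    def test_all_zero_lambda_warns(self, rng):
        with pytest.warns(UserWarning, match="all-zero"):
            out = reweight_features(rng.normal(size=4),
                                    self._fw([0.0, 0.0], np.eye(4)[:, :2]))
        assert np.array_equal(out, np.zeros(2))


class TestFuseAndClassify:
    def test_single_scale_identity(self, rng):
        f = rng.normal(size=4)
        assert np.allclose(fuse([f], [np.eye(4)]).values, f)

    def test_two_identical_scales_double(self, rng):
        f = rng.normal(size=4)
        assert np.allclose(fuse([f, f], [np.eye(4), np.eye(4)]).values, 2 * f)

    def test_zero_weights_zero_output(self, rng):
        out = fuse([rng.normal(size=4), rng.normal(size=3)],
                   [np.zeros((4, 5)), np.zeros((3, 5))])
        assert np.array_equal(out.values, np.zeros(5))

    def test_dim_mismatch(self, rng):
        with pytest.raises(ValueError, match="fusion dim mismatch"):
            fuse([rng.normal(size=4)], [np.zeros((3, 5))])

    def test_zero_logits_uniform(self):
        p = classify(np.zeros(8), np.zeros((8, 5)), np.zeros(5))
        assert np.allclose(p, 0.2)

    def test_extreme_logits_stable(self):
        p = softmax(np.array([1000.0, 0.0, 0.0]))
        assert np.isfinite(p).all()
        assert p[0] == pytest.approx(1.0)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_softmax_matches_high_precision(self, rng):
        from decimal import Decimal, getcontext
        getcontext().prec = 50
        z = rng.normal(size=6)
        exps = [Decimal(float(v)).exp() for v in z]
        total = sum(exps)
        expected = np.array([float(e / total) for e in exps])
        assert np.allclose(softmax(z), expected, atol=1e-12)
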