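"""Weight-update sub-network: Fisher-discriminant feature weighting.

Each backbone branch ends in a feature map ``f`` of shape (locations h,
channels c).  Global average pooling (GAP) gives the branch's feature vector
F_k = mean_i f_{i,k}.  Localized classification maps every location's
feature vector through the branch classifier weights, producing per-location
class scores.  Pooling those score vectors over a training batch, the Fisher
criterion compares their between-class scatter S_b to their within-class
scatter S_w; the leading generalized eigenvalues lambda of S_w^{-1} S_b and
their eigenvectors define the discriminant directions.  The GAP vector is
projected onto those directions (pulled back to feature space through the
classifier weights) and each component is scaled by lambda_j / max(lambda),
so directions that separate subjects well keep their weight and directions
dominated by nuisance (covariate) variation are suppressed.  The weighted
per-scale features are fused by learned linear maps into a single global
feature, which a softmax layer turns into class probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import scipy.linalg

from .backbone import ScaleFeatureMap

#: ridge added to the within-class scatter, relative to trace/dim
RIDGE_FACTOR = 1e-6


@dataclass
class GapVector:
    values: np.ndarray


@dataclass
class LocalizedScores:
    """Per-location class scores: ``(locations, n_classes)``."""

    scores: np.ndarray


@dataclass
class FisherWeights:
    """Top generalized eigenvalues of S_w^{-1} S_b and their directions.

    ``lambda_`` is sorted descending, length n' <= n_classes - 1.
    ``eigenvectors`` live in localized-score space, ``(score_dim, n')``.
    ``projection`` maps a feature-space vector straight onto the discriminant
    directions, ``(feature_dim, n')``; for score-space inputs it equals
    ``eigenvectors``.
    """

    lambda_: np.ndarray
    eigenvectors: np.ndarray
    projection: np.ndarray


@dataclass
class GlobalFeature:
    values: np.ndarray


def _values(x: Union[ScaleFeatureMap, GapVector, np.ndarray]) -> np.ndarray:
    if isinstance(x, (ScaleFeatureMap, GapVector)):
        return x.values
    if isinstance(x, LocalizedScores):
        return x.scores
    return np.asarray(x)


def global_average_pool(fmap: Union[ScaleFeatureMap, np.ndarray]) -> GapVector:
    """Mean over locations per channel; ``(h, c)`` -> ``(c,)``."""
    v = _values(fmap)
    if v.shape[0] == 0:
        raise ValueError("feature map has zero locations")
    return GapVector(v.mean(axis=0))


def localized_scores(
    fmap: Union[ScaleFeatureMap, np.ndarray],
    class_weights: np.ndarray,
    bias: Optional[np.ndarray] = None,
) -> LocalizedScores:
    """Per-location dot products with the classifier columns.

    Row i of the result holds location i's score for each class.
    """
    v = _values(fmap)
    class_weights = np.asarray(class_weights)
    if v.shape[-1] != class_weights.shape[0]:
        raise ValueError(
            f"channel mismatch: feature map has {v.shape[-1]} channels, "
            f"class weights expect {class_weights.shape[0]}")
    s = v @ class_weights
    if bias is not None:
        s = s + bias
    return LocalizedScores(s)


def scatter_matrices(
    scores: np.ndarray, labels: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Within-class scatter S_w and (unweighted) between-class scatter S_b.

    S_w sums outer products of deviations from each class mean; S_b sums
    outer products of class-mean deviations from the global mean, one term
    per class present.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    d = scores.shape[1]
    m = scores.mean(axis=0)
    sw = np.zeros((d, d))
    sb = np.zeros((d, d))
    for c in np.unique(labels):
        xc = scores[labels == c]
        mc = xc.mean(axis=0)
        dev = xc - mc
        sw += dev.T @ dev
        dm = mc - m
        sb += np.outer(dm, dm)
    return sw, sb


def fisher_weights(
    scores: Union[LocalizedScores, np.ndarray],
    labels: np.ndarray,
    n_prime: int,
) -> FisherWeights:
    """Solve the generalized eigenproblem of (S_b, S_w) on pooled scores.

    Returns the top ``n_prime`` eigenvalues (clipped to >= 0) with their
    eigenvectors.  A singular S_w is ridge-regularized with
    ``1e-6 * trace/dim * I`` (always added; it is negligible when S_w is well
    conditioned).  With a single class present, S_b vanishes and zero weights
    are returned with a warning.
    """
    s = _values(scores)
    if s.ndim != 2:
        raise ValueError("scores must be 2-D (samples x dims)")
    labels = np.asarray(labels)
    if len(labels) != s.shape[0]:
        raise ValueError("labels length must match score rows")
    classes = np.unique(labels)
    d = s.shape[1]
    if n_prime < 1:
        raise ValueError("n_prime must be positive")
    if len(classes) < 2:
        warnings.warn("fisher_weights: single class present; zero weights")
        return FisherWeights(np.zeros(n_prime), np.zeros((d, n_prime)),
                             np.zeros((d, n_prime)))
    if n_prime > len(classes) - 1:
        raise ValueError(
            f"n_prime={n_prime} exceeds n_classes-1={len(classes) - 1}")
    sw, sb = scatter_matrices(s, labels)
    return fisher_weights_from_scatter(sw, sb, n_prime)


def fisher_weights_from_scatter(
    sw: np.ndarray, sb: np.ndarray, n_prime: int
) -> FisherWeights:
    """Eigen-solve (S_b, S_w + ridge) given precomputed scatter matrices."""
    d = sw.shape[0]
    tr = float(np.trace(sw))
    eps = RIDGE_FACTOR * (tr / d if tr > 0 else 1.0)
    sw_r = sw + eps * np.eye(d)
    # symmetrize against accumulation round-off before the dense solve
    evals, evecs = scipy.linalg.eigh((sb + sb.T) / 2.0, (sw_r + sw_r.T) / 2.0)
    order = np.argsort(evals)[::-1][:n_prime]
    lam = evals[order]
    if np.any(lam < -1e-8):
        warnings.warn("fisher_weights: clipping negative eigenvalues")
    lam = np.clip(lam, 0.0, None)
    V = evecs[:, order]
    # eigh returns S_w-orthonormal vectors, whose Euclidean scale (and sign)
    # depends on the scatter magnitude; rescale each direction to unit norm
    # with its largest-magnitude component positive so the projection is
    # stable across repeated estimates of the same subspace
    norms = np.linalg.norm(V, axis=0)
    norms[norms == 0] = 1.0
    V = V / norms
    signs = np.sign(V[np.abs(V).argmax(axis=0), np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    V = V * signs
    return FisherWeights(lam, V, V)


def reweight_features(
    gap: Union[GapVector, np.ndarray], fw: FisherWeights
) -> np.ndarray:
    """Project a feature vector and scale component j by lambda_j/max(lambda).

    The top discriminant direction keeps weight 1; the rest are attenuated in
    proportion to their eigenvalue.  All-zero eigenvalues yield a zero vector
    with a warning.
    """
    g = _values(gap)
    if g.shape[-1] != fw.projection.shape[0]:
        raise ValueError(
            f"dim mismatch: vector has {g.shape[-1]} dims, projection "
            f"expects {fw.projection.shape[0]}")
    proj = g @ fw.projection
    lam_max = fw.lambda_.max() if fw.lambda_.size else 0.0
    if lam_max <= 0.0:
        warnings.warn("reweight_features: all-zero eigenvalues; zero output")
        return np.zeros_like(proj)
    return proj * (fw.lambda_ / lam_max)


def fuse(
    weighted: Sequence[np.ndarray],
    fusion_weights: Sequence[np.ndarray],
) -> GlobalFeature:
    """Sum of per-scale linear maps: F_global = sum_s F_s @ W_s."""
    if len(weighted) != len(fusion_weights):
        raise ValueError("one fusion weight matrix per scale required")
    out = None
    for f, W in zip(weighted, fusion_weights):
        f = np.asarray(f)
        W = np.asarray(W)
        if f.shape[-1] != W.shape[0]:
            raise ValueError(
                f"fusion dim mismatch: feature dim {f.shape[-1]} vs weight "
                f"rows {W.shape[0]}")
        term = f @ W
        out = term if out is None else out + term
    return GlobalFeature(out)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Max-stabilized softmax."""
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def classify(
    global_feat: Union[GlobalFeature, np.ndarray],
    fc_weights: np.ndarray,
    fc_bias: np.ndarray,
) -> np.ndarray:
    """Softmax class probabilities of the fused global feature."""
    g = _values(global_feat)
    return softmax(g @ fc_weights + fc_bias)
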