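"""Identification and verification metrics for gallery/probe protocols.

Identification is closed-set: each probe window is scored against every
enrolled subject and the rank-k identification rate (IR) is the percentage of
probes whose true subject is among the k best-scoring ones.  Verification is
open-set pairwise: cosine similarities of global-feature pairs are split into
genuine (same subject) and impostor (different subject) scores, swept over
thresholds into a ROC of (FAR, TAR) points, and summarized as the
verification rate VR at a fixed false-acceptance rate (10^-3 by default).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np


@dataclass
class EvalReport:
    """Summary metrics of one gallery/probe evaluation."""

    rank1_ir: float
    rank5_ir: float
    roc: List[Tuple[float, float]]
    vr_at_far: Dict[float, float]
    n_probes: int = 0

    def to_dict(self) -> dict:
        return {
            "rank1_ir": self.rank1_ir,
            "rank5_ir": self.rank5_ir,
            "roc": [[float(f), float(t)] for f, t in self.roc],
            "vr_at_far": {str(k): float(v) for k, v in self.vr_at_far.items()},
            "n_probes": self.n_probes,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def rank_k_identification(
    probe_scores: np.ndarray, labels: np.ndarray, k: int
) -> float:
    """Percentage of probes whose true class is among the k highest scores.

    Ties are broken in favour of the lowest class index (a tied lower index
    outranks a tied higher one).
    """
    probe_scores = np.asarray(probe_scores)
    labels = np.asarray(labels)
    n_classes = probe_scores.shape[1]
    if not 1 <= k <= n_classes:
        raise ValueError(f"k must be in 1..{n_classes}")
    # stable sort on (-score, class index): lowest index wins ties
    order = np.argsort(-probe_scores, axis=1, kind="stable")
    topk = order[:, :k]
    hits = (topk == labels[:, None]).any(axis=1)
    return float(hits.mean() * 100.0)


def verification_scores(
    embeddings_a: np.ndarray, embeddings_b: np.ndarray
) -> np.ndarray:
    """Row-wise cosine similarity between two stacks of embeddings.

    Zero-norm embeddings score 0 with a warning.
    """
    a = np.atleast_2d(np.asarray(embeddings_a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(embeddings_b, dtype=np.float64))
    if a.shape != b.shape:
        raise ValueError("embedding stacks must have equal shapes")
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    bad = (na == 0) | (nb == 0)
    if np.any(bad):
        warnings.warn("verification_scores: zero-norm embedding, score 0")
    denom = np.where(bad, 1.0, na * nb)
    return np.where(bad, 0.0, (a * b).sum(axis=1) / denom)


def genuine_impostor_scores(
    embeddings: np.ndarray, labels: np.ndarray,
    max_pairs: Optional[int] = None, seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """All-pairs cosine scores split into genuine and impostor sets."""
    embeddings = np.asarray(embeddings, dtype=np.float64)
    labels = np.asarray(labels)
    n = len(labels)
    iu, ju = np.triu_indices(n, k=1)
    if max_pairs is not None and len(iu) > max_pairs:
        keep = np.random.default_rng(seed).choice(
            len(iu), size=max_pairs, replace=False)
        iu, ju = iu[keep], ju[keep]
    scores = verification_scores(embeddings[iu], embeddings[ju])
    same = labels[iu] == labels[ju]
    return scores[same], scores[~same]


def roc_curve(
    genuine_scores: np.ndarray,
    impostor_scores: np.ndarray,
    tar_definition: str = "tpr",
) -> List[Tuple[float, float]]:
    """Sweep accept thresholds over all distinct scores into (FAR, TAR).

    A pair is accepted when its score >= threshold.  FAR is the accepted
    fraction of impostor pairs.  TAR defaults to the true-positive rate
    TP/(TP+FN); ``tar_definition="printed"`` selects the precision form
    TP/(TP+FP) instead.  The curve is returned sorted by FAR ascending and
    includes the reject-all (0, .) and accept-all (1, 1) endpoints.
    """
    if tar_definition not in ("tpr", "printed"):
        raise ValueError("tar_definition must be 'tpr' or 'printed'")
    g = np.sort(np.asarray(genuine_scores, dtype=np.float64))
    i = np.sort(np.asarray(impostor_scores, dtype=np.float64))
    if g.size == 0 or i.size == 0:
        raise ValueError("both score sets must be non-empty")
    all_scores = np.unique(np.concatenate([g, i]))
    # thresholds: one below everything (accept all) plus every distinct score,
    # plus one above everything (reject all)
    thresholds = np.concatenate(
        [[all_scores[0] - 1.0], all_scores, [all_scores[-1] + 1.0]])
    points = []
    for thr in thresholds:
        tp = g.size - np.searchsorted(g, thr, side="left")
        fp = i.size - np.searchsorted(i, thr, side="left")
        fn = g.size - tp
        tn = i.size - fp
        far = fp / (fp + tn) if (fp + tn) else 0.0
        if tar_definition == "tpr":
            tar = tp / (tp + fn) if (tp + fn) else 0.0
        else:
            tar = tp / (tp + fp) if (tp + fp) else 0.0
        points.append((float(far), float(tar)))
    points.sort(key=lambda p: (p[0], p[1]))
    return points


def vr_at_far(
    roc: Sequence[Tuple[float, float]], far_target: float = 1e-3
) -> float:
    """TAR at a FAR operating point, linearly interpolated along the curve.

    If the target lies below the smallest achievable nonzero operating
    region, the TAR at the smallest FAR is returned with a warning.
    """
    if not len(roc):
        raise ValueError("empty ROC")
    far = np.array([p[0] for p in roc])
    tar = np.array([p[1] for p in roc])
    # collapse duplicate FARs to their best TAR, keep FAR ascending
    uniq_far, inv = np.unique(far, return_inverse=True)
    best_tar = np.full(uniq_far.shape, -np.inf)
    np.maximum.at(best_tar, inv, tar)
    if far_target < uniq_far[0]:
        warnings.warn(
            f"vr_at_far: target {far_target} below smallest achievable "
            f"FAR {uniq_far[0]}; returning TAR there")
        return float(best_tar[0])
    return float(np.interp(far_target, uniq_far, best_tar))


def evaluate(
    probe_probs: np.ndarray,
    probe_embeddings: np.ndarray,
    probe_labels: np.ndarray,
    far_targets: Sequence[float] = (1e-3, 1e-2),
) -> EvalReport:
    """Full report from probe class scores and global-feature embeddings."""
    probe_labels = np.asarray(probe_labels)
    n_classes = probe_probs.shape[1]
    rank1 = rank_k_identification(probe_probs, probe_labels, 1)
    rank5 = rank_k_identification(probe_probs, probe_labels, min(5, n_classes))
    genuine, impostor = genuine_impostor_scores(probe_embeddings, probe_labels)
    roc = roc_curve(genuine, impostor)
    vr = {t: vr_at_far(roc, t) for t in far_targets}
    return EvalReport(rank1, rank5, roc, vr, n_probes=len(probe_labels))
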