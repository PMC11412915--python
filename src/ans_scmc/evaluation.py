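"""Cross-validation protocols, ROC/AUC, and per-disease candidate ranking.

Two protocols over the known associations of a binary matrix A:

* LOOCV -- each known pair (i, j) is masked in turn, the whole pipeline
  (similarities included) is recomputed from the masked matrix, and the
  held-out score is compared against the scores of all pairs that are
  zero in the original A.  Each run contributes its positive score and
  that run's negative scores; all are pooled into one ROC.
* 5-fold CV -- the positives are split into five seeded groups of
  near-equal size.  Per fold the test group is zeroed in the training
  matrix; a seeded random set of zero pairs, as large as the training
  positive set, is earmarked as "training negatives" and excluded from
  the test-negative pool; the remaining zero pairs are test negatives.
  The overall AUC is the unweighted mean of the fold AUCs.

AUC uses the Mann-Whitney convention: ties between a positive and a
negative score count 1/2.  Similarity matrices are always recomputed
inside each fold from the masked matrix — anything else would leak the
held-out associations through the neighbourhood structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .io_data import AssociationMatrix, ScoreMatrix
from .scmc import predict

logger = logging.getLogger(__name__)

__all__ = ["CvResult", "roc_auc", "loocv", "cv5", "rank_candidates"]


@dataclass
class CvResult:
    mode: str  # "loocv" | "cv5"
    auc: float
    fold_aucs: tuple[float, ...]
    roc_points: list[tuple[float, float]]
    seed: int | None = None


def roc_auc(
    pos_scores: Sequence[float], neg_scores: Sequence[float]
) -> tuple[float, list[tuple[float, float]]]:
    """Mann-Whitney AUC and ROC points for two score samples.

    The AUC equals the probability that a random positive outscores a
    random negative, ties counting one half; computed via midranks, which
    is exactly the normalised pairwise count.  ROC points come from a
    threshold sweep over the union of the scores.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need at least one positive and one negative score")
    ranks = rankdata(np.concatenate([pos, neg]))  # midranks handle ties
    auc = (ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0) / (
        pos.size * neg.size
    )
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    fpr, tpr, _ = roc_curve(labels, np.concatenate([pos, neg]))
    return float(auc), list(zip(fpr.tolist(), tpr.tolist()))


def loocv(
    A: AssociationMatrix,
    config=None,
    *,
    predict_fn: Callable[[AssociationMatrix, object], ScoreMatrix] = predict,
) -> CvResult:
    """Leave-one-out cross-validation over the known associations.

    ``predict_fn`` exists for instrumentation (e.g. asserting that the
    matrix seen by the pipeline really has the held-out entry zeroed);
    it defaults to the full pipeline.
    """
    positives = A.positives()
    if len(positives) < 2:
        raise ValueError("LOOCV needs at least 2 known associations")
    zero_mask = A.values == 0
    pos_scores: list[float] = []
    neg_scores: list[float] = []
    for idx, (i, j) in enumerate(positives):
        masked = A.with_zeroed([(i, j)])
        P = predict_fn(masked, config)
        pos_scores.append(float(P.values[i, j]))
        neg_scores.extend(P.values[zero_mask].tolist())
        if (idx + 1) % 25 == 0:
            logger.info("LOOCV: %d/%d folds done", idx + 1, len(positives))
    auc, points = roc_auc(pos_scores, neg_scores)
    return CvResult(mode="loocv", auc=auc, fold_aucs=(), roc_points=points)


def cv5(
    A: AssociationMatrix,
    config=None,
    seed: int = 0,
    *,
    n_folds: int = 5,
    predict_fn: Callable[[AssociationMatrix, object], ScoreMatrix] = predict,
) -> CvResult:
    """Five-fold cross-validation with negative down-sampling.

    Fold sizes differ by at most one.  Two calls with the same seed give
    identical partitions, negative draws, and AUCs.
    """
    positives = A.positives()
    n_pos = len(positives)
    if n_pos < n_folds:
        raise ValueError(f"need at least {n_folds} known associations")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_pos)
    folds = np.array_split(order, n_folds)
    zeros = np.argwhere(A.values == 0)
    fold_aucs: list[float] = []
    all_points: list[tuple[float, float]] = []
    for f, test_idx in enumerate(folds):
        test_pairs = [tuple(positives[t]) for t in test_idx]
        masked = A.with_zeroed(test_pairs)
        n_train_pos = n_pos - len(test_pairs)
        # training negatives: sampled from the original zero pairs, same
        # count as the training positives; only used to shrink the
        # test-negative pool
        n_train_neg = min(n_train_pos, len(zeros))
        train_neg_idx = rng.choice(len(zeros), size=n_train_neg, replace=False)
        train_neg = set(map(tuple, zeros[train_neg_idx]))
        P = predict_fn(masked, config)
        pos_scores = [float(P.values[i, j]) for i, j in test_pairs]
        neg_scores = [
            float(P.values[i, j])
            for i, j in map(tuple, zeros)
            if (i, j) not in train_neg
        ]
        auc, points = roc_auc(pos_scores, neg_scores)
        fold_aucs.append(auc)
        all_points.extend(points)
        logger.info("cv5: fold %d/%d AUC = %.4f", f + 1, n_folds, auc)
    return CvResult(
        mode="cv5",
        auc=float(np.mean(fold_aucs)),
        fold_aucs=tuple(fold_aucs),
        roc_points=all_points,
        seed=seed,
    )


def rank_candidates(
    P: ScoreMatrix, A: AssociationMatrix, disease: str, top_n: int
) -> list[tuple[str, float]]:
    """Top candidate microbes for a disease, excluding known associations.

    Returns up to ``top_n`` (microbe_id, score) pairs in descending score
    order; score ties resolve to the lower microbe index.
    """
    if disease not in A.disease_ids:
        raise KeyError(f"unknown disease label: {disease!r}")
    j = A.disease_ids.index(disease)
    candidates = np.flatnonzero(A.values[:, j] == 0)
    scores = P.values[candidates, j]
    order = np.lexsort((candidates, -scores))
    ranked = candidates[order][:top_n]
    return [(A.microbe_ids[i], float(P.values[i, j])) for i in ranked]
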