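"""Weighted k-nearest-known-neighbour (WKNKN) sparsity reduction.

A binary association matrix records only verified links; most zeros are
unobserved rather than true negatives.  WKNKN replaces each zero with a
plausibility score borrowed from the profiles of the k most similar
*known* neighbours (entities with at least one recorded association),
estimated independently from the microbe axis and the disease axis and
averaged.

For microbe i with known neighbours n_1..n_k ranked by descending GIP
similarity MF(i, .):

    Am(i, :) = (1/Z_m) * sum_t alpha^(t-1) * MF(i, n_t) * A(n_t, :),
    Z_m      = sum_t MF(i, n_t)

with decay weight ``alpha <= 1`` down-weighting farther neighbours.  The
disease-side estimate Ad is built the same way from columns and DF.  The
two estimates are averaged, Q = (Am + Ad) / 2, and only the zero cells of
A are filled:  AW_ij = A_ij if A_ij != 0 else Q_ij.  Known associations
are therefore always preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_data import AssociationMatrix, FilledMatrix, SimilarityMatrix

__all__ = ["WknknParams", "wknkn_fill"]


@dataclass(frozen=True)
class WknknParams:
    """Neighbour count ``k`` and geometric decay weight ``alpha``."""

    k: int = 6
    alpha: float = 0.8

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")


def _neighbour_estimate(
    A: np.ndarray, S: np.ndarray, known: np.ndarray, k: int, alpha: float
) -> np.ndarray:
    """Row-wise weighted neighbour profile estimate.

    ``A`` is (n, p); ``S`` is the (n, n) similarity among the rows;
    ``known`` flags rows with at least one association.  Rows with no
    known neighbours (other than themselves) get an all-zero estimate.
    Similarity ties are broken by ascending row index for determinism.
    """
    n = A.shape[0]
    est = np.zeros(A.shape, dtype=float)
    short = 0
    for i in range(n):
        cand = np.flatnonzero(known)
        cand = cand[cand != i]
        if cand.size == 0:
            continue
        if cand.size < k:
            short += 1
        sims = S[i, cand]
        # stable sort on -sims: ties resolve to the lower index
        order = np.argsort(-sims, kind="stable")[: min(k, cand.size)]
        neigh = cand[order]
        sims = sims[order]
        Z = sims.sum()
        if Z == 0:
            continue
        w = alpha ** np.arange(neigh.size) * sims
        est[i, :] = w @ A[neigh, :] / Z
    if short:
        warnings.warn(
            f"{short} rows had fewer than k={k} known neighbours; "
            "used all available neighbours",
            stacklevel=3,
        )
    return est


def wknkn_fill(
    A: AssociationMatrix,
    MF: SimilarityMatrix,
    DF: SimilarityMatrix,
    params: WknknParams = WknknParams(),
) -> FilledMatrix:
    """Fill the zero entries of ``A`` from both axes' known neighbours.

    ``MF``/``DF`` must be similarity matrices on the microbe/disease axis
    of ``A`` (same labels, same order).
    """
    if MF.axis != "microbe" or DF.axis != "disease":
        raise ValueError("MF must be a microbe similarity and DF a disease similarity")
    if MF.ids != A.microbe_ids or DF.ids != A.disease_ids:
        raise ValueError("similarity labels do not match the association matrix")
    values = A.values.astype(float)
    known_rows = values.sum(axis=1) > 0
    known_cols = values.sum(axis=0) > 0
    Am = _neighbour_estimate(values, MF.values, known_rows, params.k, params.alpha)
    Ad = _neighbour_estimate(
        values.T, DF.values, known_cols, params.k, params.alpha
    ).T
    Q = (Am + Ad) / 2.0
    np.clip(Q, 0.0, 1.0, out=Q)
    AW = np.where(values != 0, values, Q)
    return FilledMatrix(AW, A.microbe_ids, A.disease_ids)
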