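"""Sparse-constrained logistic matrix completion (SCMC).

The filled association matrix AW is modelled through low-rank latent
factors: microbe features M (nm x r) and disease features D (nd x r),
with association probability

    P_ij = sigma(m_i . d_j) = 1 / (1 + exp(-m_i . d_j)).

The factors minimise a weighted logistic negative log-likelihood plus a
sparsity (Frobenius) penalty and graph-Laplacian penalties that pull the
features of similar microbes (diseases) together:

    LOSS = sum_ij w_ij [ ln(1 + exp(m_i . d_j)) - AW_ij (m_i . d_j) ]
         + lambda_R (||M||_F^2 + ||D||_F^2)
         + lambda_alpha tr(M^T L_MS M) + lambda_beta tr(D^T L_DS D)

where L_S = diag(rowsum S) - S is the unnormalised graph Laplacian of a
symmetric similarity matrix S.  Optimisation is plain gradient descent
with a Frobenius-normalised fixed step: each update moves M (and D) by
exactly ``epsilon`` in Frobenius norm.  Iteration stops when the change
of both factor norms, |‖M_{n+1}‖_F - ‖M_n‖_F| and its D analogue, falls
below ``tol``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit

from .io_data import (
    AssociationMatrix,
    FilledMatrix,
    ScoreMatrix,
    SimilarityMatrix,
)

__all__ = [
    "ScmcParams",
    "FactorPair",
    "sigmoid_scores",
    "scmc_loss",
    "scmc_gradients",
    "scmc_fit",
    "predict",
]


@dataclass(frozen=True)
class ScmcParams:
    """Hyperparameters of the sparse-constrained completion step.

    rank
        Latent dimension r of the factor matrices.
    lambda_R
        Sparsity (Frobenius) penalty on both factors.
    lambda_alpha, lambda_beta
        Graph-Laplacian penalty weights for the microbe and disease
        similarity graphs respectively.
    epsilon
        Fixed Frobenius-normalised step size of the gradient updates.
    tol
        Stopping threshold on the change of the factor norms.
    seed
        Seed for the Gaussian factor initialisation; ``None`` defers to
        the pipeline-level seed.
    """

    rank: int = 10
    lambda_R: float = 0.01
    lambda_alpha: float = 0.1
    lambda_beta: float = 0.1
    epsilon: float = 0.1
    tol: float = 1e-5
    max_iter: int = 5000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.epsilon <= 0 or self.tol <= 0:
            raise ValueError("epsilon and tol must be > 0")
        if min(self.lambda_R, self.lambda_alpha, self.lambda_beta) < 0:
            raise ValueError("penalty weights must be >= 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class FactorPair:
    """Fitted latent factors with optimisation diagnostics."""

    M: np.ndarray
    D: np.ndarray
    iteration: int
    loss_trace: list[float] = field(default_factory=list)
    converged: bool = False


def sigmoid_scores(
    M: np.ndarray,
    D: np.ndarray,
    *,
    microbe_ids: Sequence[str] | None = None,
    disease_ids: Sequence[str] | None = None,
) -> ScoreMatrix:
    """Association probabilities P = sigma(M D^T), overflow-safe."""
    M = np.asarray(M, dtype=float)
    D = np.asarray(D, dtype=float)
    P = expit(M @ D.T)
    # expit saturates to exactly 0/1 for |x| beyond ~±37; nudge inside (0, 1)
    tiny = np.finfo(float).tiny
    np.clip(P, tiny, 1.0 - np.finfo(float).epsneg, out=P)
    if microbe_ids is None:
        microbe_ids = [str(i) for i in range(M.shape[0])]
    if disease_ids is None:
        disease_ids = [str(j) for j in range(D.shape[0])]
    return ScoreMatrix(P, tuple(microbe_ids), tuple(disease_ids))


def _laplacian(S: SimilarityMatrix) -> np.ndarray:
    V = S.values
    if not np.allclose(V, V.T, atol=1e-12, rtol=0.0):
        raise ValueError(
            f"{S.axis} similarity matrix must be symmetric for the Laplacian"
        )
    return np.diag(V.sum(axis=1)) - V


def _as_array(x) -> np.ndarray:
    return np.asarray(x.values if hasattr(x, "values") else x, dtype=float)


def scmc_loss(
    M: np.ndarray,
    D: np.ndarray,
    AW,
    W_loss,
    MS: SimilarityMatrix,
    DS: SimilarityMatrix,
    params: ScmcParams,
) -> float:
    """Weighted logistic loss with sparsity and Laplacian penalties."""
    AWv = _as_array(AW)
    Wv = _as_array(W_loss)
    MD = np.asarray(M, dtype=float) @ np.asarray(D, dtype=float).T
    data = float(np.sum(Wv * (np.logaddexp(0.0, MD) - AWv * MD)))
    reg = params.lambda_R * (float(np.sum(M**2)) + float(np.sum(D**2)))
    graph = 0.0
    if params.lambda_alpha != 0:
        graph += params.lambda_alpha * float(np.trace(M.T @ _laplacian(MS) @ M))
    if params.lambda_beta != 0:
        graph += params.lambda_beta * float(np.trace(D.T @ _laplacian(DS) @ D))
    return data + reg + graph


def scmc_gradients(
    M: np.ndarray,
    D: np.ndarray,
    AW,
    W_loss,
    MS: SimilarityMatrix,
    DS: SimilarityMatrix,
    params: ScmcParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Partial derivatives of :func:`scmc_loss` w.r.t. M and D.

    B_M = (W ⊙ (P - AW)) D + 2 lambda_R M + 2 lambda_alpha L_MS M
    B_D = (W ⊙ (P - AW))^T M + 2 lambda_R D + 2 lambda_beta L_DS D
    """
    AWv = _as_array(AW)
    Wv = _as_array(W_loss)
    P = expit(np.asarray(M, dtype=float) @ np.asarray(D, dtype=float).T)
    R = Wv * (P - AWv)
    B_M = R @ D + 2.0 * params.lambda_R * M
    B_D = R.T @ M + 2.0 * params.lambda_R * D
    if params.lambda_alpha != 0:
        B_M = B_M + 2.0 * params.lambda_alpha * (_laplacian(MS) @ M)
    if params.lambda_beta != 0:
        B_D = B_D + 2.0 * params.lambda_beta * (_laplacian(DS) @ D)
    return B_M, B_D


def scmc_fit(
    AW: FilledMatrix,
    W_loss: np.ndarray | None,
    MS: SimilarityMatrix,
    DS: SimilarityMatrix,
    params: ScmcParams = ScmcParams(),
    *,
    seed: int | None = None,
    init: tuple[np.ndarray, np.ndarray] | None = None,
    callback: Callable[[int, np.ndarray, np.ndarray, np.ndarray, np.ndarray], None]
    | None = None,
) -> tuple[FactorPair, ScoreMatrix]:
    """Fit the latent factors by normalised gradient descent.

    The factors start from i.i.d. N(0, 1/sqrt(r)) entries (or from
    ``init`` when given, which makes equivariance properties testable).
    A zero gradient is treated as convergence.  ``callback`` is invoked
    after every update with (iteration, M, D, B_M, B_D).
    """
    AWv = AW.values
    nm, nd = AWv.shape
    r = params.rank
    if r > min(nm, nd):
        raise ValueError("rank must not exceed min(nm, nd)")
    if W_loss is None:
        W_loss = np.ones((nm, nd))
    Wv = np.asarray(W_loss, dtype=float)
    if (Wv < 0).any() or not np.isfinite(Wv).all():
        raise ValueError("loss weights must be finite and >= 0")
    L_MS = _laplacian(MS) if params.lambda_alpha != 0 else None
    L_DS = _laplacian(DS) if params.lambda_beta != 0 else None

    if init is not None:
        M = np.array(init[0], dtype=float, copy=True)
        D = np.array(init[1], dtype=float, copy=True)
    else:
        if seed is None:
            seed = params.seed if params.seed is not None else 42
        rng = np.random.default_rng(seed)
        std = 1.0 / np.sqrt(r)
        M = rng.normal(0.0, std, size=(nm, r))
        D = rng.normal(0.0, std, size=(nd, r))

    loss_trace: list[float] = []
    converged = False
    iteration = 0
    norm_M = float(np.linalg.norm(M))
    norm_D = float(np.linalg.norm(D))
    for iteration in range(1, params.max_iter + 1):
        MD = M @ D.T
        P = expit(MD)
        R = Wv * (P - AWv)
        B_M = R @ D + 2.0 * params.lambda_R * M
        B_D = R.T @ M + 2.0 * params.lambda_R * D
        if params.lambda_alpha != 0:
            B_M += 2.0 * params.lambda_alpha * (L_MS @ M)
        if params.lambda_beta != 0:
            B_D += 2.0 * params.lambda_beta * (L_DS @ D)

        loss = float(np.sum(Wv * (np.logaddexp(0.0, MD) - AWv * MD)))
        loss += params.lambda_R * (norm_M**2 + norm_D**2)
        if params.lambda_alpha != 0:
            loss += params.lambda_alpha * float(np.einsum("ij,ij->", M, L_MS @ M))
        if params.lambda_beta != 0:
            loss += params.lambda_beta * float(np.einsum("ij,ij->", D, L_DS @ D))
        if not np.isfinite(loss):
            raise FloatingPointError(f"loss diverged at SCMC iteration {iteration}")
        loss_trace.append(loss)

        nB_M = float(np.linalg.norm(B_M))
        nB_D = float(np.linalg.norm(B_D))
        if nB_M == 0.0 or nB_D == 0.0:
            converged = True
            break
        M = M - params.epsilon * B_M / nB_M
        D = D - params.epsilon * B_D / nB_D
        if callback is not None:
            callback(iteration, M, D, B_M, B_D)
        new_norm_M = float(np.linalg.norm(M))
        new_norm_D = float(np.linalg.norm(D))
        delta_M = abs(new_norm_M - norm_M)
        delta_D = abs(new_norm_D - norm_D)
        norm_M, norm_D = new_norm_M, new_norm_D
        if max(delta_M, delta_D) < params.tol:
            converged = True
            break

    factors = FactorPair(
        M=M, D=D, iteration=iteration, loss_trace=loss_trace, converged=converged
    )
    scores = sigmoid_scores(
        M, D, microbe_ids=AW.microbe_ids, disease_ids=AW.disease_ids
    )
    return factors, scores


def predict(A: AssociationMatrix, config=None) -> ScoreMatrix:
    """Run the full pipeline on an association matrix and return the scores.

    Stages: GIP kernel similarity on both axes, WKNKN filling, adaptive
    neighbourhood similarity learning (on the filled matrix by default),
    then sparse-constrained logistic completion regularised by the learned
    similarity graphs.  See :class:`ans_scmc.config.PipelineConfig` for
    every knob.
    """
    from .config import PipelineConfig
    from .gip import make_mf_df
    from .wknkn import wknkn_fill
    from .ans import make_ms_ds

    if config is None:
        config = PipelineConfig()
    MF, DF = make_mf_df(A, config.gip)
    AW = wknkn_fill(A, MF, DF, config.wknkn)
    ans_input = AW.values if config.ans_input == "AW" else A.values.astype(float)
    MS, DS = make_ms_ds(
        ans_input,
        config.ans,
        microbe_ids=A.microbe_ids,
        disease_ids=A.disease_ids,
    )
    reg_m, reg_d = (MS, DS) if config.reg_similarity == "ans" else (MF, DF)
    seed = config.scmc.seed if config.scmc.seed is not None else config.seed
    _, scores = scmc_fit(AW, None, reg_m, reg_d, config.scmc, seed=seed)
    return scores
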