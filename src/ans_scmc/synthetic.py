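"""Seeded synthetic association matrices with planted low-rank structure.

Every stage of the pipeline — and its end-to-end ranking behaviour — can
be exercised without any external download by generating bipartite 0/1
matrices whose association probabilities follow a planted logistic
low-rank model:

    ground_truth = sigma(U V^T - c),  U: nm x r, V: nd x r, iid N(0, 1)

with the offset c calibrated by bisection so that the expected fraction
of ones matches the requested ``density``.  The binary matrix is a
Bernoulli draw from ground_truth, optionally corrupted by independent
bit flips.  A repair pass then gives every empty row and column one
association at its most probable cell, mirroring the premise that every
catalogued entity has at least one verified counterpart — and ensuring
the "known neighbour" sets used by the filling step are never empty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .io_data import AssociationMatrix

__all__ = ["SyntheticSpec", "generate", "hmdad_scale_fixture"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Shape, structure and noise of a generated benchmark instance."""

    nm: int = 60
    nd: int = 20
    planted_rank: int = 5
    density: float = 0.08
    noise_flip_prob: float = 0.0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.nm < 2 or self.nd < 2:
            raise ValueError("need nm >= 2 and nd >= 2")
        if not 1 <= self.planted_rank <= min(self.nm, self.nd):
            raise ValueError("planted_rank must lie in [1, min(nm, nd)]")
        if not 0 < self.density < 1:
            raise ValueError("density must lie in (0, 1)")
        if not 0 <= self.noise_flip_prob < 1:
            raise ValueError("noise_flip_prob must lie in [0, 1)")


def generate(spec: SyntheticSpec) -> tuple[AssociationMatrix, np.ndarray]:
    """Draw a seeded association matrix and its planted ground truth.

    Returns ``(A, ground_truth)`` where ``ground_truth[i, j]`` is the
    planted probability that microbe i associates with disease j.  The
    same spec (seed included) always yields byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    U = rng.standard_normal((spec.nm, spec.planted_rank))
    V = rng.standard_normal((spec.nd, spec.planted_rank))
    logits = U @ V.T
    c = brentq(lambda c: float(expit(logits - c).mean()) - spec.density, -60.0, 60.0)
    truth = expit(logits - c)
    values = (rng.random(truth.shape) < truth).astype(np.int8)
    if spec.noise_flip_prob > 0:
        flips = rng.random(truth.shape) < spec.noise_flip_prob
        values = np.where(flips, 1 - values, values)
    # repair: every row/column keeps at least one association
    for i in np.flatnonzero(values.sum(axis=1) == 0):
        values[i, int(np.argmax(truth[i]))] = 1
    for j in np.flatnonzero(values.sum(axis=0) == 0):
        values[int(np.argmax(truth[:, j])), j] = 1
    microbe_ids = [f"m{i+1}" for i in range(spec.nm)]
    disease_ids = [f"d{j+1}" for j in range(spec.nd)]
    return AssociationMatrix(values, microbe_ids, disease_ids), truth


def hmdad_scale_fixture(seed: int = 2024) -> AssociationMatrix:
    """A 292 x 39 synthetic matrix with roughly 450 associations.

    Mimics the shape and sparsity of the public microbe-disease
    association corpus for performance and smoke tests.  The requested
    density is set below the nominal 450/(292*39) because the repair pass
    re-populates empty rows, which at this sparsity are common.
    """
    spec = SyntheticSpec(
        nm=292, nd=39, planted_rank=5, density=0.027, noise_flip_prob=0.0, seed=seed
    )
    A, _ = generate(spec)
    return A
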