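# ans-scmc

Prediction of unobserved microbe–disease associations from a sparse binary
association matrix, by **a**daptive **n**eighbourhood **s**imilarity learning
combined with **s**parse-**c**onstrained logistic **m**atrix **c**ompletion
(ANS-SCMC).

## Who this is for

Microbiome researchers who have a curated catalogue of verified
microbe–disease links (for example a genus-level catalogue such as HMDAD,
292 microbes × 39 diseases with 450 distinct associations) and want a
ranked list of *candidate* associations to prioritise for experimental
follow-up. Only the 0/1 association matrix is required — no taxonomy,
sequence or ontology inputs.

## The method

Let `A ∈ {0,1}^{nm×nd}` be the association matrix over `nm` microbes and
`nd` diseases. The pipeline has four stages:

1. **GIP kernel similarity.** Each microbe's interaction profile is its
   row of `A`; similarity is a Gaussian kernel on profiles,
   `MF_ij = exp(−θ_m ‖a_i − a_j‖²)` with bandwidth normalised by the mean
   squared profile norm, `θ_m = θ′ / ((1/nm) Σ_i ‖a_i‖²)`. `DF` is built
   the same way from columns.
2. **WKNKN filling.** Each zero of `A` is replaced by a weighted average
   of the profiles of the `K` most similar *known* neighbours (entities
   with at least one association), with geometric decay `α^{t−1}`,
   computed from both axes and averaged; known entries are kept at 1.
   The result is the filled matrix `AW ∈ [0,1]^{nm×nd}`.
3. **Adaptive neighbourhood similarity (ANS).** A similarity graph `W` is
   *learned* rather than fixed, by alternating closed-form updates of a
   regularised manifold objective with a proxy variable `L`:
   `W ← r₂/(r₁+r₂)·(D_W − L)` (projected onto `[0,1]`, zero diagonal) and
   `L ← D_W − W − (1/r₂)·XXᵀ`, until the squared Frobenius change of both
   iterates falls below `10⁻³`. This yields `MS` (microbes) and `DS`
   (diseases).
4. **SCMC.** Latent factors `M ∈ R^{nm×r}`, `D ∈ R^{nd×r}` score each
   pair through `P_ij = σ(m_i·d_j)` and minimise the weighted logistic
   loss on `AW` plus a sparsity penalty `λ_R(‖M‖²_F+‖D‖²_F)` and graph
   penalties `λ_α tr(Mᵀ L_MS M) + λ_β tr(Dᵀ L_DS D)`, by gradient descent
   with a Frobenius-normalised fixed step `ε` until the factor norms
   stabilise below `10⁻⁵`.

Defaults (`K=6, α=0.8, θ′=1, r₁=7, r₂=4, λ_R=0.01, λ_α=λ_β=0.1, ε=0.1,
r=10`) are the grid-search-selected values for the benchmark corpus; all
are exposed in a strict YAML config. Evaluation (LOOCV and five-fold CV
with negative down-sampling, Mann–Whitney AUC) recomputes every
similarity inside each fold so no held-out information leaks.

## Worked example

Generate a seeded synthetic benchmark (planted low-rank structure), score
it, and rank candidates for one disease:

```console
$ ans-scmc synth --nm 60 --nd 20 --rank 5 --density 0.08 --seed 1 --out A.tsv
wrote 60x20 matrix with 108 associations to A.tsv

$ ans-scmc predict --input A.tsv --output scores.csv
wrote 60x20 score matrix to scores.csv

$ ans-scmc rank --input A.tsv --disease d7 --top 5
d7      m49     0.285694
d7      m38     0.275124
d7      m15     0.135076
d7      m58     0.113357
d7      m29     0.111396

$ ans-scmc eval --input A.tsv --mode cv5 --seed 1
cv5 AUC = 0.6018 (1.6s)
```

`scores.csv` holds `P_ij = σ(m_i·d_j)`, the predicted association
probability for every pair (known pairs score near 1 by construction).
The `rank` output lists the five highest-scoring microbes *not* already
associated with disease `d7` — the candidates one would take to
validation. The `eval` line is the mean held-out AUC over five seeded
folds: the probability that a masked true association outscores a random
unobserved pair. On this synthetic instance the held-out AUC is modest;
see `docs/methods.md` for an analysis of what the planted generator does
and does not make achievable.

Every output CSV begins with `#`-comment provenance lines (config hash
and seed), so a result file identifies the exact parameter set that
produced it.

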