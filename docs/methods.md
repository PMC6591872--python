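# Methods

## Problem and model

The package predicts missing links in a bipartite miRNA–disease association
network. The input is a binary matrix **Y** ∈ {0,1}^(n×m) (rows miRNAs,
columns diseases) in which 1 means a curated association and 0 means
*unknown* — the data contain no confirmed negatives. The working assumption,
standard in this literature, is that functionally similar miRNAs associate
with phenotypically similar diseases, so similarity structure on each side
carries information about unobserved links.

NPCMF factorizes **Y ≈ ABᵀ** with **A** ∈ ℝ^(n×k), **B** ∈ ℝ^(m×k),
minimizing

```
L(A,B) = ‖Y − ABᵀ‖²_F
       + λ_l (‖A‖²_F + ‖B‖²_F)
       + λ_d ‖N_m − AAᵀ‖²_F
       + λ_t ‖N_d − BBᵀ‖²_F .
```

The first term fits the (imputed) associations, the second is Tikhonov
shrinkage, and the last two pull each side's factor Gram matrix toward a
*nearest-profile* (NP) target. The NP matrix is built from the fused kernel
in four steps: remove self-similarity, find each entity's most similar other
entity, zero everything else, and keep the kernel value at the surviving
position. It is deliberately asymmetric (row i keeps i's nearest neighbour;
an optional `symmetrize` flag averages with the transpose but is off by
default), and the stored value is the similarity itself, not an indicator,
because the NP prediction for a profile is similarity-scaled:
`Y_NP(i) = K(i, nearest) · Y(nearest)`. The NP construction is also what
lets the model say something about a *new* entity with no known
associations: its profile is borrowed from its nearest neighbour
(`np_profile`).

Two ablation modes replace the NP targets: `semantic` uses the supplied
similarity matrices S_m/S_d directly (classic collaborative matrix
factorization, CMF) and `fused` uses the fused kernels K_m/K_d.

## Similarity kernels

* **GIP kernel** — `exp(−γ‖y_i − y_j‖²)` over binary association profiles
  (rows of Y for miRNAs, columns for diseases). γ defaults to 1 and is used
  literally, with no per-profile bandwidth normalization; entries are in
  (0,1] with unit diagonal by construction.
* **Fusion** — K = α·S + (1−α)·GIP elementwise, α ∈ [0,1], default α = 0.5.
  At α = 1 the supplied similarity is used alone, at α = 0 the pure network
  kernel.
* **Disease semantic similarity** — from a child→parent disease hierarchy.
  Each disease D defines contributions over its ancestor closure T(D):
  D1_D(D) = 1 and D1_D(d) = Δ·max over d's children inside T(D), with decay
  Δ = 0.5 by default. Pairwise similarity is the sum of both diseases'
  contributions over shared ancestors, normalized by the sum of their total
  semantic values; it is 1 on the diagonal and 0 for disjoint closures.
  Where a node has several parents the recursion takes the max over child
  paths (a sum over paths is a conceivable variant; max matches the
  recursion as defined and is what the brute-force oracle in the tests
  evaluates).

## WKNKN pre-imputation

Before factorization, unknown zeros are softened: for each miRNA i the K
most similar miRNAs *with at least one known association* (the query itself
excluded) contribute their rows with weights p^(t−1)·K_m(i, i_t), normalized
by the sum of the neighbours' similarities; the disease side is analogous
over columns. The two estimates are averaged and combined with Y by an
elementwise max, so known 1-entries are always preserved and the output
stays in [0,1]. Defaults K = 5, p = 0.7 (the values at which cross-validated
AUC stabilizes). If fewer than K known neighbours exist, all available are
used; an entity with no known neighbours gets a zero estimate on that side.
Neighbour ties break toward the smaller index.

## Optimization

**A**, **B** are initialized from the rank-k truncated SVD of the (imputed)
matrix, A = U_k·S_k^½, B = V_k·S_k^½, with a deterministic sign convention
(each left singular vector's largest-magnitude entry made positive), so fits
are bit-reproducible without a random seed. Updates alternate:

```
A ← (Y B + λ_d N_m A)(BᵀB + λ_l I_k + λ_d AᵀA)⁻¹
B ← (Yᵀ A + λ_t N_d B)(AᵀA + λ_l I_k + λ_t BᵀB)⁻¹
```

with the freshly updated A entering the B step (Gauss–Seidel order, the
usual ALS practice) and the pre-update factor in each quadratic regularizer
term. These are the stationarity conditions read as a fixed point, not
exact per-block minimizers — with λ_d, λ_t > 0 the objective is quartic in
each factor — so the objective trace is recorded and monitored rather than
assumed monotone; in practice it decreases after the first few iterations
on essentially all random instances (checked as a soft property in the
tests). Each k×k solve gets one retry with 1e-10·I jitter if singular.
Iteration stops when the relative objective change drops below `tol`
(default 1e-6) or after `max_iter` (default 100) updates.

Note the k×k system in the A-update contains λ_d·AᵀA. Writing the
regularizer's contribution with an n×n AAᵀ there instead is a
dimensionally inconsistent variant sometimes seen in print; the k×k form is
the one consistent with the B-update and with the CMF family this model
extends.

## Hyperparameters

| parameter | default | meaning |
|---|---|---|
| k | min(50, n, m) | factor rank; tests and the synthetic study use k = 10, matched to the planted rank-5 structure |
| λ_l | 1.0 | Tikhonov weight |
| λ_d, λ_t | 0.01 | side-regularizer weights; normally set by `grid_search` over λ_l ∈ {2⁻², 2⁻¹, 2⁰, 2¹} and λ_d/λ_l, λ_t/λ_l ∈ {0, 10⁻⁴, 10⁻³, 10⁻², 10⁻¹} (the λ_t ratio reuses the λ_d grid — symmetric treatment of the two sides) |
| α | 0.5 | kernel fusion weight |
| γ | 1.0 | GIP bandwidth, used literally |
| K, p | 5, 0.7 | WKNKN neighbours and decay |
| max_iter, tol | 100, 1e-6 | ALS stopping rule |

## Evaluation protocol

Cross-validation is over *pairs* (CV-p): the known 1-entries are randomly
partitioned into five near-equal folds, and each fold in turn is zeroed in
the training matrix while all entities remain present. Everything downstream
— GIP kernels, fusion, WKNKN, NP matrices, the fit itself — is recomputed
from the masked matrix in every fold, so held-out positives cannot leak into
training (an instrumented test asserts this at every pipeline stage).
Held-out positives are scored against all pairs that are 0 in the *full*
matrix (unknowns treated as negatives, the field's convention; the
alternative of excluding test positives' cells from the negative set is
moot since the sets are disjoint by construction). AUC is computed per fold
with the tie-aware ROC statistic and averaged per repeat; repeats default
to 100 in the CLI but the tests and the acceptance study use 1, which at
the synthetic problem size already has a std of well under 0.01 across
seeds. Per-fold-then-average (rather than pooling scores across folds) was
chosen because fold models are distinct estimators; at these sizes the two
differ negligibly.

## Synthetic data generator

`synthetic.generate` plants exactly the structure the model assumes so that
every stage of the pipeline has signal to exploit and a known answer:

* latent rank-r factors with cluster structure (cluster centres ~ N(0,1),
  members = centre + 0.3·N(0,1)); the top `association_density` fraction of
  the latent score matrix becomes the truth matrix;
* per-side similarities that are high (0.8) within a cluster and low (0.2)
  between, plus symmetric Gaussian noise (sd 0.05), clipped to [0,1] with
  unit diagonal;
* a rooted two-level disease hierarchy (cluster heads under a root, members
  under their head), giving a valid DAG over the disease identifiers;
* an observed matrix hiding round(`mask_fraction`·positives) of the 1s.

Defaults: 100 miRNAs × 80 diseases, planted rank 5, 5/4 clusters per side,
density 0.1, mask fraction 0.1 — sized so the full cross-validated study
runs in seconds on one CPU while leaving the low-rank structure clearly
recoverable.

What the fixture does *not* emulate: the heavy-tailed degree distribution of
curated association databases, incomplete and biased curation, similarity
matrices estimated from noisy annotation data, or a realistic ontology
depth. Passing the synthetic study therefore shows the pipeline is
implemented correctly and recovers planted structure under its own
assumptions; it does not by itself certify performance on curated data.

On this fixture the end-to-end gain of the full method over the plain-CMF
baseline (run as published: S_m/S_d regularizer targets, no WKNKN) is driven
mainly by WKNKN imputation and GIP fusion; swapping only the regularizer
target (NP vs the fixture's clean block similarities) while keeping WKNKN is
close to a tie, consistent with the nearest-profile term being most useful
when the supplied similarities are noisy or entities are new — and with the
known caveat that excessive NP information can itself add noise.

## Numerical and design notes

* All matrices are dense; at the scale this method targets (hundreds by
  hundreds) memory is trivial.
* Argmax and neighbour-ranking ties break toward the smallest index
  everywhere, so runs are exactly reproducible.
* Similarity files are reconciled at load: symmetrized by averaging (with a
  logged warning beyond 1e-6 asymmetry) and unit diagonal enforced.
* WKNKN output (real-valued) enters the data-fit term, since imputation
  exists precisely to replace the unknown zeros before fitting; the binary
  matrix is still what defines "known" for evaluation and ranking flags.
* `recovery_report` with the observed matrix as scores returns AUC 0.5
  exactly: masked positives and negatives are all zeros there, and the
  tie-aware statistic counts ties as half.

## Limitations

* The ALS updates are fixed-point, not guaranteed descent steps; for
  extreme λ_d/λ_t the trace can oscillate. The objective trace is exposed on
  the results object (`plot_objective`) for diagnosis.
* Computing miRNA functional similarity (MISIM) from annotation data is out
  of scope; it is consumed as an input matrix.
* No nonnegativity constraints are imposed, so scores can exceed [0,1];
  only their ranking is meaningful.
* The AUC negative set treats all unknown pairs as negatives, which
  understates performance to the extent that unknowns contain true
  associations.
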