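# npcmf — nearest-profile collaborative matrix factorization for miRNA–disease association prediction

Experimentally validating a miRNA–disease association (MDA) is slow and
expensive, so computational ranking of candidate associations is a standard
first step in miRNA research. `npcmf` implements **NPCMF**
(nearest-profile-based collaborative matrix factorization), a link-prediction
method for the bipartite miRNA–disease network, together with everything
needed to run and evaluate it: Gaussian interaction profile (GIP) kernels,
kernel fusion, disease semantic similarity from a MeSH-style hierarchy,
WKNKN pre-imputation, pair-holdout cross-validation, and a planted-structure
synthetic data generator so the whole pipeline is testable without any
external downloads.

## The model

Given a binary association matrix **Y** ∈ {0,1}^(n×m) (rows miRNAs, columns
diseases), NPCMF finds low-rank factors **A** (n×k) and **B** (m×k)
minimizing

```
‖Y − ABᵀ‖²_F + λ_l(‖A‖²_F + ‖B‖²_F) + λ_d‖N_m − AAᵀ‖²_F + λ_t‖N_d − BBᵀ‖²_F
```

where **N_m**, **N_d** are *nearest-profile* matrices: each side's fused
similarity kernel with the self-similarity removed and every row sparsified
to its single most similar neighbour. The fused kernels are
**K** = α·**S** + (1−α)·**GIP**, combining a supplied similarity (functional
similarity for miRNAs, hierarchy-derived semantic similarity for diseases)
with the GIP kernel `exp(−γ‖y_i − y_j‖²)` computed from association
profiles. Because a 0 in **Y** means "unknown" rather than "negative", WKNKN
(weighted K nearest known neighbours) pre-imputes likely-missing entries
before factorization. Factors are initialized from the truncated SVD of
**Y** and refined by alternating least-squares fixed-point updates; the
prediction score for every (miRNA, disease) pair is the corresponding entry
of **ABᵀ**.

Two ablation modes are built in: `semantic` (plain CMF — the supplied
similarities are the regularizer targets) and `fused` (the fused kernels are
the targets), selected via `HyperParams.regularizer_mode`.

## Worked example

```python
from npcmf import NPCMF, HyperParams, synthetic

data = synthetic.generate(synthetic.SyntheticSpec(seed=0))   # 100 x 80, rank-5 planted
model = NPCMF(data.observed, data.sim_mirna, data.sim_disease,
              params=HyperParams(k=10))
res = model.fit()
print(res.summary())
```

```
                NPCMF Factorization Results
============================================================
miRNAs (rows):                     100
diseases (cols):                    80
known associations:                720
rank k:                             10
regularizer mode:           nearest_profile
lambda_l / _d / _t:                  1 0.01 0.01
alpha (fusion):                    0.5
iterations run:                     16
converged:                        True
final objective:                160.71
relative residual:              0.2534
============================================================
```

720 of the 800 planted associations were observed (10% were masked); the
solver converged in 16 ALS iterations. Ranking miRNAs for one disease:

```python
print(res.rank_for_disease("disease_000", top_k=5).to_frame().to_string(index=False))
```

```
 rank     miRNA    score  known
    1 miRNA_043 1.035356   True
    2 miRNA_007 0.938140   True
    3 miRNA_097 0.926080   True
    4 miRNA_076 0.792752   True
    5 miRNA_006 0.771114   True
```

Known associations dominate the top ranks, as they should; rows flagged
`False` are novel predictions. Recovery of the 80 masked positives:

```python
print(synthetic.recovery_report(data.truth, data.observed, res.scores))
```

```
{'heldout_auc': 0.9931, 'mean_rank_masked': 2.96, 'n_masked': 80}
```

A masked true association is ranked on average within the top 3 candidate
miRNAs of its disease, and masked positives score above true negatives with
AUC 0.993.

## Command line

```bash
npcmf simulate --out-dir fixtures/            # write a synthetic dataset
npcmf fit --assoc Y.tsv --sim-mirna Sm.tsv --sim-disease Sd.tsv --out scores.tsv
npcmf cv  --assoc Y.tsv --sim-mirna Sm.tsv --sim-disease Sd.tsv --repeats 100 --seed 0
npcmf rank --assoc Y.tsv --scores scores.tsv --disease "Gastric Neoplasms" --top 10
npcmf similarity --assoc Y.tsv --side disease --dag dag.tsv --alpha 0.5 --out Kd.tsv
```

Associations are headerless two-column TSV edge lists (or labelled dense
TSV with `--assoc-format dense`); similarities are labelled dense TSV;
disease hierarchies are headerless `(child, parent)` TSV edge lists.

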