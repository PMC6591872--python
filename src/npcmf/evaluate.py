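"""Cross-validation, ROC/AUC and ranking evaluation for association
prediction.

The protocol is pair-holdout cross-validation (CV-p): the known (miRNA,
disease) pairs are partitioned into folds and each fold's entries are set to
0 in the training matrix, while every entity stays present.  Everything
downstream of the mask — GIP kernels, kernel fusion, WKNKN imputation,
nearest-profile matrices, the factorization itself — is recomputed from the
masked matrix, so held-out positives never leak into training.  Held-out
positives are then scored against all pairs that are 0 in the *full* matrix
(the unknowns, treated as negatives, the convention in this literature) and
summarized as per-fold ROC AUC, averaged per repeat.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .io import AssociationMatrix
from .model import HyperParams, build_regularizer_targets, fit_factors
from .preprocess import WknknParams, wknkn
from .similarity import KernelMatrix, fuse_kernels, gip_kernel

__all__ = [
    "ConfusionCounts",
    "CVResult",
    "RankedPrediction",
    "cvp_split",
    "auc",
    "run_cv",
    "grid_search",
    "sensitivity_sweep",
    "rank_for_disease",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion-table counts at one decision threshold."""

    TP: int
    FN: int
    TN: int
    FP: int

    @property
    def N(self) -> int:
        """Total negatives."""
        return self.TN + self.FP

    @property
    def sensitivity(self) -> float:
        return self.TP / (self.TP + self.FN)

    @property
    def specificity(self) -> float:
        return self.TN / self.N


@dataclass
class CVResult:
    """Aggregated CV-p outcome."""

    fold_assignments: dict[tuple[int, int], int]
    per_repeat_auc: list[float]
    per_fold_auc: list[list[float]]
    params: HyperParams
    wknkn_params: WknknParams | None

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.per_repeat_auc))

    @property
    def std_auc(self) -> float:
        if len(self.per_repeat_auc) < 2:
            return 0.0
        return float(np.std(self.per_repeat_auc, ddof=1))


@dataclass
class RankedPrediction:
    """Top-k ranked miRNAs for one disease, flagged known/novel."""

    disease_id: str
    rows: list[tuple[int, str, float, bool]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["rank", "miRNA", "score", "known"])


def cvp_split(Y: AssociationMatrix | np.ndarray, n_folds: int = 5, seed: int = 0) -> dict[tuple[int, int], int]:
    """Partition the known pairs into ``n_folds`` near-equal folds.

    Returns a map (row, col) -> fold in {1..n_folds}; fold sizes differ by
    at most one.  Deterministic for a given seed.
    """
    Yv = Y.values if isinstance(Y, AssociationMatrix) else np.asarray(Y)
    pairs = np.argwhere(Yv == 1)
    if len(pairs) < n_folds:
        raise ValueError(f"need at least {n_folds} known pairs, have {len(pairs)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    assignments: dict[tuple[int, int], int] = {}
    for fold, chunk in enumerate(np.array_split(order, n_folds), start=1):
        for idx in chunk:
            i, j = pairs[idx]
            assignments[(int(i), int(j))] = fold
    return assignments


def auc(scores, labels) -> float:
    """Area under the ROC curve.

    Equals the tie-aware rank statistic P(score+ > score-) + 0.5 P(equal).
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: only one class present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def _fit_masked(
    Y_train: np.ndarray,
    Sm: np.ndarray | None,
    Sd: np.ndarray | None,
    params: HyperParams,
    wknkn_params: WknknParams | None,
):
    """Full training pipeline on a masked matrix: kernels, WKNKN,
    regularizer targets, factorization.  Everything derives from Y_train."""
    Gm = gip_kernel(Y_train, "mirna", params.gamma)
    Gd = gip_kernel(Y_train, "disease", params.gamma)
    Km = Gm if Sm is None else fuse_kernels(KernelMatrix(Sm, "mirna", "functional"), Gm, params.alpha)
    Kd = Gd if Sd is None else fuse_kernels(KernelMatrix(Sd, "disease", "semantic"), Gd, params.alpha)
    Y_fit = Y_train if wknkn_params is None else wknkn(Y_train, Km, Kd, wknkn_params)
    Rm, Rd = build_regularizer_targets(Km, Kd, Sm, Sd, params.regularizer_mode)
    pair = fit_factors(Y_fit, Rm, Rd, params)
    return pair.scores


def run_cv(
    Y: AssociationMatrix | np.ndarray,
    Sm: np.ndarray | None = None,
    Sd: np.ndarray | None = None,
    params: HyperParams = HyperParams(),
    wknkn_params: WknknParams | None = WknknParams(),
    n_repeats: int = 1,
    n_folds: int = 5,
    seed: int = 0,
) -> CVResult:
    """Repeated n-fold CV-p with per-fold retraining from scratch.

    For each fold, the held-out positives are scored against all pairs that
    are 0 in the full matrix; per-repeat AUC is the mean over folds.
    """
    Yv = Y.values if isinstance(Y, AssociationMatrix) else np.asarray(Y, dtype=float)
    neg_mask = Yv == 0
    first_assignments: dict[tuple[int, int], int] = {}
    per_repeat: list[float] = []
    per_fold_all: list[list[float]] = []
    for r in range(n_repeats):
        assignments = cvp_split(Yv, n_folds=n_folds, seed=seed + r)
        if r == 0:
            first_assignments = assignments
        fold_aucs = []
        for fold in range(1, n_folds + 1):
            test_pairs = [p for p, f in assignments.items() if f == fold]
            Y_train = Yv.copy()
            for i, j in test_pairs:
                Y_train[i, j] = 0.0
            scores = _fit_masked(Y_train, Sm, Sd, params, wknkn_params)
            pos_scores = np.array([scores[i, j] for i, j in test_pairs])
            neg_scores = scores[neg_mask]
            all_scores = np.concatenate([pos_scores, neg_scores])
            labels = np.concatenate([np.ones(len(pos_scores)), np.zeros(len(neg_scores))])
            fold_aucs.append(auc(all_scores, labels))
        per_fold_all.append(fold_aucs)
        per_repeat.append(float(np.mean(fold_aucs)))
    return CVResult(
        fold_assignments=first_assignments,
        per_repeat_auc=per_repeat,
        per_fold_auc=per_fold_all,
        params=params,
        wknkn_params=wknkn_params,
    )


DEFAULT_LAMBDA_L_GRID = (2.0**-2, 2.0**-1, 2.0**0, 2.0**1)
DEFAULT_RATIO_GRID = (0.0, 1e-4, 1e-3, 1e-2, 1e-1)


def grid_search(
    Y,
    Sm=None,
    Sd=None,
    params: HyperParams = HyperParams(),
    wknkn_params: WknknParams | None = WknknParams(),
    lambda_l_grid=DEFAULT_LAMBDA_L_GRID,
    ratio_grid=DEFAULT_RATIO_GRID,
    n_repeats: int = 1,
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[HyperParams, pd.DataFrame]:
    """Exhaustive hyperparameter search by cross-validated AUC.

    lambda_d and lambda_t are parameterized as ratios to lambda_l, each
    swept over ``ratio_grid`` independently.  Ties resolve to the smallest
    (lambda_l, lambda_d ratio, lambda_t ratio) lexicographically.
    """
    lambda_l_grid = sorted(lambda_l_grid)
    ratio_grid = sorted(ratio_grid)
    if not lambda_l_grid or not ratio_grid:
        raise ValueError("empty hyperparameter grid")
    rows = []
    best: tuple[float, HyperParams] | None = None
    for ll in lambda_l_grid:
        for rd in ratio_grid:
            for rt in ratio_grid:
                cand = replace(params, lambda_l=ll, lambda_d=ll * rd, lambda_t=ll * rt)
                res = run_cv(Y, Sm, Sd, cand, wknkn_params, n_repeats, n_folds, seed)
                rows.append(
                    {
                        "lambda_l": ll,
                        "lambda_d_ratio": rd,
                        "lambda_t_ratio": rt,
                        "mean_auc": res.mean_auc,
                        "std_auc": res.std_auc,
                    }
                )
                if best is None or res.mean_auc > best[0]:
                    best = (res.mean_auc, cand)
    return best[1], pd.DataFrame(rows)


def sensitivity_sweep(
    parameter: str,
    values,
    Y,
    Sm=None,
    Sd=None,
    params: HyperParams = HyperParams(),
    wknkn_params: WknknParams = WknknParams(),
    n_repeats: int = 1,
    n_folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Sweep one of the WKNKN/fusion hyperparameters, all else fixed.

    ``parameter`` is ``"K"`` or ``"p"`` (WKNKN) or ``"alpha"`` (kernel
    fusion); returns a plot-ready table of value vs mean/std AUC.
    """
    Yv = Y.values if isinstance(Y, AssociationMatrix) else np.asarray(Y)
    n, m = Yv.shape
    rows = []
    for v in values:
        if parameter == "K":
            if not 1 <= v <= min(n, m) - 1:
                raise ValueError(f"K must lie in [1, {min(n, m) - 1}], got {v}")
            wp, pp = replace(wknkn_params, K=int(v)), params
        elif parameter == "p":
            if not 0 < v <= 1:
                raise ValueError(f"p must lie in (0, 1], got {v}")
            wp, pp = replace(wknkn_params, p=float(v)), params
        elif parameter == "alpha":
            if not 0 <= v <= 1:
                raise ValueError(f"alpha must lie in [0, 1], got {v}")
            wp, pp = wknkn_params, replace(params, alpha=float(v))
        else:
            raise ValueError(f"unknown sweep parameter {parameter!r}")
        res = run_cv(Y, Sm, Sd, pp, wp, n_repeats, n_folds, seed)
        rows.append({parameter: v, "mean_auc": res.mean_auc, "std_auc": res.std_auc})
    return pd.DataFrame(rows)


def rank_for_disease(
    Y: AssociationMatrix,
    scores: np.ndarray,
    disease_id: str,
    top_k: int = 10,
) -> RankedPrediction:
    """Rank miRNAs for one disease by descending score.

    Each row carries whether the pair is already known (Y=1) or a novel
    prediction; ties resolve to the smaller miRNA index.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    j = Y.index.disease_pos(str(disease_id))
    col = np.asarray(scores)[:, j]
    order = np.argsort(-col, kind="stable")[:top_k]
    rows = [
        (rank, Y.index.mirna_ids[i], float(col[i]), bool(Y.values[i, j] == 1))
        for rank, i in enumerate(order, start=1)
    ]
    return RankedPrediction(disease_id=str(disease_id), rows=rows)
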