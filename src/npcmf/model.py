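"""Nearest-profile collaborative matrix factorization (NPCMF).

The association matrix Y (miRNAs x diseases) is factorized as Y ~ A B^T with
low-rank factors A (n x k) and B (m x k), minimizing

    ||Y - A B^T||_F^2 + lambda_l (||A||_F^2 + ||B||_F^2)
      + lambda_d ||R_m - A A^T||_F^2 + lambda_t ||R_d - B B^T||_F^2

where the side regularizer targets R_m, R_d depend on the mode:

* ``nearest_profile`` (NPCMF, the default) — the one-nonzero-per-row NP
  matrices N_m, N_d extracted from the fused kernels;
* ``fused`` (GIP-CMF ablation) — the fused kernels K_m, K_d themselves;
* ``semantic`` (plain CMF ablation) — the supplied functional/semantic
  similarities S_m, S_d.

Factors are initialized from the truncated SVD of Y and refined by
alternating least-squares fixed-point updates:

    A <- (Y B + lambda_d R_m A) (B^T B + lambda_l I_k + lambda_d A^T A)^-1
    B <- (Y^T A + lambda_t R_d B) (A^T A + lambda_l I_k + lambda_t B^T B)^-1

with the freshly updated A entering the B step (Gauss-Seidel order).  These
updates are the stationarity conditions read as a fixed point, not exact
per-block minimizers, so the objective trace is monitored rather than
assumed monotone.

The user-facing surface follows the statsmodels convention: an
:class:`NPCMF` model is built from data, ``fit()`` returns an
:class:`NPCMFResults` carrying the factors, score matrix, objective trace
and diagnostics, and ranking/plotting hang off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import AssociationMatrix, DiseaseDAG, EntityIndex
from .preprocess import WknknParams, wknkn
from .similarity import (
    KernelMatrix,
    fuse_kernels,
    gip_kernel,
    nearest_profile_matrix,
    semantic_similarity,
)

__all__ = [
    "HyperParams",
    "FactorPair",
    "svd_init",
    "objective",
    "als_step",
    "fit_factors",
    "predict",
    "NPCMF",
    "NPCMFResults",
]

_MODES = ("semantic", "fused", "nearest_profile")


@dataclass(frozen=True)
class HyperParams:
    """Hyperparameters of the factorization.

    Parameters
    ----------
    k
        Factor rank.  ``None`` resolves to min(50, min(n, m)) at fit time.
    lambda_l
        Tikhonov weight on ||A||^2 + ||B||^2.
    lambda_d, lambda_t
        Weights on the miRNA-side and disease-side regularizer targets.
    alpha
        Fusion weight between supplied similarity and GIP kernel, in [0, 1].
    gamma
        GIP kernel bandwidth (used literally; default 1).
    regularizer_mode
        ``nearest_profile`` | ``fused`` | ``semantic`` (see module docs).
    max_iter, tol
        ALS stopping rule: stop when the relative objective change drops
        below ``tol`` or after ``max_iter`` updates.
    seed
        Recorded for provenance; the solver itself is deterministic.
    """

    k: int | None = None
    lambda_l: float = 1.0
    lambda_d: float = 0.01
    lambda_t: float = 0.01
    alpha: float = 0.5
    gamma: float = 1.0
    regularizer_mode: str = "nearest_profile"
    max_iter: int = 100
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        if self.k is not None and self.k < 1:
            raise ValueError("rank k must be a positive integer")
        for name in ("lambda_l", "lambda_d", "lambda_t"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.regularizer_mode not in _MODES:
            raise ValueError(f"regularizer_mode must be one of {_MODES}")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")

    def resolve_k(self, n: int, m: int) -> int:
        k = self.k if self.k is not None else min(50, n, m)
        if k > min(n, m):
            raise ValueError(f"rank k={k} exceeds min(n, m)={min(n, m)}")
        return k


@dataclass
class FactorPair:
    """Low-rank factors A (n x k), B (m x k) with fitting diagnostics."""

    A: np.ndarray
    B: np.ndarray
    iterations_run: int = 0
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = False

    @property
    def scores(self) -> np.ndarray:
        return self.A @ self.B.T


def svd_init(Y: np.ndarray, k: int) -> FactorPair:
    """Initialize factors from the rank-k truncated SVD of Y.

    A = U_k S_k^{1/2}, B = V_k S_k^{1/2}.  Sign convention: each left
    singular vector's largest-magnitude component is made positive (the
    matching right vector is flipped with it), so initialization is
    deterministic with no random seed.
    """
    Y = np.asarray(Y, dtype=float)
    n, m = Y.shape
    if k > min(n, m):
        raise ValueError(f"rank k={k} exceeds min(n, m)={min(n, m)}")
    U, s, Vt = np.linalg.svd(Y, full_matrices=False)
    U, s, Vt = U[:, :k], s[:k], Vt[:k, :]
    for l in range(k):
        pivot = np.argmax(np.abs(U[:, l]))
        if U[pivot, l] < 0:
            U[:, l] = -U[:, l]
            Vt[l, :] = -Vt[l, :]
    root = np.sqrt(s)
    return FactorPair(A=U * root, B=Vt.T * root)


def objective(
    Y: np.ndarray,
    A: np.ndarray,
    B: np.ndarray,
    Rm: np.ndarray,
    Rd: np.ndarray,
    params: HyperParams,
) -> float:
    """Regularized squared-error objective at (A, B)."""
    Y = np.asarray(Y, dtype=float)
    if Y.shape != (A.shape[0], B.shape[0]) or A.shape[1] != B.shape[1]:
        raise ValueError("factor shapes inconsistent with Y")
    if Rm.shape != (A.shape[0],) * 2 or Rd.shape != (B.shape[0],) * 2:
        raise ValueError("regularizer target shapes inconsistent with factors")
    val = np.linalg.norm(Y - A @ B.T, "fro") ** 2
    val += params.lambda_l * (np.linalg.norm(A, "fro") ** 2 + np.linalg.norm(B, "fro") ** 2)
    val += params.lambda_d * np.linalg.norm(Rm - A @ A.T, "fro") ** 2
    val += params.lambda_t * np.linalg.norm(Rd - B @ B.T, "fro") ** 2
    return float(val)


def _solve_right(numer: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Solve X M = numer for X, adding 1e-10 jitter once if M is singular."""
    try:
        return np.linalg.solve(M.T, numer.T).T
    except np.linalg.LinAlgError:
        M = M + 1e-10 * np.eye(M.shape[0])
        try:
            return np.linalg.solve(M.T, numer.T).T
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "ALS normal-equation matrix is singular even after jitter"
            ) from exc


def als_step(
    Y: np.ndarray,
    A: np.ndarray,
    B: np.ndarray,
    Rm: np.ndarray,
    Rd: np.ndarray,
    params: HyperParams,
) -> tuple[np.ndarray, np.ndarray]:
    """One alternating fixed-point update of (A, B).

    A is updated first from the current B; B is then updated from the *new*
    A.  The quadratic regularizer terms A^T A and B^T B inside each k x k
    system use the pre-update factor, per the fixed-point reading of the
    stationarity conditions.
    """
    k = A.shape[1]
    Ik = np.eye(k)
    A_new = _solve_right(Y @ B + params.lambda_d * Rm @ A, B.T @ B + params.lambda_l * Ik + params.lambda_d * A.T @ A)
    B_new = _solve_right(
        Y.T @ A_new + params.lambda_t * Rd @ B,
        A_new.T @ A_new + params.lambda_l * Ik + params.lambda_t * B.T @ B,
    )
    return A_new, B_new


def fit_factors(
    Y: np.ndarray,
    Rm: np.ndarray,
    Rd: np.ndarray,
    params: HyperParams,
) -> FactorPair:
    """SVD-initialize then iterate ALS updates to convergence.

    Stops when the relative objective change falls below ``params.tol`` or
    after ``params.max_iter`` updates; the trace records the objective after
    initialization and after every update.
    """
    Y = np.asarray(Y, dtype=float)
    k = params.resolve_k(*Y.shape)
    pair = svd_init(Y, k)
    A, B = pair.A, pair.B
    trace = [objective(Y, A, B, Rm, Rd, params)]
    converged = False
    for _ in range(params.max_iter):
        A, B = als_step(Y, A, B, Rm, Rd, params)
        trace.append(objective(Y, A, B, Rm, Rd, params))
        if abs(trace[-1] - trace[-2]) / max(trace[-2], 1e-12) < params.tol:
            converged = True
            break
    return FactorPair(A=A, B=B, iterations_run=len(trace) - 1, objective_trace=trace, converged=converged)


def predict(pair: FactorPair) -> np.ndarray:
    """Score matrix A B^T of a fitted pair."""
    return pair.scores


def build_regularizer_targets(
    Km: KernelMatrix,
    Kd: KernelMatrix,
    Sm: np.ndarray | None,
    Sd: np.ndarray | None,
    mode: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Resolve the side regularizer targets for the requested mode."""
    if mode == "nearest_profile":
        return (
            nearest_profile_matrix(Km).values,
            nearest_profile_matrix(Kd).values,
        )
    if mode == "fused":
        return Km.values, Kd.values
    if mode == "semantic":
        if Sm is None or Sd is None:
            raise ValueError("semantic mode requires supplied similarity matrices")
        return np.asarray(Sm, dtype=float), np.asarray(Sd, dtype=float)
    raise ValueError(f"unknown regularizer mode {mode!r}")


class NPCMF:
    """Nearest-profile collaborative matrix factorization model.

    Parameters
    ----------
    Y
        Binary association matrix (an :class:`AssociationMatrix` or a plain
        array, in which case positional identifiers are synthesized).
    sim_mirna
        miRNA functional similarity matrix (n x n), e.g. MISIM scores.
        Optional; without it the miRNA side uses the pure GIP kernel.
    sim_disease
        Disease semantic similarity matrix (m x m).  Optional; may instead
        be derived from ``dag``.
    dag
        Disease hierarchy from which semantic similarity is computed when
        ``sim_disease`` is not given.
    params
        :class:`HyperParams`; keyword overrides may also be passed to
        :meth:`fit`.
    wknkn_params
        WKNKN pre-imputation settings; ``None`` disables imputation.

    Examples
    --------
    >>> model = NPCMF(Y, sim_mirna=Sm, sim_disease=Sd)
    >>> res = model.fit()
    >>> res.scores_for_disease("Gastric Neoplasms").head()
    """

    def __init__(
        self,
        Y: AssociationMatrix | np.ndarray,
        sim_mirna: np.ndarray | None = None,
        sim_disease: np.ndarray | None = None,
        dag: DiseaseDAG | None = None,
        params: HyperParams = HyperParams(),
        wknkn_params: WknknParams | None = WknknParams(),
        delta: float = 0.5,
    ):
        if isinstance(Y, AssociationMatrix):
            self.Y = Y
        else:
            Y = np.asarray(Y, dtype=float)
            index = EntityIndex(
                tuple(f"miRNA_{i}" for i in range(Y.shape[0])),
                tuple(f"disease_{j}" for j in range(Y.shape[1])),
            )
            self.Y = AssociationMatrix(Y, index)
        n, m = self.Y.shape
        if sim_disease is None and dag is not None:
            sim_disease = semantic_similarity(dag, self.Y.index.disease_ids, delta).values
        self.sim_mirna = None if sim_mirna is None else np.asarray(sim_mirna, dtype=float)
        self.sim_disease = None if sim_disease is None else np.asarray(sim_disease, dtype=float)
        if self.sim_mirna is not None and self.sim_mirna.shape != (n, n):
            raise ValueError("sim_mirna shape inconsistent with Y")
        if self.sim_disease is not None and self.sim_disease.shape != (m, m):
            raise ValueError("sim_disease shape inconsistent with Y")
        self.params = params
        self.wknkn_params = wknkn_params

    @classmethod
    def from_files(
        cls,
        assoc_path,
        sim_mirna_path=None,
        sim_disease_path=None,
        dag_path=None,
        assoc_format: str = "edge_list",
        **kwargs,
    ) -> "NPCMF":
        """Build a model from the TSV formats of :mod:`npcmf.io`."""
        from . import io

        Y = io.read_associations(assoc_path, format=assoc_format)
        Sm = None if sim_mirna_path is None else io.read_similarity(sim_mirna_path, Y.index.mirna_ids)
        Sd = None if sim_disease_path is None else io.read_similarity(sim_disease_path, Y.index.disease_ids)
        dag = None if dag_path is None else io.read_dag(dag_path)
        return cls(Y, sim_mirna=Sm, sim_disease=Sd, dag=dag, **kwargs)

    def build_kernels(
        self, Y_train: np.ndarray | None = None, params: HyperParams | None = None
    ) -> tuple[KernelMatrix, KernelMatrix]:
        """Fused per-side kernels from (possibly masked) training data.

        The GIP kernels are always recomputed from the matrix actually used
        for training, so cross-validation masking propagates into them.
        """
        params = params or self.params
        Yv = self.Y.values if Y_train is None else np.asarray(Y_train, dtype=float)
        Gm = gip_kernel(Yv, "mirna", params.gamma)
        Gd = gip_kernel(Yv, "disease", params.gamma)
        if self.sim_mirna is not None:
            Km = fuse_kernels(KernelMatrix(self.sim_mirna, "mirna", "functional"), Gm, params.alpha)
        else:
            Km = Gm
        if self.sim_disease is not None:
            Kd = fuse_kernels(KernelMatrix(self.sim_disease, "disease", "semantic"), Gd, params.alpha)
        else:
            Kd = Gd
        return Km, Kd

    def fit(self, Y_train: np.ndarray | None = None, **overrides) -> "NPCMFResults":
        """Impute, build kernels and regularizer targets, and factorize.

        Parameters
        ----------
        Y_train
            Optional masked training matrix (for cross-validation); defaults
            to the full association matrix.
        **overrides
            :class:`HyperParams` field overrides for this fit.
        """
        params = replace(self.params, **overrides) if overrides else self.params
        Yv = self.Y.values if Y_train is None else np.asarray(Y_train, dtype=float)
        Km, Kd = self.build_kernels(Yv, params)
        Y_fit = Yv if self.wknkn_params is None else wknkn(Yv, Km, Kd, self.wknkn_params)
        Rm, Rd = build_regularizer_targets(Km, Kd, self.sim_mirna, self.sim_disease, params.regularizer_mode)
        pair = fit_factors(Y_fit, Rm, Rd, params)
        return NPCMFResults(self, pair, params, Y_train=Yv, Y_imputed=Y_fit)


class NPCMFResults:
    """Fitted NPCMF factors, scores and diagnostics."""

    def __init__(self, model: NPCMF, pair: FactorPair, params: HyperParams, Y_train, Y_imputed):
        self.model = model
        self.factors = pair
        self.params = params
        self.Y_train = Y_train
        self.Y_imputed = Y_imputed
        self.scores = pair.scores

    @property
    def index(self) -> EntityIndex:
        return self.model.Y.index

    @property
    def objective_trace(self) -> list[float]:
        return self.factors.objective_trace

    @property
    def final_objective(self) -> float:
        return self.factors.objective_trace[-1]

    def rank_for_disease(self, disease_id: str, top_k: int = 10):
        """Ranked miRNA predictions for one disease (see evaluate module)."""
        from .evaluate import rank_for_disease

        return rank_for_disease(self.model.Y, self.scores, disease_id, top_k)

    def scores_for_disease(self, disease_id: str):
        """All miRNA scores for one disease as a sorted pandas Series."""
        import pandas as pd

        j = self.index.disease_pos(str(disease_id))
        s = pd.Series(self.scores[:, j], index=list(self.index.mirna_ids), name=disease_id)
        return s.sort_values(ascending=False, kind="stable")

    def summary(self) -> str:
        """Plain-text fit summary in the statsmodels style."""
        n, m = self.model.Y.shape
        p = self.params
        rel_resid = np.linalg.norm(self.Y_imputed - self.scores, "fro") / max(
            np.linalg.norm(self.Y_imputed, "fro"), 1e-300
        )
        lines = [
            "                NPCMF Factorization Results",
            "=" * 60,
            f"{'miRNAs (rows):':<28}{n:>10}",
            f"{'diseases (cols):':<28}{m:>10}",
            f"{'known associations:':<28}{int(self.Y_train.sum()):>10}",
            f"{'rank k:':<28}{self.factors.A.shape[1]:>10}",
            f"{'regularizer mode:':<28}{p.regularizer_mode:>10}",
            f"{'lambda_l / _d / _t:':<28}{p.lambda_l:>10.4g} {p.lambda_d:.4g} {p.lambda_t:.4g}",
            f"{'alpha (fusion):':<28}{p.alpha:>10.4g}",
            f"{'iterations run:':<28}{self.factors.iterations_run:>10}",
            f"{'converged:':<28}{str(self.factors.converged):>10}",
            f"{'final objective:':<28}{self.final_objective:>10.6g}",
            f"{'relative residual:':<28}{rel_resid:>10.4g}",
            "=" * 60,
        ]
        return "\n".join(lines)

    def plot_objective(self, ax=None):
        """Objective value per ALS iteration (convergence diagnostic)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(range(len(self.objective_trace)), self.objective_trace, marker="o", ms=3)
        ax.set_xlabel("iteration")
        ax.set_ylabel("objective")
        ax.set_title("NPCMF convergence")
        return ax

    def save_scores(self, path) -> None:
        from .io import write_scores

        write_scores(self.scores, self.index, path)
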