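"""WKNKN pre-imputation of likely-missing associations.

A 0 in the association matrix means "unknown", not "known negative".  Before
factorization, each unknown entry is replaced by a decay-weighted average of
the profiles of the K most similar entities that *do* have known
associations, computed independently on the miRNA and disease sides and
averaged; known 1-entries are always preserved by an elementwise max.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import AssociationMatrix
from .similarity import KernelMatrix

logger = logging.getLogger(__name__)

__all__ = ["WknknParams", "wknkn"]


@dataclass(frozen=True)
class WknknParams:
    """WKNKN hyperparameters.

    K is the number of nearest known neighbours consulted; p in (0, 1] is
    the decay applied per neighbour rank, so the t-th nearest neighbour is
    weighted by ``p**(t-1)`` times its similarity.  Defaults K=5, p=0.7 are
    the values at which cross-validated AUC stabilizes.
    """

    K: int = 5
    p: float = 0.7

    def __post_init__(self):
        if self.K < 1:
            raise ValueError(f"K must be >= 1, got {self.K}")
        if not 0.0 < self.p <= 1.0:
            raise ValueError(f"p must lie in (0, 1], got {self.p}")


def _side_estimate(Y: np.ndarray, K_sim: np.ndarray, params: WknknParams) -> np.ndarray:
    """Row-wise neighbour estimate: each row of Y re-predicted from the K
    most similar *known* rows (rows with at least one association)."""
    n = Y.shape[0]
    known = np.flatnonzero(Y.sum(axis=1) > 0)
    est = np.zeros_like(Y, dtype=float)
    if known.size == 0:
        return est
    short = known.size < min(params.K, n - 1)
    if short:
        logger.info("only %d known neighbours available (K=%d); using all", known.size, params.K)
    for i in range(n):
        cand = known[known != i]
        if cand.size == 0:
            continue
        k = min(params.K, cand.size)
        sims = K_sim[i, cand]
        # stable sort keeps ties in ascending candidate-index order
        order = np.argsort(-sims, kind="stable")[:k]
        nbr = cand[order]
        w = params.p ** np.arange(k) * K_sim[i, nbr]
        denom = K_sim[i, nbr].sum()
        if denom <= 0:
            continue
        est[i] = w @ Y[nbr] / denom
    return est


def wknkn(
    Y: AssociationMatrix | np.ndarray,
    Km: KernelMatrix | np.ndarray,
    Kd: KernelMatrix | np.ndarray,
    params: WknknParams = WknknParams(),
) -> np.ndarray:
    """Impute unknown associations from weighted nearest known neighbours.

    Parameters
    ----------
    Y
        Binary association matrix (miRNAs x diseases).
    Km, Kd
        miRNA-side and disease-side similarity kernels (normally the fused
        kernels).
    params
        Neighbour count K and decay p.

    Returns
    -------
    ndarray
        Real-valued matrix in [0, 1]: elementwise max of Y with the average
        of the miRNA-side and disease-side neighbour estimates.
    """
    Yv = Y.values if isinstance(Y, AssociationMatrix) else np.asarray(Y, dtype=float)
    Kmv = Km.values if isinstance(Km, KernelMatrix) else np.asarray(Km, dtype=float)
    Kdv = Kd.values if isinstance(Kd, KernelMatrix) else np.asarray(Kd, dtype=float)
    if Kmv.shape != (Yv.shape[0],) * 2 or Kdv.shape != (Yv.shape[1],) * 2:
        raise ValueError("kernel shapes inconsistent with association matrix")
    Ym = _side_estimate(Yv, Kmv, params)
    Yd = _side_estimate(Yv.T, Kdv, params).T
    return np.maximum(Yv, (Ym + Yd) / 2.0)
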