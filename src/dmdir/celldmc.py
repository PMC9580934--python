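"""Interaction regression for cell-type-level differential methylation.

The CellDMC-style test regresses bulk methylation, per CpG, on cell-type
proportions and proportion-by-phenotype interaction terms:

    X_ij = sum_h W_ih * m_hj + sum_h (W_ih * y_i) * b_hj [+ covariates] + e_ij

The k interaction coefficients b_hj are the cell-type-level effect estimates;
each is tested with a two-sided t-test. No separate intercept is included:
rows of W sum to one, so its columns span the constant vector and an
intercept column would be structurally collinear. The model is committed to
the X|Y directionality — methylation is the dependent variable.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientSamplesError, ParameterError, SingularDesignError

__all__ = ["fit_interaction_model", "build_design", "association_frame"]

_RCOND = 1e-10


def build_design(W: np.ndarray, y: np.ndarray,
                 covariates: Optional[np.ndarray] = None,
                 celltype_ids: Optional[Sequence[str]] = None):
    """Assemble [W | W*y | covariates] and its column names."""
    W = np.asarray(W, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, k = W.shape
    if y.size != n:
        raise ParameterError(f"y has length {y.size}, expected {n}")
    if celltype_ids is None:
        celltype_ids = [f"ct{h + 1}" for h in range(k)]
    blocks = [W, W * y[:, None]]
    names = list(celltype_ids) + [f"{c}:y" for c in celltype_ids]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[0] != n:
            raise ParameterError("covariates row count does not match samples")
        blocks.append(C)
        names += [f"cov{p + 1}" for p in range(C.shape[1])]
    return np.column_stack(blocks), names


def _check_rank(D: np.ndarray, names):
    """Raise SingularDesignError naming collapsed columns if D is deficient."""
    _, R = np.linalg.qr(D)
    diag = np.abs(np.diag(R))
    tol = D.shape[1] * np.finfo(float).eps * max(diag.max(), 1.0)
    bad = diag < max(tol, _RCOND * diag.max())
    if bad.any():
        raise SingularDesignError([names[i] for i in np.nonzero(bad)[0]])


def association_frame(cpg_ids, celltype_ids, estimate, std_error, statistic,
                      p_value) -> pd.DataFrame:
    """Long-format association table: one row per (CpG, cell type).

    ``estimate`` .. ``p_value`` are (m, k) arrays; rows are emitted CpG-major.
    """
    m, k = np.asarray(estimate).shape
    return pd.DataFrame({
        "cpg": np.repeat(list(cpg_ids), k),
        "cell_type": np.tile(list(celltype_ids), m),
        "estimate": np.asarray(estimate).ravel(),
        "std_error": np.asarray(std_error).ravel(),
        "statistic": np.asarray(statistic).ravel(),
        "p_value": np.asarray(p_value).ravel(),
    })


def fit_interaction_model(X: np.ndarray, W: np.ndarray, y: np.ndarray,
                          covariates: Optional[np.ndarray] = None,
                          cpg_ids: Optional[Sequence[str]] = None,
                          celltype_ids: Optional[Sequence[str]] = None,
                          ) -> pd.DataFrame:
    """OLS interaction test per CpG; returns an m x k association table.

    Parameters
    ----------
    X : (n, m) bulk methylation, samples in rows.
    W : (n, k) cell-type proportions, rows on the simplex.
    y : (n,) phenotype (binary or continuous).
    covariates : optional (n, p), enter additively.

    Returns
    -------
    DataFrame with columns ``cpg, cell_type, estimate, std_error, statistic,
    p_value`` — t-tests on the k interaction coefficients with
    n - (2k + p) residual degrees of freedom.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    k = W.shape[1]
    D, names = build_design(W, y, covariates, celltype_ids)
    q = D.shape[1]
    if n <= q:
        raise InsufficientSamplesError(
            f"need more than {q} samples for {q} parameters, got {n}")
    _check_rank(D, names)
    G = D.T @ D
    Ginv = np.linalg.inv(G)
    coef = Ginv @ (D.T @ X)  # (q, m)
    resid = X - D @ coef
    dof = n - q
    s2 = np.einsum("ij,ij->j", resid, resid) / dof
    se_all = np.sqrt(np.outer(np.diag(Ginv), s2))  # (q, m)
    inter = slice(k, 2 * k)
    est = coef[inter].T  # (m, k)
    se = se_all[inter].T
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, est / se, 0.0)
    pval = 2.0 * stats.t.sf(np.abs(tstat), dof)
    if cpg_ids is None:
        cpg_ids = [f"cpg{j:05d}" for j in range(m)]
    if celltype_ids is None:
        celltype_ids = [f"ct{h + 1}" for h in range(k)]
    return association_frame(cpg_ids, celltype_ids, est, se, tstat, pval)
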