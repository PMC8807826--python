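"""Pre-modeling transformations.

Rank-based inverse-normal transform (to satisfy the normality assumption
of the linear mixed models), surrogate-variable estimation by principal
components of the covariate-residualized matrix, and ordinary
least-squares residualization of features on known covariates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

#: Supported rank offsets for the inverse-normal transform.
INT_OFFSETS = (0.0, 3.0 / 8.0, 0.5)


def inverse_normal_transform(values, c: float = 3.0 / 8.0):
    """Blom-style rank-based inverse-normal transform.

    Maps values to Phi^-1((rank - c) / (n - 2c + 1)) using average ranks
    for ties; missing values pass through as missing.
    """
    arr = np.asarray(values, dtype=float)
    finite = np.isfinite(arr)
    x = arr[finite]
    if x.size < 2:
        raise ValueError("need at least 2 finite values")
    if np.ptp(x) == 0.0:
        raise ValueError("transform undefined: all values identical")
    ranks = rankdata(x, method="average")
    out = np.full(arr.shape, np.nan)
    out[finite] = norm.ppf((ranks - c) / (x.size - 2.0 * c + 1.0))
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


def int_matrix(matrix: pd.DataFrame, c: float = 3.0 / 8.0,
               min_complete: float = 0.8) -> pd.DataFrame:
    """Row-wise INT of a feature x sample matrix.

    Features with fewer than ``min_complete`` complete samples, or with
    zero variance, are dropped (their count is reported via the returned
    frame's ``attrs['n_dropped']``).
    """
    vals = matrix.to_numpy(dtype=float)
    n = matrix.shape[1]
    finite = np.isfinite(vals)
    keep = (finite.sum(axis=1) >= min_complete * n) & (
        np.nanmax(vals, axis=1) > np.nanmin(vals, axis=1)
    )
    complete = keep & finite.all(axis=1)
    out_vals = np.full(vals.shape, np.nan)
    if complete.any():  # fast path: vectorized ranks for complete rows
        ranks = rankdata(vals[complete], method="average", axis=1)
        out_vals[complete] = norm.ppf((ranks - c) / (n - 2.0 * c + 1.0))
    for i in np.nonzero(keep & ~complete)[0]:
        out_vals[i] = inverse_normal_transform(vals[i], c=c)
    out = pd.DataFrame(out_vals[keep], index=matrix.index[keep],
                       columns=matrix.columns)
    out.index.name = "probe_id"
    out.attrs["n_dropped"] = int(matrix.shape[0] - keep.sum())
    out.attrs["provenance"] = "INT"
    return out


def _design_with_intercept(covariates) -> np.ndarray:
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.size == 0:
        C = np.empty((len(covariates), 0))
    ones = np.ones((C.shape[0], 1))
    # drop a covariate column that is itself constant-1 duplicate
    return np.column_stack([ones, C])


def residualize(matrix: pd.DataFrame, covariates) -> pd.DataFrame:
    """OLS residuals of every feature on covariates + intercept."""
    C = _design_with_intercept(covariates)
    n = C.shape[0]
    if matrix.shape[1] != n:
        raise ValueError("covariate rows must match samples")
    if n <= C.shape[1]:
        raise ValueError("need more samples than covariates + intercept")
    rank = np.linalg.matrix_rank(C)
    if rank < C.shape[1]:
        # identify offending columns for the error message
        bad = []
        for j in range(1, C.shape[1]):
            sub = np.delete(C, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(j - 1)
        raise ValueError(f"rank-deficient covariates (collinear columns: {bad})")
    Y = matrix.to_numpy(dtype=float).T  # samples x features
    coef, *_ = np.linalg.lstsq(C, Y, rcond=None)
    R = Y - C @ coef
    out = pd.DataFrame(R.T, index=matrix.index, columns=matrix.columns)
    out.attrs["provenance"] = "residualized"
    return out


def estimate_surrogate_variables(
    matrix: pd.DataFrame,
    known_covariates,
    k: int | None = None,
    n_permutations: int = 19,
    seed: int = 0,
) -> pd.DataFrame:
    """Surrogate variables as principal components of the residual matrix.

    Known covariates (plus an intercept) are regressed out of every
    feature; the top-k right singular vectors of the residual matrix in
    sample space are returned as surrogate-variable scores.  They are
    orthogonal to the known-covariate column space by construction.

    When ``k`` is None it is chosen by permutation-based parallel
    analysis: components whose singular value exceeds the 95th percentile
    of singular values from row-permuted residual matrices are kept.
    """
    C = _design_with_intercept(known_covariates)
    n = C.shape[0]
    max_k = n - np.linalg.matrix_rank(C)
    if k is not None and k <= 0:
        return pd.DataFrame(index=matrix.columns)
    if k is not None and k >= max_k:
        raise ValueError(f"k must be < n_samples - rank(covariates) = {max_k}")
    R = residualize(matrix, known_covariates).to_numpy(dtype=float)  # features x samples
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    if k is None:
        rng = np.random.default_rng(seed)
        null_top = np.empty((n_permutations, len(s)))
        for b in range(n_permutations):
            Rp = np.array([rng.permutation(row) for row in R])
            Rp = residualize(
                pd.DataFrame(Rp, columns=matrix.columns), known_covariates
            ).to_numpy()
            null_top[b] = np.linalg.svd(Rp, compute_uv=False)[: len(s)]
        thresh = np.quantile(null_top, 0.95, axis=0)
        k = int(np.sum(s > thresh))
        if k == 0:
            return pd.DataFrame(index=matrix.columns)
    scores = Vt[:k].T * s[:k]
    return pd.DataFrame(
        scores, index=matrix.columns, columns=[f"SV{i + 1}" for i in range(k)]
    )
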