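"""Reference-based leukocyte deconvolution (Houseman-style projection).

Each sample's beta vector is projected onto the cell-type reference
profiles by non-negative least squares; the resulting weights are
renormalized to sum to one.  The granulocyte-to-lymphocyte ratio (GLR)
is derived from the estimated fractions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .io import LYMPHOCYTES


def estimate_proportions(beta_column: pd.Series, profiles: pd.DataFrame):
    """Estimate one sample's cell-type fractions.

    Solves min ||beta - P w||^2 subject to w >= 0, then renormalizes the
    weights to sum to one.  Returns ``(weights, residual_norm)`` where the
    residual norm (of the constrained fit, before renormalization) serves
    as a per-sample fit diagnostic.
    """
    shared = profiles.index.intersection(beta_column.index)
    k = profiles.shape[1]
    if len(shared) < k:
        raise ValueError(
            f"only {len(shared)} shared CpGs for {k} cell types; need at least {k}"
        )
    P = profiles.loc[shared].to_numpy(dtype=float)
    if np.allclose(P.std(axis=1), 0.0):
        raise ValueError("singular design: all profile rows are constant across cell types")
    y = beta_column.loc[shared].to_numpy(dtype=float)
    w, rnorm = nnls(P, y)
    total = w.sum()
    if total <= 0:
        raise ValueError("non-negative fit collapsed to zero weights")
    w = w / total
    return pd.Series(w, index=profiles.columns), float(rnorm)


def deconvolve(beta: pd.DataFrame, profiles: pd.DataFrame) -> pd.DataFrame:
    """Estimate proportions for every sample (columns of ``beta``).

    Returns a sample x cell-type DataFrame with a ``residual_norm``
    diagnostic column appended.
    """
    rows, rnorms = [], []
    for sample in beta.columns:
        w, rn = estimate_proportions(beta[sample], profiles)
        rows.append(w)
        rnorms.append(rn)
    out = pd.DataFrame(rows, index=pd.Index(beta.columns, name="sample_id"))
    out["residual_norm"] = rnorms
    return out


def compute_glr(proportions) -> float | pd.Series:
    """Granulocyte-to-lymphocyte ratio: Gran / (CD4T + CD8T + NK + B).

    Monocytes are excluded from the denominator.  A zero lymphocyte sum
    yields a missing value (NaN) rather than an exception.
    """
    if isinstance(proportions, pd.DataFrame):
        lymph = proportions[list(LYMPHOCYTES)].sum(axis=1)
        glr = proportions["Gran"] / lymph.where(lymph > 0)
        return glr.rename("glr")
    lymph = float(sum(proportions[ct] for ct in LYMPHOCYTES))
    if lymph <= 0:
        return float("nan")
    return float(proportions["Gran"]) / lymph


def grid_search_proportions(beta_column, profiles, coarse=0.05, fine=0.01):
    """Brute-force simplex grid oracle for the constrained projection.

    Enumerates compositions on a coarse simplex grid, then exhaustively
    refines on the fine grid inside a +/- coarse neighborhood of the
    coarse optimum.  Intended for validation only (small k).
    """
    shared = profiles.index.intersection(beta_column.index)
    P = profiles.loc[shared].to_numpy(dtype=float)
    y = beta_column.loc[shared].to_numpy(dtype=float)
    k = P.shape[1]

    def _rss_argmin(W):
        resid = P @ W.T - y[:, None]
        return W[np.argmin(np.einsum("ij,ij->j", resid, resid))]

    def _compositions(total, k, step_count):
        # integer compositions of `total` into k parts, each 0..total
        out = []
        comp = np.zeros(k, dtype=int)

        def rec(pos, remaining):
            if pos == k - 1:
                comp[pos] = remaining
                out.append(comp.copy())
                return
            for v in range(remaining + 1):
                comp[pos] = v
                rec(pos + 1, remaining - v)

        rec(0, total)
        return np.array(out)

    n_coarse = int(round(1.0 / coarse))
    W = _compositions(n_coarse, k, n_coarse) * coarse
    best = _rss_argmin(W)

    # fine local refinement around the coarse optimum
    n_fine = int(round(1.0 / fine))
    center = np.round(best * n_fine).astype(int)
    radius = int(round(coarse / fine))
    ranges = [
        np.arange(max(0, c - radius), min(n_fine, c + radius) + 1) for c in center
    ]
    grids = np.meshgrid(*ranges[:-1], indexing="ij")
    cand = np.stack([g.ravel() for g in grids], axis=1)
    last = n_fine - cand.sum(axis=1)
    ok = (last >= ranges[-1][0]) & (last <= ranges[-1][-1])
    cand = np.column_stack([cand[ok], last[ok]])
    if len(cand) == 0:
        return pd.Series(best, index=profiles.columns)
    Wf = cand * fine
    bestf = _rss_argmin(Wf)
    return pd.Series(bestf, index=profiles.columns)
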