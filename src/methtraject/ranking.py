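"""Dual statistical + biological ranking and the paired first-vs-last screen.

The statistical ranking orders features by their time-effect p-value; the
biological ranking orders them by the maximum absolute difference between
timepoint mean methylations on the raw beta scale.  Their sum gives the
combined ranking from which the top-k candidates are selected.  The
paired screen tests first-vs-last persistence with paired t tests and
Benjamini-Hochberg FDR correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def benjamini_hochberg(p_values) -> np.ndarray | pd.Series:
    """Step-up BH q-values with monotonicity enforcement.

    Missing p-values yield missing q-values and are not counted in the
    family size m.
    """
    p = np.asarray(p_values, dtype=float)
    finite = np.isfinite(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    pf = p[finite]
    m = pf.size
    if m:
        order = np.argsort(pf, kind="stable")
        ranked = pf[order] * m / np.arange(1, m + 1)
        qf = np.minimum.accumulate(ranked[::-1])[::-1]
        qvals = np.empty(m)
        qvals[order] = np.minimum(qf, 1.0)
        q[finite] = qvals
    if isinstance(p_values, pd.Series):
        return pd.Series(q, index=p_values.index, name="q")
    return q


def biological_difference(beta_row: pd.Series, phenotypes: pd.DataFrame,
                          phase: str) -> float:
    """Maximum absolute difference between timepoint mean betas (raw scale)."""
    pheno = phenotypes[phenotypes["phase"] == phase]
    vals = beta_row.reindex(pheno["sample_id"]).to_numpy(dtype=float)
    means = []
    for tp in pheno["timepoint"].unique():
        sel = (pheno["timepoint"] == tp).to_numpy()
        v = vals[sel]
        v = v[np.isfinite(v)]
        if v.size == 0:
            continue  # timepoint without samples is excluded
        means.append(v.mean())
    if len(means) < 2:
        raise ValueError("need >= 2 timepoints with samples")
    means = np.asarray(means)
    return float(np.max(means) - np.min(means))


def biological_difference_matrix(beta: pd.DataFrame, phenotypes: pd.DataFrame,
                                 phase: str) -> pd.Series:
    """Vectorized :func:`biological_difference` over all features."""
    pheno = phenotypes[phenotypes["phase"] == phase]
    sub = beta[pheno["sample_id"]]
    groups = pheno["timepoint"].to_numpy()
    means = sub.T.groupby(groups).mean().T
    return (means.max(axis=1) - means.min(axis=1)).rename("bio_diff")


def dual_rank(p_values: pd.Series, bio_diffs: pd.Series, k: int = 100) -> pd.DataFrame:
    """Combine statistical and biological rankings into the sum ranking.

    Ranks ascend on p (smaller is better) and descend on bio_diff (larger
    is better), with average ranks at ties; sum-rank ties are broken by
    stat_rank, then feature id.  Returns the full table ordered by the
    combined ranking with a ``top_k`` boolean column marking the top-k.
    """
    common = p_values.index.intersection(bio_diffs.index)
    p = p_values.loc[common]
    b = bio_diffs.loc[common]
    keep = p.notna() & b.notna()
    n_excluded = int((~keep).sum()) + (len(p_values) - len(common)) + (
        len(bio_diffs) - len(common)
    )
    p, b = p[keep], b[keep]
    tab = pd.DataFrame({"p_time": p, "bio_diff": b})
    tab["stat_rank"] = p.rank(method="average")
    tab["bio_rank"] = (-b).rank(method="average")
    tab["sum_rank"] = tab["stat_rank"] + tab["bio_rank"]
    tab.index.name = "feature"
    tab = tab.reset_index()
    tab = tab.sort_values(["sum_rank", "stat_rank", "feature"], kind="stable")
    tab = tab.set_index("feature")
    tab["overall_order"] = np.arange(1, len(tab) + 1)
    tab["top_k"] = tab["overall_order"] <= k
    tab.attrs["n_excluded"] = n_excluded
    return tab


def paired_delta_screen(values: pd.DataFrame, phenotypes: pd.DataFrame,
                        phase: str) -> pd.DataFrame:
    """Paired t tests of last-vs-first timepoint within subjects.

    ``values`` should be residualized (covariates cannot enter a paired
    test).  Features whose within-subject differences have zero variance
    are flagged with missing statistics and excluded from the FDR family.
    """
    pheno = phenotypes[phenotypes["phase"] == phase]
    tps = list(pheno["timepoint"].unique())
    first, last = tps[0], tps[-1]
    a = pheno[pheno["timepoint"] == first].set_index("subject_id")["sample_id"]
    b = pheno[pheno["timepoint"] == last].set_index("subject_id")["sample_id"]
    subjects = a.index.intersection(b.index)
    if len(subjects) < 3:
        raise ValueError("need >= 3 subjects with both first and last timepoints")
    X_first = values[a.loc[subjects]].to_numpy(dtype=float)
    X_last = values[b.loc[subjects]].to_numpy(dtype=float)
    diffs = X_last - X_first
    nvalid = np.isfinite(diffs).sum(axis=1)
    mean = np.nanmean(diffs, axis=1)
    sd = np.nanstd(diffs, axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(nvalid))
    df = nvalid - 1
    bad = (sd == 0) | (nvalid < 3) | ~np.isfinite(t)
    t[bad] = np.nan
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[bad] = np.nan
    out = pd.DataFrame(
        {"t": t, "df": df.astype(float), "p": p}, index=values.index
    )
    out["q"] = benjamini_hochberg(out["p"])
    return out


def candidate_subset(rank_table: pd.DataFrame, gene_list, manifest: pd.DataFrame,
                     k: int = 100) -> pd.DataFrame:
    """Recompute the ranking restricted to CpGs annotated to given genes."""
    genes = set(gene_list)
    ann = manifest.loc[manifest.index.intersection(rank_table.index)]
    members = ann.index[ann["gene"].isin(genes)]
    if len(members) == 0:
        matched = set(ann["gene"]) & genes
        raise ValueError(
            f"no CpGs matched the gene list (unmatched genes: {sorted(genes - matched)[:10]})"
        )
    sub = rank_table.loc[members]
    out = dual_rank(sub["p_time"], sub["bio_diff"], k=k)
    out["gene"] = manifest.loc[out.index, "gene"]
    return out
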