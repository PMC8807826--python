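"""Candidate linear-mixed-model fitting, selection and time-effect testing.

Four candidate models are fit per feature by maximum likelihood:

    M1: fixed linear time,            random subject intercept
    M2: fixed linear + quadratic time, random subject intercept
    M3: M1 + independent random time slope
    M4: M2 + independent random time slope

all sharing the same covariates (age, sex, cigarettes/day, cell-type
proportions, surrogate variables as supplied by the caller).  Nested
pairs are compared by likelihood-ratio tests — quadratic over linear
with chi2(1); random slope over intercept-only with the boundary
0.5*chi2(0) + 0.5*chi2(1) mixture — and remaining non-nested candidates
by minimum AIC.  The time-effect p-value is the LRT of the selected
model against the same model with every time fixed-effect removed.

Time is coded as the ordinal within-phase index centered at mid-phase;
the quadratic term is the squared centered index.  Exposure and therapy
phases are always analyzed separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .deconv import compute_glr
from .io import CELL_TYPES
from .lmm import LmmFit, RepeatedMeasuresDesign
from .ranking import benjamini_hochberg

MODEL_NAMES = ("M1", "M2", "M3", "M4")
_MODEL_SPECS = {
    "M1": {"quadratic": False, "random_slope": False},
    "M2": {"quadratic": True, "random_slope": False},
    "M3": {"quadratic": False, "random_slope": True},
    "M4": {"quadratic": True, "random_slope": True},
}


@dataclass
class ModelSelection:
    selected: str
    lrt_pvalues: dict
    reason: str


@dataclass
class TrajectoryFitRecord:
    feature: str
    phase: str
    selected_model: str
    p_time: float
    beta_time: float
    beta_time2: float
    loglik: dict
    aic: dict
    converged: dict
    p_time_method: str = "lrt"


def time_codes(phenotypes: pd.DataFrame, phase: str,
               coding: str = "centered") -> tuple[pd.DataFrame, np.ndarray]:
    """Numeric time per sample of the phase.

    ``centered`` (default): ordinal index centered at mid-phase, quadratic
    term = squared centered index.  ``raw``: uncentered ordinal index.
    """
    pheno = phenotypes[phenotypes["phase"] == phase].copy()
    if pheno.empty:
        raise ValueError(f"no samples in phase {phase!r}")
    tps = list(dict.fromkeys(pheno["timepoint"]))
    idx = pheno["timepoint"].map({tp: i for i, tp in enumerate(tps)}).to_numpy(float)
    if coding == "centered":
        t = idx - idx.mean()
    elif coding == "raw":
        t = idx
    else:
        raise ValueError(f"unknown time coding {coding!r}")
    return pheno, t


def build_design(phenotypes: pd.DataFrame, phase: str, covariates=None,
                 coding: str = "centered") -> RepeatedMeasuresDesign:
    """Assemble the shared fixed-effect design for one phase.

    ``covariates`` is an optional sample-indexed DataFrame (cell-type
    proportions, surrogate variables, ...) appended to the built-in
    age / sex / cigarettes terms.
    """
    pheno, t = time_codes(phenotypes, phase, coding=coding)
    cols = {
        "Intercept": np.ones(len(pheno)),
        "time": t,
        "time2": t**2,
        "age": pheno["age"].to_numpy(float),
        "sex": (pheno["sex"] == "M").to_numpy(float),
        "cigarettes": pheno["cigarettes_per_day"].to_numpy(float),
    }
    if covariates is not None:
        cov = covariates.reindex(pheno["sample_id"])
        if cov.isna().any().any():
            raise ValueError("covariates missing for some phase samples")
        for name in cov.columns:
            cols[name] = cov[name].to_numpy(float)
    X = np.column_stack(list(cols.values()))
    design = RepeatedMeasuresDesign(
        X, pheno["subject_id"].to_numpy(), t, columns=tuple(cols)
    )
    design.sample_ids = list(pheno["sample_id"])
    return design


def _model_cols(design: RepeatedMeasuresDesign, quadratic: bool,
                with_time: bool = True) -> tuple[str, ...]:
    cols = list(design.columns)
    if not quadratic:
        cols.remove("time2")
    if not with_time:
        cols = [c for c in cols if c not in ("time", "time2")]
    return tuple(cols)


def fit_candidate_lmms(values, design: RepeatedMeasuresDesign) -> dict[str, LmmFit]:
    """ML fits of all four candidates; non-converged fits are kept but flagged.

    The random-slope searches are seeded with the intercept variance ratio
    of the matching intercept-only fit.
    """
    y = np.asarray(values, dtype=float)
    fits = {}
    seeds = {"M3": "M1", "M4": "M2"}
    for name, spec in _MODEL_SPECS.items():
        cols = _model_cols(design, spec["quadratic"])
        init = None
        parent = fits.get(seeds.get(name))
        if parent is not None and parent.converged:
            init = parent.gamma_intercept
        try:
            fits[name] = design.fit(y, cols=cols, random_slope=spec["random_slope"],
                                    gamma0_init=init)
        except np.linalg.LinAlgError:
            continue
    if not fits:
        raise ValueError("no candidate model could be fitted")
    return fits


def _lrt_p(ll_full: float, ll_reduced: float, df: int) -> float:
    stat = max(2.0 * (ll_full - ll_reduced), 0.0)
    return float(chi2.sf(stat, df)) if df > 0 else 1.0


def _boundary_lrt_p(ll_full: float, ll_reduced: float) -> float:
    """0.5*chi2(0) + 0.5*chi2(1) mixture for a variance on the boundary."""
    stat = max(2.0 * (ll_full - ll_reduced), 0.0)
    if stat <= 0.0:
        return 1.0
    return float(0.5 * chi2.sf(stat, 1))


def select_best_model(fits: dict[str, LmmFit], alpha_lrt: float = 0.05) -> ModelSelection:
    """LRT on nested pairs, minimum AIC for non-nested survivors."""
    conv = {k: f for k, f in fits.items() if f.converged}
    if not conv:
        raise ValueError("no converged candidate model")
    lrt_ps: dict[str, float] = {}

    def pick_quadratic(lin: str, quad: str) -> str | None:
        if lin in conv and quad in conv:
            p = _lrt_p(conv[quad].loglik, conv[lin].loglik, 1)
            lrt_ps[f"{quad}_vs_{lin}"] = p
            return quad if p < alpha_lrt else lin
        if lin in conv:
            return lin
        if quad in conv:
            return quad
        return None

    a = pick_quadratic("M1", "M2")  # random-intercept family
    b = pick_quadratic("M3", "M4")  # random-slope family
    if a is not None and b is not None:
        if _MODEL_SPECS[a]["quadratic"] == _MODEL_SPECS[b]["quadratic"]:
            p = _boundary_lrt_p(conv[b].loglik, conv[a].loglik)
            lrt_ps[f"{b}_vs_{a}"] = p
            sel, reason = (b, "boundary-lrt") if p < alpha_lrt else (a, "boundary-lrt")
        else:
            sel = a if conv[a].aic <= conv[b].aic else b
            reason = "aic"
    else:
        sel = a if a is not None else b
        reason = "fallback"
    return ModelSelection(selected=sel, lrt_pvalues=lrt_ps, reason=reason)


def time_effect_pvalue(values, design: RepeatedMeasuresDesign,
                       selection: ModelSelection,
                       fits: dict[str, LmmFit]) -> tuple[float, str]:
    """LRT of the selected model against it with all time terms removed.

    Falls back to a Wald test on the time coefficients if the reduced
    model cannot be fitted; the second return value names the method.
    """
    spec = _MODEL_SPECS[selection.selected]
    full = fits[selection.selected]
    df = 2 if spec["quadratic"] else 1
    cols = _model_cols(design, spec["quadratic"], with_time=False)
    try:
        reduced = design.fit(np.asarray(values, float), cols=cols,
                             random_slope=spec["random_slope"])
        if not reduced.converged:
            raise np.linalg.LinAlgError("reduced model did not converge")
        return _lrt_p(full.loglik, reduced.loglik, df), "lrt"
    except (np.linalg.LinAlgError, ValueError):
        wald = full.coef_p("time")
        if spec["quadratic"]:
            # combine the two 1-df Wald chi-squares
            z1 = full.coef("time") / full.bse[full.columns.index("time")]
            z2 = full.coef("time2") / full.bse[full.columns.index("time2")]
            return float(chi2.sf(z1**2 + z2**2, 2)), "wald"
        return wald, "wald"


def analyze_feature(values, design: RepeatedMeasuresDesign, feature: str = "",
                    phase: str = "", alpha_lrt: float = 0.05) -> TrajectoryFitRecord:
    """Full per-feature analysis: fit, select, test."""
    fits = fit_candidate_lmms(values, design)
    sel = select_best_model(fits, alpha_lrt=alpha_lrt)
    p, method = time_effect_pvalue(values, design, sel, fits)
    best = fits[sel.selected]
    b_t = best.coef("time")
    b_t2 = best.coef("time2") if "time2" in best.columns else np.nan
    return TrajectoryFitRecord(
        feature=feature,
        phase=phase,
        selected_model=sel.selected,
        p_time=max(p, np.finfo(float).tiny),
        beta_time=b_t,
        beta_time2=b_t2,
        loglik={k: f.loglik for k, f in fits.items()},
        aic={k: f.aic for k, f in fits.items()},
        converged={k: f.converged for k, f in fits.items()},
        p_time_method=method,
    )


def fit_feature_table(matrix: pd.DataFrame, phenotypes: pd.DataFrame, phase: str,
                      covariates=None, alpha_lrt: float = 0.05,
                      coding: str = "centered") -> pd.DataFrame:
    """Per-feature trajectory scan over a feature x sample matrix.

    Besides the selected-model time-effect test, the table carries the
    uncorrected time-effect p-values of the two fixed-structure
    random-intercept models (``p_linear_ri`` for M1, ``p_quadratic_ri``
    for M2), which feed the spatial DMR caller: one fixed model per
    phase keeps the p-value track's spatial correlation interpretable.
    """
    design = build_design(phenotypes, phase, covariates=covariates, coding=coding)
    sub = matrix[design.sample_ids]
    rows, skipped = [], []
    for pid, row in sub.iterrows():
        y = row.to_numpy(float)
        try:
            fits = fit_candidate_lmms(y, design)
            sel = select_best_model(fits, alpha_lrt=alpha_lrt)
        except ValueError as exc:
            skipped.append((pid, str(exc)))
            continue
        # shared reduced model (no time terms, random intercept)
        red_cols = _model_cols(design, quadratic=False, with_time=False)
        try:
            reduced_ri = design.fit(y, cols=red_cols)
        except np.linalg.LinAlgError:
            reduced_ri = None
        spec = _MODEL_SPECS[sel.selected]
        if not spec["random_slope"] and reduced_ri is not None and reduced_ri.converged:
            df = 2 if spec["quadratic"] else 1
            p_time = _lrt_p(fits[sel.selected].loglik, reduced_ri.loglik, df)
            method = "lrt"
        else:
            p_time, method = time_effect_pvalue(y, design, sel, fits)
        best = fits[sel.selected]
        p_lin = p_quad = np.nan
        if reduced_ri is not None and reduced_ri.converged:
            if "M1" in fits and fits["M1"].converged:
                p_lin = _lrt_p(fits["M1"].loglik, reduced_ri.loglik, 1)
            if "M2" in fits and fits["M2"].converged:
                p_quad = _lrt_p(fits["M2"].loglik, reduced_ri.loglik, 2)
        rows.append(
            {
                "feature": pid,
                "selected_model": sel.selected,
                "p_time": max(p_time, np.finfo(float).tiny),
                "p_time_method": method,
                "beta_time": best.coef("time"),
                "beta_time2": best.coef("time2") if "time2" in best.columns else np.nan,
                "p_linear_ri": p_lin,
                "p_quadratic_ri": p_quad,
                **{f"aic_{m}": fits[m].aic if m in fits else np.nan
                   for m in MODEL_NAMES},
                **{f"converged_{m}": fits[m].converged if m in fits else False
                   for m in MODEL_NAMES},
            }
        )
    out = pd.DataFrame(rows).set_index("feature") if rows else pd.DataFrame(
        columns=["selected_model", "p_time"]
    )
    if len(out):
        out["q_time"] = benjamini_hochberg(out["p_time"])
    out.attrs["skipped"] = skipped
    out.attrs["phase"] = phase
    return out


def remission_interaction_test(values, phenotypes: pd.DataFrame,
                               phase: str = "therapy") -> float:
    """Wald p for time x remission on the first and last phase timepoints."""
    phase_pheno = phenotypes[phenotypes["phase"] == phase]
    tps = list(dict.fromkeys(phase_pheno["timepoint"]))
    keep = phase_pheno["timepoint"].isin([tps[0], tps[-1]])
    pheno = phase_pheno[keep]
    if isinstance(values, pd.Series):
        vals = values.reindex(pheno["sample_id"]).to_numpy(float)
    else:
        vals = np.asarray(values, dtype=float)
        if len(vals) == len(phenotypes):
            vals = vals[phenotypes["phase"].eq(phase).to_numpy()][keep.to_numpy()]
        elif len(vals) == len(phase_pheno):
            vals = vals[keep.to_numpy()]
        elif len(vals) != int(keep.sum()):
            raise ValueError("values length does not match the design")
    rem = (pheno["remission"] == "remitter").to_numpy(float)
    if rem.min() == rem.max():
        raise ValueError("remission status is constant; no contrast possible")
    t = (pheno["timepoint"] == tps[-1]).to_numpy(float)
    X = np.column_stack([np.ones_like(t), t, rem, t * rem])
    design = RepeatedMeasuresDesign(
        X, pheno["subject_id"].to_numpy(), t,
        columns=("Intercept", "time", "remission", "time_x_remission"),
    )
    fit = design.fit(vals)
    return fit.coef_p("time_x_remission")


def cell_type_trajectory_scan(proportions: pd.DataFrame, phenotypes: pd.DataFrame,
                              phase: str, alpha_lrt: float = 0.05) -> pd.DataFrame:
    """Trajectory test for each of the six cell types plus the GLR.

    Covariates are age, sex and cigarettes/day; p-values are BH-corrected
    across the 7 outcomes of the phase.  For the therapy phase a
    remission x time interaction on the first and last timepoints is
    reported as well.
    """
    outcomes = proportions[list(CELL_TYPES)].copy()
    outcomes["GLR"] = compute_glr(proportions)
    design = build_design(phenotypes, phase)
    rows = []
    for name, col in outcomes.items():
        vals = col.reindex(design.sample_ids).to_numpy(float)
        row = {"cell_type": name, "selected_model": None, "p_time": np.nan,
               "p_remission": np.nan, "flagged": False}
        try:
            rec = analyze_feature(vals, design, feature=name, phase=phase,
                                  alpha_lrt=alpha_lrt)
            row["selected_model"] = rec.selected_model
            row["p_time"] = rec.p_time
        except ValueError:
            row["flagged"] = True
        if phase == "therapy" and not row["flagged"]:
            try:
                row["p_remission"] = remission_interaction_test(
                    col, phenotypes, phase=phase
                )
            except ValueError:
                pass
        rows.append(row)
    out = pd.DataFrame(rows).set_index("cell_type")
    out["q_time"] = benjamini_hochberg(out["p_time"])
    if phase == "therapy":
        out["q_remission"] = benjamini_hochberg(out["p_remission"])
    return out


def average_probes(expression: pd.DataFrame, probe_ids) -> pd.Series:
    """Mean expression over a probe set (e.g. two probes of one transcript)."""
    return expression.loc[list(probe_ids)].mean(axis=0)


def expression_exposure_model(expr_values, phenotypes: pd.DataFrame,
                              covariates=None) -> dict[str, float]:
    """Quadratic-time LMM for exposure expression with remission interaction.

    Fits value ~ time + time^2 + remission + time^2 x remission with a
    random subject intercept on the exposure samples and returns Wald
    p-values for the time^2 term and its interaction with remission.
    """
    pheno, t = time_codes(phenotypes, "exposure")
    vals = np.asarray(expr_values, dtype=float)
    if isinstance(expr_values, pd.Series):
        vals = expr_values.reindex(pheno["sample_id"]).to_numpy(float)
    rem = (pheno["remission"] == "remitter").to_numpy(float)
    if rem.min() == rem.max():
        raise ValueError("remission status is constant; no contrast possible")
    cols = {
        "Intercept": np.ones_like(t),
        "time": t,
        "time2": t**2,
        "remission": rem,
        "time2_x_remission": t**2 * rem,
    }
    if covariates is not None:
        cov = covariates.reindex(pheno["sample_id"])
        for name in cov.columns:
            cols[name] = cov[name].to_numpy(float)
    X = np.column_stack(list(cols.values()))
    design = RepeatedMeasuresDesign(X, pheno["subject_id"].to_numpy(), t,
                                    columns=tuple(cols))
    fit = design.fit(vals)
    return {
        "p_time2": fit.coef_p("time2"),
        "p_time2_x_remission": fit.coef_p("time2_x_remission"),
    }
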