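"""Candidate-model selection, time-effect tests and the cell-type scan."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2, kstest

from methtraject import synth
from methtraject.lmm import LmmFit
from methtraject.trajectories import (
    analyze_feature,
    build_design,
    cell_type_trajectory_scan,
    expression_exposure_model,
    fit_candidate_lmms,
    remission_interaction_test,
    select_best_model,
    time_effect_pvalue,
)


def _fake_fit(loglik, k_fixed, n_vc=1, converged=True):
    return LmmFit(loglik=loglik, beta=np.zeros(k_fixed), bse=np.ones(k_fixed),
                  sigma2=1.0, gamma_intercept=0.1, gamma_slope=0.0, n_obs=100,
                  k_fixed=k_fixed, n_vc=n_vc, converged=converged)


class TestSelection:
    def test_equal_loglik_prefers_smaller_model(self):
        fits = {"M1": _fake_fit(-100.0, 3), "M2": _fake_fit(-100.0, 4),
                "M3": _fake_fit(-100.0, 3, 2), "M4": _fake_fit(-100.0, 4, 2)}
        sel = select_best_model(fits)
        assert sel.selected == "M1"

    def test_strong_quadratic_gain_selects_m2(self):
        # 2*dLL = 10 on 1 df -> p = 0.0016 < 0.05
        fits = {"M1": _fake_fit(-105.0, 3), "M2": _fake_fit(-100.0, 4),
                "M3": _fake_fit(-105.0, 3, 2), "M4": _fake_fit(-100.0, 4, 2)}
        sel = select_best_model(fits)
        assert sel.selected == "M2"
        assert sel.lrt_pvalues["M2_vs_M1"] == pytest.approx(
            chi2.sf(10.0, 1), rel=1e-12
        )
        assert sel.lrt_pvalues["M2_vs_M1"] == pytest.approx(0.001565, abs=2e-6)

    def test_strong_random_slope_gain_selects_m3(self):
        fits = {"M1": _fake_fit(-110.0, 3), "M2": _fake_fit(-109.9, 4),
                "M3": _fake_fit(-100.0, 3, 2), "M4": _fake_fit(-99.95, 4, 2)}
        sel = select_best_model(fits)
        assert sel.selected == "M3"
        # boundary mixture: 0.5 * chi2(1) tail
        assert sel.lrt_pvalues["M3_vs_M1"] == pytest.approx(
            0.5 * chi2.sf(20.0, 1), rel=1e-12
        )

    def test_only_one_converged_is_fallback(self):
        fits = {"M1": _fake_fit(-100.0, 3),
                "M2": _fake_fit(-90.0, 4, converged=False),
                "M3": _fake_fit(-90.0, 3, 2, converged=False),
                "M4": _fake_fit(-80.0, 4, 2, converged=False)}
        sel = select_best_model(fits)
        assert sel.selected == "M1" and sel.reason == "fallback"

    def test_no_converged_fit_raises(self):
        with pytest.raises(ValueError, match="converged"):
            select_best_model({"M1": _fake_fit(-1.0, 3, converged=False)})

    def test_mixed_fixed_orders_resolved_by_aic(self):
        # family A keeps M1, family B keeps M4 -> non-nested, min AIC wins
        fits = {"M1": _fake_fit(-100.0, 3), "M2": _fake_fit(-99.9, 4),
                "M3": _fake_fit(-100.0, 3, 2), "M4": _fake_fit(-90.0, 4, 2)}
        sel = select_best_model(fits)
        assert sel.reason == "aic"
        assert sel.selected == "M4"


class TestTimeEffect:
    def test_zero_gain_gives_p_one(self, exposure_layout):
        rng = np.random.default_rng(0)
        lay = exposure_layout
        des = build_design(lay["pheno"], "exposure")
        y = rng.normal(0, 1, lay["n_subjects"])[lay["subject_index"]] + rng.normal(
            0, 1, len(lay["time_centered"])
        )
        fits = fit_candidate_lmms(y, des)
        sel = select_best_model(fits)
        p, method = time_effect_pvalue(y, des, sel, fits)
        assert 0 < p <= 1

    def test_chi2_two_df_closed_form(self):
        # 2*dLL = 13.8 on 2 df -> exp(-6.9)
        assert chi2.sf(13.8, 2) == pytest.approx(np.exp(-6.9), rel=1e-12)
        assert chi2.sf(13.8, 2) == pytest.approx(0.0010078, abs=1e-7)

    def test_null_pvalues_approximately_uniform(self, exposure_layout):
        """Select-then-test on 200 pure-noise features stays calibrated."""
        rng = np.random.default_rng(1)
        lay = exposure_layout
        des = build_design(lay["pheno"], "exposure")
        n = len(lay["time_centered"])
        ps = []
        for _ in range(200):
            y = rng.normal(0, 1, lay["n_subjects"])[lay["subject_index"]] \
                + rng.normal(0, 1, n)
            ps.append(analyze_feature(y, des).p_time)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_covariate_feature_has_no_time_signal(self, exposure_layout):
        lay = exposure_layout
        des = build_design(lay["pheno"], "exposure")
        age = lay["pheno"][lay["pheno"]["phase"] == "exposure"]["age"].to_numpy()
        rng = np.random.default_rng(2)
        y = age + rng.normal(0, 1, lay["n_subjects"])[lay["subject_index"]] \
            + 0.5 * rng.normal(size=len(age))
        rec = analyze_feature(y, des)
        assert rec.p_time > 0.01


class TestPlantedTrajectories:
    def test_quadratic_pulse_selects_quadratic_family(self, exposure_layout):
        rng = np.random.default_rng(3)
        lay = exposure_layout
        des = build_design(lay["pheno"], "exposure")
        shape = 1.0 - lay["time_centered"] ** 2
        n = len(shape)
        hits = 0
        for _ in range(50):
            y = 3.0 * shape + rng.normal(0, 0.7, lay["n_subjects"])[
                lay["subject_index"]] + rng.normal(0, 1, n)
            hits += analyze_feature(y, des).selected_model in ("M2", "M4")
        assert hits >= 45

    def test_linear_trend_selects_linear_family(self, exposure_layout):
        rng = np.random.default_rng(4)
        lay = exposure_layout
        des = build_design(lay["pheno"], "exposure")
        t = lay["time_centered"]
        hits = 0
        for _ in range(50):
            y = 1.5 * t + rng.normal(0, 0.7, lay["n_subjects"])[
                lay["subject_index"]] + rng.normal(0, 1, len(t))
            hits += analyze_feature(y, des).selected_model in ("M1", "M3")
        assert hits >= 45


class TestRemissionInteraction:
    def test_planted_slope_difference_detected(self):
        design = synth.StudyDesign(n_subjects=40, remitter_fraction=0.5, seed=20)
        pheno = synth.make_phenotypes(design)
        th = pheno[pheno["phase"] == "therapy"]
        rng = np.random.default_rng(5)
        su = th["subject_id"].to_numpy()
        uniq = {s: i for i, s in enumerate(dict.fromkeys(su))}
        sidx = np.array([uniq[s] for s in su])
        rem = (th["remission"] == "remitter").to_numpy(float)
        tt = th["timepoint"].map({"T0": 0, "T4": 1, "E": 2, "K": 3}).to_numpy(float)
        hits = 0
        for _ in range(30):
            y = 3.0 * (tt / 3.0) * rem + rng.normal(0, 1, 40)[sidx] \
                + rng.normal(0, 1, len(tt))
            p = remission_interaction_test(
                pd.Series(y, index=th["sample_id"].to_numpy()), pheno
            )
            hits += p < 0.05
        assert hits >= 27

    def test_constant_remission_raises(self):
        design = synth.StudyDesign(n_subjects=10, remitter_fraction=0.0, seed=21)
        pheno = synth.make_phenotypes(design)
        th = pheno[pheno["phase"] == "therapy"]
        vals = pd.Series(np.random.default_rng(0).normal(size=len(th)),
                         index=th["sample_id"].to_numpy())
        with pytest.raises(ValueError, match="constant"):
            remission_interaction_test(vals, pheno)


class TestCellScan:
    def test_planted_granulocyte_pulse_found_flat_types_clean(self):
        detected, false_pos = 0, 0
        for rep in range(10):
            design = synth.StudyDesign(n_subjects=50, seed=100 + rep)
            pheno = synth.make_phenotypes(design)
            props = synth.simulate_cell_trajectories(design, "exposure",
                                                     phenotypes=pheno)
            scan = cell_type_trajectory_scan(props, pheno, "exposure")
            detected += (scan.loc["Gran", "q_time"] < 0.05) and (
                scan.loc["GLR", "q_time"] < 0.05
            )
            # CD8T and Bcell have no planted pulse (the others balance Gran)
            false_pos += (scan.loc[["CD8T", "Bcell"], "q_time"] < 0.05).sum()
        assert detected == 10
        assert false_pos <= 3

    def test_zero_variance_cell_type_flagged_others_unaffected(self):
        design = synth.StudyDesign(n_subjects=30, seed=30)
        pheno = synth.make_phenotypes(design)
        props = synth.simulate_cell_trajectories(design, "exposure",
                                                 phenotypes=pheno)
        props["CD8T"] = 0.1  # degenerate outcome
        scan = cell_type_trajectory_scan(props, pheno, "exposure")
        assert bool(scan.loc["CD8T", "flagged"])
        assert scan.drop("CD8T")["p_time"].notna().all()

    def test_therapy_scan_reports_remission_interaction(self):
        design = synth.StudyDesign(n_subjects=30, remitter_fraction=0.5, seed=31)
        pheno = synth.make_phenotypes(design)
        props = synth.simulate_cell_trajectories(design, "therapy",
                                                 phenotypes=pheno)
        scan = cell_type_trajectory_scan(props, pheno, "therapy")
        assert scan["p_remission"].notna().all()
        assert (scan["q_remission"] >= scan["p_remission"] - 1e-12).all()


class TestExpressionModel:
    def test_averaging_identical_probes_matches_single_probe(self):
        design = synth.StudyDesign(n_subjects=21, remitter_fraction=7 / 21, seed=40)
        pheno = synth.make_phenotypes(design)
        spec = pd.DataFrame(
            {"trajectory_class": ["quadratic_transient"], "effect_size": [-1.0],
             "remission_interaction": [-1.5]}, index=["probeA"],
        )
        expr, _ = synth.simulate_expression(design, spec, phenotypes=pheno)
        doubled = pd.concat([expr, expr.rename(index={"probeA": "probeB"})])
        from methtraject.trajectories import average_probes

        avg = average_probes(doubled, ["probeA", "probeB"])
        res_single = expression_exposure_model(expr.loc["probeA"], pheno)
        res_avg = expression_exposure_model(avg, pheno)
        assert res_avg["p_time2"] == pytest.approx(res_single["p_time2"], abs=1e-12)
        assert res_avg["p_time2_x_remission"] == pytest.approx(
            res_single["p_time2_x_remission"], abs=1e-12
        )

    def test_remitter_only_dip_yields_small_interaction_p(self):
        design = synth.StudyDesign(n_subjects=21, remitter_fraction=7 / 21, seed=41)
        pheno = synth.make_phenotypes(design)
        spec = pd.DataFrame(
            {"trajectory_class": ["quadratic_transient"], "effect_size": [0.0],
             "remission_interaction": [-2.5]}, index=["p1"],
        )
        hits = 0
        for rep in range(25):
            expr, _ = synth.simulate_expression(design, spec, seed=500 + rep,
                                                phenotypes=pheno)
            res = expression_exposure_model(expr.loc["p1"], pheno)
            hits += res["p_time2_x_remission"] < 0.05
        assert hits >= 20  # >= 80% power at the study's own sample size
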