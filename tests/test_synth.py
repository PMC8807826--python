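"""Generator correctness: identity cases, planted means, determinism."""

import numpy as np
import pandas as pd
import pytest

from methtraject import deconv, synth
from methtraject.io import CELL_TYPES


def test_flat_parameters_reproduce_baseline_composition():
    design = synth.StudyDesign(n_subjects=10, seed=1)
    params = {
        ct: {"baseline": synth.DEFAULT_BASELINES[ct], "slope": 0.0, "pulse": 0.0}
        for ct in CELL_TYPES
    }
    props = synth.simulate_cell_trajectories(
        design, "exposure", trajectory_params=params, subject_sd=0.0
    )
    expected = np.array([synth.DEFAULT_BASELINES[ct] for ct in CELL_TYPES])
    assert np.allclose(props.to_numpy(), expected[None, :], atol=1e-12)


def test_granulocyte_pulse_peaks_at_middle_timepoint():
    design = synth.StudyDesign(n_subjects=200, seed=2)
    props = synth.simulate_cell_trajectories(design, "exposure")
    pheno = synth.make_phenotypes(design)
    tp = pheno.set_index("sample_id").loc[props.index, "timepoint"]
    means = props.groupby(tp.to_numpy())["Gran"].mean()
    assert means["P1h"] > means["BE"]
    assert means["P1h"] > means["P24h"]


def test_out_of_simplex_parameters_name_the_cell_type():
    design = synth.StudyDesign(n_subjects=5, seed=3)
    params = {
        ct: {"baseline": synth.DEFAULT_BASELINES[ct], "slope": 0.0,
             "pulse": -0.10 if ct == "NK" else 0.0}
        for ct in CELL_TYPES
    }
    with pytest.raises(ValueError, match="NK"):
        synth.simulate_cell_trajectories(design, "exposure", trajectory_params=params)


def test_same_seed_identical_different_seed_differs(small_design):
    effects = synth.EffectSpec(n_cpgs=100, n_linear=5, n_quadratic=5,
                               n_clusters=2, cluster_size=5)
    a = synth.generate_study(small_design, effects=effects)
    b = synth.generate_study(small_design, effects=effects)
    pd.testing.assert_frame_equal(a.beta, b.beta)
    pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
    other = synth.generate_study(
        synth.StudyDesign(n_subjects=20, seed=99), effects=effects
    )
    assert not np.allclose(a.beta.to_numpy(), other.beta.to_numpy())


def test_pure_mixture_equals_profile_column():
    """One pure cell type, zero noise and effects: beta is the profile."""
    design = synth.StudyDesign(n_subjects=4, seed=5)
    profiles = synth.synthetic_reference(50, seed=5)
    effects = synth.EffectSpec(n_cpgs=50, n_linear=0, n_quadratic=0, n_clusters=0,
                               noise_sd=0.0, subject_sd=0.0, covariate_coefs={})
    pheno = synth.make_phenotypes(design)
    samples = pheno.loc[pheno["phase"] == "exposure", "sample_id"]
    pure = pd.DataFrame(0.0, index=samples, columns=list(CELL_TYPES))
    pure["CD4T"] = 1.0
    beta, _, _ = synth.mix_methylome(pure, profiles, effects, design, pheno)
    expected = profiles.profile_matrix["CD4T"].to_numpy()
    assert np.allclose(beta.to_numpy(), expected[:, None], atol=1e-12)


def _flat_composition_study(n_subjects, effects, seed):
    """Study with time-constant cell composition, isolating CpG effects."""
    design = synth.StudyDesign(n_subjects=n_subjects, seed=seed)
    pheno = synth.make_phenotypes(design)
    params = {
        ct: {"baseline": synth.DEFAULT_BASELINES[ct], "slope": 0.0, "pulse": 0.0}
        for ct in CELL_TYPES
    }
    parts = [
        synth.simulate_cell_trajectories(design, phase, trajectory_params=params,
                                         phenotypes=pheno)
        for phase in ("exposure", "therapy")
    ]
    props = pd.concat(parts).loc[pheno["sample_id"]]
    profiles = synth.synthetic_reference(effects.n_cpgs, seed=seed)
    beta, truth, _ = synth.mix_methylome(props, profiles, effects, design, pheno)
    return beta, truth, pheno


def test_null_cpgs_have_equal_timepoint_means():
    """With a time-constant composition, null CpGs have flat mean curves."""
    effects = synth.EffectSpec(n_cpgs=60, n_linear=0, n_quadratic=0, n_clusters=0)
    beta, truth, pheno = _flat_composition_study(200, effects, seed=6)
    expo = pheno[pheno["phase"] == "exposure"].set_index("sample_id")
    vals = beta[expo.index]
    means = vals.T.groupby(expo["timepoint"].to_numpy()).mean()
    spread = (means.max(axis=0) - means.min(axis=0)).to_numpy()
    se = vals.to_numpy().std(axis=1) / np.sqrt(200)
    assert (spread < 3 * se + 1e-9).mean() > 0.95


def test_transient_amplitude_matches_closed_form_mean():
    """Planted pulse of 0.05: middle-vs-outer mean difference ~ 0.05.

    With a time-constant composition the generative mean difference is
    exactly the planted amplitude (the pulse carrier is 1 at the middle
    exposure timepoint, 0 at the ends), so the observed difference must
    match 0.05 within Monte-Carlo error.
    """
    effects = synth.EffectSpec(n_cpgs=80, n_linear=0, n_quadratic=40,
                               n_clusters=0, effect_size=0.05)
    beta, truth, pheno = _flat_composition_study(200, effects, seed=7)
    quad = truth.query("trajectory_class == 'quadratic_transient'")
    expo = pheno[pheno["phase"] == "exposure"].set_index("sample_id")
    vals = beta.loc[quad.index, expo.index]
    means = vals.T.groupby(expo["timepoint"].to_numpy()).mean()
    observed = (means.loc["P1h"] - 0.5 * (means.loc["BE"] + means.loc["P24h"]))
    observed = observed.to_numpy() * np.sign(quad["effect_size"].to_numpy())
    se = vals.to_numpy().std(axis=1) / np.sqrt(200)
    assert (np.abs(observed - 0.05) < 3 * se + 0.01).all()
    assert abs(observed.mean() - 0.05) < 0.01


def test_mixture_term_shifts_discriminating_probes_with_composition():
    """With the default pulsed composition, even null CpGs whose profiles
    differ across cell types move at the middle exposure timepoint, and the
    realized means match the summed generative terms (mixture + effect)."""
    design = synth.StudyDesign(n_subjects=200, seed=17)
    effects = synth.EffectSpec(n_cpgs=60, n_linear=0, n_quadratic=0, n_clusters=0,
                               noise_sd=0.0, subject_sd=0.0, covariate_coefs={})
    study = synth.generate_study(design, effects=effects)
    # reconstruct expected beta from components: P @ w per sample
    P = study.reference.profile_matrix.loc[study.beta.index].to_numpy()
    W = study.true_proportions.loc[study.beta.columns].to_numpy()
    assert np.allclose(study.beta.to_numpy(), P @ W.T, atol=1e-9)


def test_truth_classes_partition_and_match_request(small_study):
    truth = small_study.truth
    counts = truth["trajectory_class"].value_counts()
    # 4 clusters x 5 probes: 3 transient clusters + 1 linear cluster
    assert counts["linear"] == 20 + 5
    assert counts["quadratic_transient"] == 20 + 15
    assert counts.sum() == 400
    assert set(truth["trajectory_class"]) <= set(synth.TRAJECTORY_CLASSES)


def test_beta_in_unit_interval_and_positions_increasing(small_study):
    beta = small_study.beta.to_numpy()
    assert beta.min() >= 0.0 and beta.max() <= 1.0
    for _, sub in small_study.manifest.groupby("chrom"):
        pos = np.sort(sub["pos"].to_numpy())
        assert (np.diff(pos) > 0).all()


def test_cluster_probes_fit_in_window(small_study):
    truth = small_study.truth
    for cid, sub in truth[truth["cluster_id"] >= 0].groupby("cluster_id"):
        assert sub["chrom"].nunique() == 1
        gaps = np.diff(np.sort(sub["pos"].to_numpy()))
        assert (gaps >= 50).all() and (gaps <= 400).all()


def test_zero_noise_mixture_is_invertible():
    design = synth.StudyDesign(n_subjects=10, seed=8)
    effects = synth.EffectSpec(n_cpgs=200, n_linear=0, n_quadratic=0, n_clusters=0,
                               noise_sd=0.0, subject_sd=0.0, covariate_coefs={})
    study = synth.generate_study(design, effects=effects)
    est = deconv.deconvolve(study.beta, study.reference.profile_matrix)
    err = (est[list(CELL_TYPES)] - study.true_proportions.loc[est.index]).abs()
    assert float(err.max().max()) < 1e-8


def test_paper_partition_shape():
    """4 exposure-only, 17 dual-phase and 21 therapy-only subjects."""
    design = synth.StudyDesign(n_subjects=42, partition=(4, 17, 21), seed=9)
    pheno = synth.make_phenotypes(design)
    by_subject = pheno.groupby("subject_id")["phase"].agg(set)
    n_expo = sum(v == {"exposure"} for v in by_subject)
    n_both = sum(v == {"exposure", "therapy"} for v in by_subject)
    n_ther = sum(v == {"therapy"} for v in by_subject)
    assert (n_expo, n_both, n_ther) == (4, 17, 21)
    assert (pheno["phase"] == "exposure").sum() == 21 * 3
    assert (pheno["phase"] == "therapy").sum() == 38 * 4


def test_full_overlap_puts_every_subject_in_both_phases():
    design = synth.StudyDesign(n_subjects=12, overlap_fraction=1.0, seed=10)
    pheno = synth.make_phenotypes(design)
    by_subject = pheno.groupby("subject_id")["phase"].nunique()
    assert (by_subject == 2).all()


def test_study_round_trips_through_readers(small_study, tmp_path):
    from methtraject import io

    paths = synth.write_study(small_study, tmp_path)
    beta = io.read_matrix(paths["beta"])
    pheno = io.read_sample_sheet(paths["phenotypes"])
    ref = io.read_reference(paths["reference"])
    manifest = io.read_manifest(paths["manifest"])
    assert beta.shape == small_study.beta.shape
    assert np.allclose(beta.to_numpy(), small_study.beta.to_numpy(), atol=1e-9)
    assert list(pheno["sample_id"]) == list(small_study.phenotypes["sample_id"])
    assert ref.shape == small_study.reference.profile_matrix.shape
    assert manifest.shape[0] == small_study.manifest.shape[0]


def test_expression_interaction_requires_two_groups():
    design = synth.StudyDesign(n_subjects=10, remitter_fraction=1.0, seed=12)
    spec = pd.DataFrame(
        {"trajectory_class": ["quadratic_transient"], "effect_size": [1.0],
         "remission_interaction": [0.5]}, index=["probe1"],
    )
    with pytest.raises(ValueError, match="remission"):
        synth.simulate_expression(design, spec)


def test_expression_null_interaction_identical_group_curves():
    design = synth.StudyDesign(n_subjects=400, remitter_fraction=0.5, seed=13)
    spec = pd.DataFrame(
        {"trajectory_class": ["quadratic_transient"], "effect_size": [2.0],
         "remission_interaction": [0.0]}, index=["p1"],
    )
    expr, _ = synth.simulate_expression(design, spec, noise_sd=0.3, subject_sd=0.0)
    pheno = synth.make_phenotypes(design).set_index("sample_id")
    expo = pheno.loc[expr.columns]
    df = pd.DataFrame({"y": expr.iloc[0].to_numpy(),
                       "tp": expo["timepoint"].to_numpy(),
                       "rem": expo["remission"].to_numpy()})
    curves = df.groupby(["rem", "tp"])["y"].mean().unstack()
    gap = (curves.loc["remitter"] - curves.loc["nonremitter"]).abs().max()
    assert gap < 3 * 0.3 / np.sqrt(200) * 2
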