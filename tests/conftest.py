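import warnings

import numpy as np
import pytest

from methtraject import synth

warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def small_design():
    return synth.StudyDesign(n_subjects=20, seed=11)


@pytest.fixture(scope="session")
def small_study(small_design):
    """A compact cohort with planted effects, shared across tests."""
    effects = synth.EffectSpec(
        n_cpgs=400, n_linear=20, n_quadratic=20, n_clusters=4, cluster_size=5
    )
    return synth.generate_study(small_design, effects=effects)


@pytest.fixture(scope="session")
def exposure_layout():
    """Subject/time layout of a 50-subject exposure phase for model tests."""
    design = synth.StudyDesign(n_subjects=50, seed=3)
    pheno = synth.make_phenotypes(design)
    sub = pheno[pheno["phase"] == "exposure"]
    subj = sub["subject_id"].to_numpy()
    uniq = {s: i for i, s in enumerate(dict.fromkeys(subj))}
    return {
        "design": design,
        "pheno": pheno,
        "subject_index": np.array([uniq[s] for s in subj]),
        "n_subjects": len(uniq),
        "time_centered": sub["timepoint"].map(
            {"BE": -1.0, "P1h": 0.0, "P24h": 1.0}
        ).to_numpy(),
    }
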