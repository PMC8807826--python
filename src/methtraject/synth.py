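"""Synthetic two-phase longitudinal methylation cohorts with known truth.

The generator emulates the design of a two-phase intervention study: an
acute exposure phase sampled at three timepoints (before, 1 h after the
anxiety peak, 24 h after) and a therapy course sampled at four (baseline,
mid-therapy, end, 2-month follow-up).  Beta values arise as cell-type
mixtures with time-varying leukocyte proportions; on top of the mixture,
individual CpGs carry null, linear or transient (quadratic-pulse)
subject-level trajectories, covariate effects (age, sex, smoking), an
optional remission-by-time interaction, and spatially clustered probe
runs that share a latent effect for DMR testing.  Noise is added on the
logit-beta scale and back-transformed, which keeps values inside (0, 1)
without heavy clipping.

Everything is driven by a single integer seed; the same seed yields
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io import (
    CELL_TYPES,
    write_manifest,
    write_matrix,
    write_reference,
    write_sample_sheet,
)

TRAJECTORY_CLASSES = ("null", "linear", "quadratic_transient")

#: Mean adult whole-blood composition used as the default baseline mixture.
DEFAULT_BASELINES = {
    "CD8T": 0.09,
    "CD4T": 0.16,
    "NK": 0.06,
    "Bcell": 0.07,
    "Mono": 0.07,
    "Gran": 0.55,
}

#: Acute-exposure pulse amplitudes: granulocytes surge one hour after the
#: anxiety peak while CD4 T and NK cells drop, all reverting by 24 h.
EXPOSURE_CELL_PARAMS = {
    ct: {"baseline": DEFAULT_BASELINES[ct], "slope": 0.0, "pulse": p}
    for ct, p in {
        "CD8T": 0.0,
        "CD4T": -0.04,
        "NK": -0.03,
        "Bcell": 0.0,
        "Mono": -0.01,
        "Gran": 0.08,
    }.items()
}

#: Therapy-course linear drifts: gradual granulocyte decline with rising
#: lymphocyte fractions over the weeks of treatment.
THERAPY_CELL_PARAMS = {
    ct: {"baseline": DEFAULT_BASELINES[ct], "slope": s, "pulse": 0.0}
    for ct, s in {
        "CD8T": 0.004,
        "CD4T": 0.008,
        "NK": 0.0,
        "Bcell": 0.003,
        "Mono": 0.0,
        "Gran": -0.015,
    }.items()
}


@dataclass(frozen=True)
class StudyDesign:
    """Shape of the two-phase longitudinal cohort."""

    n_subjects: int = 50
    exposure_timepoints: tuple[str, ...] = ("BE", "P1h", "P24h")
    therapy_timepoints: tuple[str, ...] = ("T0", "T4", "E", "K")
    overlap_fraction: float = 1.0
    remitter_fraction: float = 1.0 / 3.0
    seed: int = 0
    #: optional explicit partition (exposure-only, both, therapy-only);
    #: overrides overlap_fraction when set.
    partition: tuple[int, int, int] | None = None

    def __post_init__(self):
        for name, tps in (
            ("exposure_timepoints", self.exposure_timepoints),
            ("therapy_timepoints", self.therapy_timepoints),
        ):
            if len(tps) == 0:
                raise ValueError(f"{name} must be non-empty")
            if len(set(tps)) != len(tps):
                raise ValueError(f"{name} contains duplicate labels")
        for name, frac in (
            ("overlap_fraction", self.overlap_fraction),
            ("remitter_fraction", self.remitter_fraction),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.partition is not None:
            if len(self.partition) != 3 or any(v < 0 for v in self.partition):
                raise ValueError("partition must be 3 non-negative counts")
            if sum(self.partition) != self.n_subjects:
                raise ValueError("partition must sum to n_subjects")

    def subject_partition(self) -> tuple[int, int, int]:
        """Counts of (exposure-only, both-phase, therapy-only) subjects."""
        if self.partition is not None:
            return tuple(self.partition)
        n_both = int(round(self.overlap_fraction * self.n_subjects))
        rest = self.n_subjects - n_both
        n_expo_only = rest // 2
        return (n_expo_only, n_both, rest - n_expo_only)

    def timepoints(self, phase: str) -> tuple[str, ...]:
        if phase == "exposure":
            return self.exposure_timepoints
        if phase == "therapy":
            return self.therapy_timepoints
        raise ValueError(f"unknown phase: {phase!r}")


@dataclass(frozen=True)
class ReferenceProfiles:
    """Cell-type mean-beta reference basis for mixing and deconvolution."""

    cell_types: tuple[str, ...]
    profile_matrix: pd.DataFrame  # CpG x cell type

    def __post_init__(self):
        if len(self.cell_types) < 2:
            raise ValueError("need at least 2 cell types")
        if len(set(self.cell_types)) != len(self.cell_types):
            raise ValueError("cell-type names must be unique")
        vals = self.profile_matrix[list(self.cell_types)].values
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError("profile entries must lie in [0, 1]")


@dataclass
class EffectSpec:
    """Per-CpG statistical structure planted into the mixture."""

    n_cpgs: int = 5000
    n_linear: int = 150
    n_quadratic: int = 150
    effect_size: float = 0.05
    remission_interaction: float = 0.0
    n_clusters: int = 7
    cluster_size: int = 5
    cluster_latent_sd: float = 0.15
    noise_sd: float = 0.30
    subject_sd: float = 0.20
    covariate_coefs: dict = field(
        default_factory=lambda: {"age": 0.0004, "sex": 0.01, "cigarettes": 0.001}
    )

    def __post_init__(self):
        if self.noise_sd < 0 or self.subject_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if not np.isfinite([self.effect_size, self.remission_interaction]).all():
            raise ValueError("effect sizes must be finite")
        if self.n_linear + self.n_quadratic + self.n_clusters * self.cluster_size > self.n_cpgs:
            raise ValueError("more effect CpGs requested than n_cpgs")


@dataclass
class SyntheticStudy:
    """A fully realized synthetic cohort plus its ground truth."""

    beta: pd.DataFrame
    manifest: pd.DataFrame
    phenotypes: pd.DataFrame
    reference: ReferenceProfiles
    true_proportions: pd.DataFrame
    truth: pd.DataFrame
    expression: pd.DataFrame | None = None
    expression_truth: pd.DataFrame | None = None
    n_clipped: int = 0


# ---------------------------------------------------------------------------
# building blocks


def pulse_shape(n_timepoints: int) -> np.ndarray:
    """Quadratic pulse over ordinal timepoints: 0 at the ends, 1 at the center."""
    idx = np.arange(n_timepoints, dtype=float)
    c = idx - idx.mean()
    half = max(c.max(), 1.0)
    return 1.0 - (c / half) ** 2


def centered_index(n_timepoints: int) -> np.ndarray:
    idx = np.arange(n_timepoints, dtype=float)
    return idx - idx.mean()


def synthetic_reference(
    n_cpgs: int,
    seed: int = 0,
    cell_types: tuple[str, ...] = CELL_TYPES,
    frac_discriminating: float = 0.15,
) -> ReferenceProfiles:
    """Build a synthetic leukocyte reference-profile matrix.

    Most CpGs share a common methylation level across cell types (with a
    small jitter); a fraction are fully discriminating, mimicking the
    differentially methylated library sites used by reference panels.
    """
    rng = np.random.default_rng(seed)
    k = len(cell_types)
    base = rng.uniform(0.08, 0.92, size=n_cpgs)
    vals = np.clip(base[:, None] + rng.normal(0, 0.01, size=(n_cpgs, k)), 0.02, 0.98)
    n_disc = int(round(frac_discriminating * n_cpgs))
    disc = rng.choice(n_cpgs, size=n_disc, replace=False)
    vals[disc] = rng.uniform(0.05, 0.95, size=(n_disc, k))
    probes = [f"cg{i:08d}" for i in range(n_cpgs)]
    return ReferenceProfiles(
        cell_types=tuple(cell_types),
        profile_matrix=pd.DataFrame(vals, index=pd.Index(probes, name="probe_id"),
                                    columns=list(cell_types)),
    )


def make_phenotypes(design: StudyDesign) -> pd.DataFrame:
    """Sample sheet for the design: one row per collected blood sample."""
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 11]))
    n = design.n_subjects
    subjects = [f"S{i + 1:03d}" for i in range(n)]
    age = np.clip(np.round(rng.normal(32, 10, size=n)), 18, 65)
    sex = np.where(rng.random(n) < 0.64, "F", "M")  # female-predominant cohort
    smoker = rng.random(n) < 0.3
    cigs = np.where(smoker, rng.poisson(10, size=n), 0)
    n_rem = int(round(design.remitter_fraction * n))
    rem_idx = rng.permutation(n)[:n_rem]
    remission = np.array(["nonremitter"] * n, dtype=object)
    remission[rem_idx] = "remitter"

    n_expo_only, n_both, n_ther_only = design.subject_partition()
    in_exposure = np.zeros(n, dtype=bool)
    in_therapy = np.zeros(n, dtype=bool)
    in_exposure[: n_expo_only + n_both] = True
    in_therapy[n_expo_only:] = True

    rows = []
    for phase, member in (("exposure", in_exposure), ("therapy", in_therapy)):
        tps = design.timepoints(phase)
        for i in np.nonzero(member)[0]:
            for tp in tps:
                rows.append(
                    {
                        "sample_id": f"{subjects[i]}_{phase[:3]}_{tp}",
                        "subject_id": subjects[i],
                        "phase": phase,
                        "timepoint": tp,
                        "age": float(age[i]),
                        "sex": sex[i],
                        "cigarettes_per_day": int(cigs[i]),
                        "remission": remission[i],
                    }
                )
    return pd.DataFrame(rows)


def simulate_cell_trajectories(
    design: StudyDesign,
    phase: str,
    trajectory_params: dict | None = None,
    seed: int | None = None,
    phenotypes: pd.DataFrame | None = None,
    subject_sd: float = 0.01,
) -> pd.DataFrame:
    """Per-sample leukocyte composition with time-varying means.

    Each cell type follows baseline + slope * centered ordinal time +
    pulse * quadratic pulse shape, plus a subject-level random intercept;
    compositions are renormalized to sum to one after perturbation.
    """
    if trajectory_params is None:
        trajectory_params = (
            EXPOSURE_CELL_PARAMS if phase == "exposure" else THERAPY_CELL_PARAMS
        )
    if seed is None:
        seed = design.seed
    if phenotypes is None:
        phenotypes = make_phenotypes(design)
    pheno = phenotypes[phenotypes["phase"] == phase]
    if pheno.empty:
        raise ValueError(f"no samples in phase {phase!r}")
    tps = list(design.timepoints(phase))
    tidx = pheno["timepoint"].map({tp: i for i, tp in enumerate(tps)}).to_numpy()
    tc = centered_index(len(tps))[tidx]
    shape = pulse_shape(len(tps))[tidx]

    cell_types = list(trajectory_params)
    subjects = pheno["subject_id"].unique()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    b = rng.normal(0.0, subject_sd, size=(len(subjects), len(cell_types)))
    # truncate at 2 sd so rare draws cannot push small fractions out of (0, 1)
    b = np.clip(b, -2.0 * subject_sd, 2.0 * subject_sd)
    b -= b.mean(axis=1, keepdims=True)  # keep compositions near the simplex
    b_map = {s: b[i] for i, s in enumerate(subjects)}

    props = np.empty((len(pheno), len(cell_types)))
    for j, ct in enumerate(cell_types):
        par = trajectory_params[ct]
        props[:, j] = (
            par["baseline"]
            + par.get("slope", 0.0) * tc
            + par.get("pulse", 0.0) * shape
        )
    props += np.stack([b_map[s] for s in pheno["subject_id"]])
    for j, ct in enumerate(cell_types):
        col = props[:, j]
        if ((col <= 0.0) | (col >= 1.0)).any():
            raise ValueError(
                f"trajectory parameters push cell type {ct!r} outside (0, 1) "
                "before renormalization"
            )
    props /= props.sum(axis=1, keepdims=True)
    return pd.DataFrame(props, index=pd.Index(pheno["sample_id"], name="sample_id"),
                        columns=cell_types)


def realize_effects(effects: EffectSpec, seed: int) -> pd.DataFrame:
    """Assign trajectory classes, signed effect sizes and genomic positions.

    Cluster members (DMR-bearing runs) are quadratic-transient CpGs placed
    50-400 bp apart so a whole cluster fits inside a 750 bp window; all
    other probes are spaced 10 kb apart.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 37]))
    n = effects.n_cpgs
    probes = [f"cg{i:08d}" for i in range(n)]
    classes = np.array(["null"] * n, dtype=object)
    sizes = np.zeros(n)
    cluster_id = np.full(n, -1)

    order = rng.permutation(n)
    n_clu = effects.n_clusters * effects.cluster_size
    pos_ptr = 0
    for c in range(effects.n_clusters):
        members = order[pos_ptr : pos_ptr + effects.cluster_size]
        # most clusters are acute (transient) runs; the last one drifts
        # linearly so the gradual phase also carries a spatial signal
        is_linear_cluster = effects.n_clusters >= 2 and c == effects.n_clusters - 1
        classes[members] = "linear" if is_linear_cluster else "quadratic_transient"
        sizes[members] = effects.effect_size
        cluster_id[members] = c
        pos_ptr += effects.cluster_size
    lin = order[n_clu : n_clu + effects.n_linear]
    classes[lin] = "linear"
    sizes[lin] = effects.effect_size * rng.choice([-1.0, 1.0], size=len(lin))
    quad = order[n_clu + effects.n_linear : n_clu + effects.n_linear + effects.n_quadratic]
    classes[quad] = "quadratic_transient"
    sizes[quad] = effects.effect_size * rng.choice([-1.0, 1.0], size=len(quad))

    # genomic layout: clusters first (tight runs), then isolated probes
    chrom = np.empty(n, dtype=object)
    pos = np.zeros(n, dtype=int)
    chroms = [f"chr{c}" for c in range(1, 23)]
    cursor = {c: 1000 for c in chroms}
    idx_sorted = np.argsort(np.where(cluster_id >= 0, cluster_id, n + np.arange(n)))
    for i in idx_sorted:
        if cluster_id[i] >= 0:
            c = chroms[cluster_id[i] % len(chroms)]
            step = int(rng.integers(50, 401))
        else:
            c = chroms[i % len(chroms)]
            step = 10_000
        cursor[c] += step
        chrom[i] = c
        pos[i] = cursor[c]

    genes = [f"GENE{i // 10:04d}" for i in range(n)]
    return pd.DataFrame(
        {
            "probe_id": probes,
            "trajectory_class": classes,
            "effect_size": sizes,
            "remission_interaction": np.where(
                classes != "null", effects.remission_interaction, 0.0
            ),
            "cluster_id": cluster_id,
            "chrom": chrom,
            "pos": pos,
            "gene": genes,
        }
    ).set_index("probe_id")


def mix_methylome(
    proportions: pd.DataFrame,
    profiles: ReferenceProfiles,
    effects: EffectSpec,
    design: StudyDesign,
    phenotypes: pd.DataFrame,
    seed: int | None = None,
    truth: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Mix reference profiles by per-sample proportions and add effects.

    beta(cpg, sample) = inv-logit( logit( clip( P @ w + delta + covariates ) )
    + subject intercept + noise ), with delta determined by the CpG's
    trajectory class.  Returns (beta, truth, n_clipped).
    """
    if seed is None:
        seed = design.seed
    sample_ids = list(proportions.index)
    pheno = phenotypes.set_index("sample_id")
    missing = set(sample_ids) - set(pheno.index)
    if missing:
        raise ValueError(f"samples missing from phenotypes: {sorted(missing)[:5]}")
    pheno = pheno.loc[sample_ids]

    if truth is None:
        truth = realize_effects(effects, seed)
    probe_ids = list(truth.index)
    prof = profiles.profile_matrix
    if not set(probe_ids) <= set(prof.index):
        raise ValueError("profile CpG set does not cover requested CpGs")
    P = prof.loc[probe_ids, list(proportions.columns)].to_numpy()
    W = proportions.to_numpy()
    base = P @ W.T  # (n_cpgs, n_samples)

    # per-sample phase/timepoint codes
    n_samp = len(sample_ids)
    tc = np.zeros(n_samp)
    shape = np.zeros(n_samp)
    rel = np.zeros(n_samp)  # 0..1 position within phase (linear effect carrier)
    for phase in ("exposure", "therapy"):
        tps = list(design.timepoints(phase))
        in_ph = (pheno["phase"] == phase).to_numpy()
        if not in_ph.any():
            continue
        tidx = pheno.loc[in_ph, "timepoint"].map(
            {tp: i for i, tp in enumerate(tps)}
        ).to_numpy()
        tc[in_ph] = centered_index(len(tps))[tidx]
        shape[in_ph] = pulse_shape(len(tps))[tidx]
        rel[in_ph] = tidx / max(len(tps) - 1, 1)

    rem = (pheno["remission"] == "remitter").to_numpy().astype(float)
    classes = truth["trajectory_class"].to_numpy()
    sizes = truth["effect_size"].to_numpy()
    inter = truth["remission_interaction"].to_numpy()

    carrier = np.zeros((len(probe_ids), n_samp))
    is_lin = classes == "linear"
    is_quad = classes == "quadratic_transient"
    carrier[is_lin] = rel[None, :]
    carrier[is_quad] = shape[None, :]
    # remitters' time effects are scaled by (1 + interaction)
    scale = 1.0 + inter[:, None] * rem[None, :]
    delta = sizes[:, None] * carrier * scale

    coefs = effects.covariate_coefs
    age_c = pheno["age"].to_numpy() - pheno["age"].to_numpy().mean()
    sex_num = (pheno["sex"] == "M").to_numpy().astype(float)
    cigs = pheno["cigarettes_per_day"].to_numpy().astype(float)
    cov_term = (
        coefs.get("age", 0.0) * age_c
        + coefs.get("sex", 0.0) * sex_num
        + coefs.get("cigarettes", 0.0) * cigs
    )

    mu = base + delta + cov_term[None, :]
    eps = 1e-6
    n_clipped = int(((mu < eps) | (mu > 1 - eps)).sum())
    mu = np.clip(mu, eps, 1 - eps)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 53]))
    subjects = pheno["subject_id"].to_numpy()
    uniq_subj = pd.unique(subjects)
    subj_idx = pd.Series(np.arange(len(uniq_subj)), index=uniq_subj)[subjects].to_numpy()
    subj_int = rng.normal(0.0, effects.subject_sd, size=(len(probe_ids), len(uniq_subj)))
    noise = rng.normal(0.0, effects.noise_sd, size=mu.shape)
    # clustered probes share a latent per-sample effect on the logit scale
    clu = truth["cluster_id"].to_numpy()
    if (clu >= 0).any():
        n_clusters = int(clu.max()) + 1
        latent = rng.normal(0.0, effects.cluster_latent_sd, size=(n_clusters, n_samp))
        noise[clu >= 0] += latent[clu[clu >= 0]]

    z = logit(mu) + subj_int[:, subj_idx] + noise
    beta = expit(z)
    beta_df = pd.DataFrame(beta, index=pd.Index(probe_ids, name="probe_id"),
                           columns=sample_ids)
    return beta_df, truth, n_clipped


def simulate_expression(
    design: StudyDesign,
    probe_spec: pd.DataFrame,
    seed: int | None = None,
    phenotypes: pd.DataFrame | None = None,
    noise_sd: float = 1.0,
    subject_sd: float = 0.7,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gaussian expression intensities over the exposure timepoints.

    ``probe_spec`` is indexed by probe id with columns ``trajectory_class``,
    ``effect_size`` and ``remission_interaction``; the interaction shifts
    the remitter mean curve by exactly interaction * pulse shape.
    """
    if seed is None:
        seed = design.seed
    if len(design.exposure_timepoints) < 3:
        raise ValueError("expression model needs >= 3 exposure timepoints")
    if phenotypes is None:
        phenotypes = make_phenotypes(design)
    pheno = phenotypes[phenotypes["phase"] == "exposure"]
    if (probe_spec["remission_interaction"] != 0).any():
        groups = set(pheno.drop_duplicates("subject_id")["remission"])
        if len(groups) < 2:
            raise ValueError(
                "remission interaction requested but only one remission group present"
            )
    tps = list(design.exposure_timepoints)
    tidx = pheno["timepoint"].map({tp: i for i, tp in enumerate(tps)}).to_numpy()
    shape = pulse_shape(len(tps))[tidx]
    rel = tidx / max(len(tps) - 1, 1)
    rem = (pheno["remission"] == "remitter").to_numpy().astype(float)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 71]))
    subjects = pheno["subject_id"].to_numpy()
    uniq = pd.unique(subjects)
    sidx = pd.Series(np.arange(len(uniq)), index=uniq)[subjects].to_numpy()

    rows = []
    for pid, spec in probe_spec.iterrows():
        cls = spec["trajectory_class"]
        size = float(spec["effect_size"])
        inter = float(spec["remission_interaction"])
        if cls == "linear":
            carrier = rel
        elif cls == "quadratic_transient":
            carrier = shape
        else:
            carrier = np.zeros_like(shape)
        mean = size * carrier + inter * carrier * rem
        b = rng.normal(0.0, subject_sd, size=len(uniq))[sidx]
        rows.append(mean + b + rng.normal(0.0, noise_sd, size=len(shape)))
    expr = pd.DataFrame(rows, index=pd.Index(probe_spec.index, name="probe_id"),
                        columns=list(pheno["sample_id"]))
    return expr, probe_spec.copy()


def generate_study(
    design: StudyDesign,
    profiles: ReferenceProfiles | None = None,
    effects: EffectSpec | None = None,
    expression_spec: pd.DataFrame | None = None,
) -> SyntheticStudy:
    """Compose phenotypes, proportions, beta matrix and optional expression."""
    effects = effects if effects is not None else EffectSpec()
    if profiles is None:
        profiles = synthetic_reference(effects.n_cpgs, seed=design.seed)
    phenotypes = make_phenotypes(design)
    parts = []
    for phase in ("exposure", "therapy"):
        if (phenotypes["phase"] == phase).any():
            parts.append(
                simulate_cell_trajectories(design, phase, phenotypes=phenotypes)
            )
    proportions = pd.concat(parts)
    proportions = proportions.loc[phenotypes["sample_id"]]
    beta, truth, n_clipped = mix_methylome(
        proportions, profiles, effects, design, phenotypes
    )
    expression = expr_truth = None
    if expression_spec is not None:
        expression, expr_truth = simulate_expression(
            design, expression_spec, phenotypes=phenotypes
        )
    manifest = truth[["chrom", "pos", "gene"]].copy()
    return SyntheticStudy(
        beta=beta,
        manifest=manifest,
        phenotypes=phenotypes,
        reference=profiles,
        true_proportions=proportions,
        truth=truth,
        expression=expression,
        expression_truth=expr_truth,
        n_clipped=n_clipped,
    )


def write_study(study: SyntheticStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write the TSV bundle mirroring the pipeline's external input formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": out / "beta.tsv",
        "manifest": out / "manifest.tsv",
        "phenotypes": out / "samples.tsv",
        "reference": out / "reference.tsv",
        "truth": out / "truth.tsv",
        "proportions": out / "true_proportions.tsv",
    }
    write_matrix(study.beta, paths["beta"])
    write_manifest(study.manifest, paths["manifest"])
    write_sample_sheet(study.phenotypes, paths["phenotypes"])
    write_reference(study.reference.profile_matrix, paths["reference"])
    study.truth.reset_index().to_csv(paths["truth"], sep="\t", index=False)
    study.true_proportions.to_csv(paths["proportions"], sep="\t", float_format="%.10g")
    if study.expression is not None:
        paths["expression"] = out / "expression.tsv"
        write_matrix(study.expression, paths["expression"])
    return paths
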