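"""End-to-end orchestration from a single structured config.

Stage order: deconvolution -> cell-type trajectory scan -> inverse-normal
transform + surrogate variables -> per-CpG candidate-model fits ->
dual ranking and paired screens (-> candidate-gene subset) -> DMR calling.
Outputs are fixed-column TSVs plus a BED per phase and a JSON run
manifest; given the same config and seed every output byte is identical
across runs (wall-clock timings go to the log file only).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, deconv, dmr, io, preprocess, ranking, trajectories

log = logging.getLogger("methtraject")

DEFAULT_CONFIG = {
    "seed": 0,
    "paths": {},
    "phases": ["exposure", "therapy"],
    "model": {"time_coding": "centered", "n_sv": 2, "alpha_lrt": 0.05},
    "screen": {"top_k": 100, "q_threshold": 0.05},
    "dmr": {"window": 750, "seed_p": 0.05, "min_probes": 2},
}

#: fixed model feeding the DMR p-value track, per phase: the acute phase
#: uses the quadratic random-intercept model, the gradual phase the linear.
DMR_TRACK_COLUMN = {"exposure": "p_quadratic_ri", "therapy": "p_linear_ri"}


def load_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    _validate_config(cfg)
    return cfg


def _validate_config(cfg: dict) -> None:
    for name in ("alpha_lrt",):
        v = cfg["model"][name]
        if not 0 < v < 1:
            raise ValueError(f"model.{name} must lie in (0, 1)")
    for name in ("seed_p",):
        v = cfg["dmr"][name]
        if not 0 < v < 1:
            raise ValueError(f"dmr.{name} must lie in (0, 1)")
    if cfg["screen"]["top_k"] < 1:
        raise ValueError("screen.top_k must be >= 1")
    for key, p in cfg["paths"].items():
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"paths.{key}: {p} does not exist")


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode("utf-8")
    ).hexdigest()[:16]


def _covariate_frame(phenotypes: pd.DataFrame) -> pd.DataFrame:
    ph = phenotypes.set_index("sample_id")
    return pd.DataFrame(
        {
            "age": ph["age"].astype(float),
            "sex": (ph["sex"] == "M").astype(float),
            "cigarettes": ph["cigarettes_per_day"].astype(float),
        }
    )


def run_pipeline(cfg: dict, out_dir: str | Path) -> dict:
    """Execute every stage and write the output bundle; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    manifest: dict = {
        "config_hash": config_hash(cfg),
        "version": __version__,
        "stages": {},
        "warnings": [],
    }
    t_start = time.time()
    written: list[Path] = []
    try:
        _run_stages(cfg, out, manifest, written)
    except Exception:
        for path in written:  # partial outputs are removed on failure
            path.unlink(missing_ok=True)
        raise
    finally:
        log.info("total wall time %.1f s", time.time() - t_start)
        log.removeHandler(handler)
        handler.close()
    with open(out / "run_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _stage(manifest, name, n_in, n_out, note=""):
    manifest["stages"][name] = {"features_in": int(n_in), "features_out": int(n_out),
                                "note": note}
    log.info("stage %s: %d -> %d %s", name, n_in, n_out, note)


def _run_stages(cfg: dict, out: Path, manifest: dict, written: list[Path]) -> None:
    paths = cfg["paths"]
    for req in ("beta", "manifest", "phenotypes", "reference"):
        if not paths.get(req):
            raise FileNotFoundError(f"config paths.{req} is required")
    beta = io.read_matrix(paths["beta"])
    probe_manifest = io.read_manifest(paths["manifest"])
    phenotypes = io.read_sample_sheet(paths["phenotypes"])
    reference = io.read_reference(paths["reference"])
    _stage(manifest, "load", len(beta), len(beta))

    def emit(df, name, **kw):
        path = out / name
        df.to_csv(path, sep="\t", float_format="%.10g", **kw)
        written.append(path)
        return path

    # 1. deconvolution ------------------------------------------------------
    t0 = time.time()
    proportions = deconv.deconvolve(beta, reference)
    proportions["glr"] = deconv.compute_glr(proportions)
    emit(proportions, "proportions.tsv")
    _stage(manifest, "deconvolution", beta.shape[1], len(proportions))
    log.info("deconvolution %.1f s", time.time() - t0)

    cell_props = proportions[list(io.CELL_TYPES)]
    phases = [p for p in cfg["phases"] if (phenotypes["phase"] == p).any()]

    # 2. cell-type trajectory scan (Table-1-like) ---------------------------
    for phase in phases:
        scan = trajectories.cell_type_trajectory_scan(
            cell_props, phenotypes, phase, alpha_lrt=cfg["model"]["alpha_lrt"]
        )
        emit(scan, f"cell_trajectories_{phase}.tsv")
        _stage(manifest, f"cell_scan_{phase}", scan.shape[0], scan["p_time"].notna().sum())

    # 3. preprocessing ------------------------------------------------------
    t0 = time.time()
    beta_int = preprocess.int_matrix(beta)
    n_dropped = beta_int.attrs["n_dropped"]
    if n_dropped:
        manifest["warnings"].append(f"INT dropped {n_dropped} features")
    _stage(manifest, "inverse_normal", len(beta), len(beta_int),
           note=f"{n_dropped} dropped")
    log.info("INT %.1f s", time.time() - t0)

    base_cov = _covariate_frame(phenotypes)
    # drop one cell type (granulocytes) to avoid simplex collinearity
    model_cov = base_cov.join(cell_props.drop(columns="Gran"))

    results: dict[str, dict] = {}
    for phase in phases:
        phase_samples = phenotypes.loc[phenotypes["phase"] == phase, "sample_id"]
        n_sv = int(cfg["model"]["n_sv"])
        cov_phase = model_cov.loc[phase_samples]
        if n_sv > 0:
            svs = preprocess.estimate_surrogate_variables(
                beta_int[phase_samples], cov_phase, k=n_sv, seed=cfg["seed"]
            )
            cov_phase = cov_phase.join(svs)
        # 4. per-CpG candidate fits ----------------------------------------
        t0 = time.time()
        fits = trajectories.fit_feature_table(
            beta_int, phenotypes, phase, covariates=cov_phase,
            alpha_lrt=cfg["model"]["alpha_lrt"],
            coding=cfg["model"]["time_coding"],
        )
        emit(fits, f"fits_{phase}.tsv")
        _stage(manifest, f"fits_{phase}", len(beta_int), len(fits),
               note=f"{len(fits.attrs['skipped'])} skipped")
        log.info("fits %s %.1f s", phase, time.time() - t0)

        # 5. dual ranking (Table-2-like) -----------------------------------
        bio = ranking.biological_difference_matrix(beta, phenotypes, phase)
        rank = ranking.dual_rank(fits["p_time"], bio, k=cfg["screen"]["top_k"])
        rank["q_time"] = fits["q_time"].reindex(rank.index)
        rank["gene"] = probe_manifest["gene"].reindex(rank.index)
        emit(rank, f"rank_{phase}.tsv")
        _stage(manifest, f"rank_{phase}", len(fits), len(rank),
               note=f"{rank.attrs['n_excluded']} excluded")

        # 6. paired first-vs-last screen on residualized values ------------
        resid = preprocess.residualize(
            beta_int[phase_samples],
            cell_props.drop(columns="Gran").loc[phase_samples],
        )
        screen = ranking.paired_delta_screen(resid, phenotypes, phase)
        emit(screen, f"screen_{phase}.tsv")
        _stage(manifest, f"screen_{phase}", len(resid), screen["p"].notna().sum())

        # 7. candidate-gene subset -----------------------------------------
        if paths.get("gene_list"):
            genes = [
                g.strip() for g in Path(paths["gene_list"]).read_text().splitlines()
                if g.strip()
            ]
            subset = ranking.candidate_subset(rank, genes, probe_manifest,
                                              k=cfg["screen"]["top_k"])
            emit(subset, f"candidate_{phase}.tsv")
            _stage(manifest, f"candidate_{phase}", len(rank), len(subset))

        # 8. DMR calling ----------------------------------------------------
        track_col = DMR_TRACK_COLUMN[phase]
        track = probe_manifest.join(fits[track_col].rename("p"), how="inner")
        track = track.reset_index().rename(columns={"index": "probe_id"})
        track = track[np.isfinite(track["p"])]
        track["p"] = track["p"].clip(lower=dmr.P_FLOOR)
        regions = dmr.dmr_scan(
            track[["chrom", "pos", "p", "probe_id"]],
            window=cfg["dmr"]["window"], seed_p=cfg["dmr"]["seed_p"],
            min_probes=cfg["dmr"]["min_probes"],
        )
        bed = out / f"dmr_{phase}.bed"
        io.write_regions_bed(regions, bed)
        written.append(bed)
        _stage(manifest, f"dmr_{phase}", len(track), len(regions))
        results[phase] = {"fits": fits, "rank": rank, "screen": screen,
                          "regions": regions}

    # 9. expression exposure model -----------------------------------------
    if paths.get("expression") and "exposure" in phases:
        expr = io.read_matrix(paths["expression"])
        rows = []
        for pid, row in expr.iterrows():
            try:
                res = trajectories.expression_exposure_model(row, phenotypes)
            except ValueError as exc:
                manifest["warnings"].append(f"expression {pid}: {exc}")
                continue
            rows.append({"probe_id": pid, **res})
        if rows:
            emit(pd.DataFrame(rows).set_index("probe_id"), "expression_exposure.tsv")
        _stage(manifest, "expression", len(expr), len(rows))

    manifest["stages_order"] = list(manifest["stages"])
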