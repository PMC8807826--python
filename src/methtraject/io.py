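"""Tab-delimited readers and writers for the pipeline's interchange formats.

All tables are TSV with a header row, UTF-8, '.' decimal.  Matrices put
features on rows with the probe id in the first column; the sample sheet
is one row per collected sample.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

#: Canonical leukocyte panel, in reference-profile column order.
CELL_TYPES = ("CD8T", "CD4T", "NK", "Bcell", "Mono", "Gran")

#: Lymphocyte subset used in the granulocyte-to-lymphocyte ratio denominator.
LYMPHOCYTES = ("CD8T", "CD4T", "NK", "Bcell")

SAMPLE_SHEET_COLUMNS = (
    "sample_id",
    "subject_id",
    "phase",
    "timepoint",
    "age",
    "sex",
    "cigarettes_per_day",
    "remission",
)

MANIFEST_COLUMNS = ("probe_id", "chrom", "pos", "gene")

PHASES = ("exposure", "therapy")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a feature-by-sample matrix TSV (first column = probe id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "probe_id"
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df = df.copy()
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str, "gene": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df.set_index("probe_id")


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.reset_index().to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    pheno = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    return validate_sample_sheet(pheno)


def write_sample_sheet(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(path, sep="\t", index=False)


def validate_sample_sheet(pheno: pd.DataFrame) -> pd.DataFrame:
    missing = set(SAMPLE_SHEET_COLUMNS) - set(pheno.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if pheno["sample_id"].duplicated().any():
        dupes = pheno.loc[pheno["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids: {dupes[:5]}")
    bad = set(pheno["phase"]) - set(PHASES)
    if bad:
        raise ValueError(f"unknown phase labels: {sorted(bad)}")
    return pheno


def read_reference(path: str | Path) -> pd.DataFrame:
    """Read a CpG x cell-type mean-beta reference profile matrix."""
    ref = pd.read_csv(path, sep="\t", index_col=0)
    ref.index.name = "probe_id"
    if ref.shape[1] < 2:
        raise ValueError("reference must contain at least 2 cell types")
    if ref.columns.duplicated().any():
        raise ValueError("duplicate cell-type names in reference")
    if ((ref.values < 0) | (ref.values > 1)).any():
        raise ValueError("reference profile entries must lie in [0, 1]")
    return ref


def write_reference(ref: pd.DataFrame, path: str | Path) -> None:
    write_matrix(ref, path)


def read_pvalue_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED-like (chrom, start, end, p) p-value track.

    Positions are converted from 0-based half-open BED intervals back to
    1-based probe positions (pos = end).
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "p"],
                     dtype={"chrom": str})
    track = pd.DataFrame({
        "chrom": df["chrom"],
        "pos": df["end"].astype(int),
        "p": df["p"].astype(float),
    })
    return track


def write_regions_bed(regions: pd.DataFrame, path: str | Path) -> None:
    """Write DMR calls as BED6+ (0-based half-open intervals)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#chrom\tstart\tend\tname\tn_probes\tregion_p\tsidak_p\n")
        for i, row in enumerate(regions.itertuples(index=False)):
            fh.write(
                f"{row.chrom}\t{row.start - 1}\t{row.end}\tdmr_{i + 1}\t"
                f"{row.n_probes}\t{row.region_p:.6g}\t{row.sidak_p:.6g}\n"
            )
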