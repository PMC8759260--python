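"""Readers and writers for the package's tabular file dialects.

All matrices are TSV with samples in rows and feature IDs in the
header; coordinates are TSV with 1-based CpG positions; interval tracks
are BED (0-based half-open).  Values are written with full float
precision so every file round-trips through its reader bit-exactly.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd

from .simulate import SortedCellReference, SyntheticCohort


def write_matrix(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = out.index.name or "sample"
    out.to_csv(path, sep="\t")


def read_matrix(path, dtype=None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(dtype) if dtype is not None else df


def write_covariates(cov: pd.DataFrame, path) -> None:
    write_matrix(cov, path)


def read_covariates(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_cpg_coords(coords: pd.DataFrame, path) -> None:
    out = coords.reset_index()
    out = out[["chrom", "pos", out.columns[0]]]
    out.columns = ["chrom", "pos", "cpg"]
    out.to_csv(path, sep="\t", index=False)


def read_cpg_coords(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return df.set_index("cpg")[["chrom", "pos"]]


def write_gene_coords(coords: pd.DataFrame, path) -> None:
    out = coords.reset_index()
    out = out[["chrom", "start", "end", "strand", "biotype", out.columns[0]]]
    out.columns = ["chrom", "start", "end", "strand", "biotype", "gene"]
    out.to_csv(path, sep="\t", index=False)


def read_gene_coords(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return df.set_index("gene")[["chrom", "start", "end", "strand", "biotype"]]


def read_bed(path, names=("chrom", "start", "end", "name")) -> pd.DataFrame:
    """BED3/BED4 reader; intervals stay 0-based half-open."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = list(names[: df.shape[1]])
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def write_qtl_table(df: pd.DataFrame, path) -> None:
    df[["snp", "target"]].to_csv(path, sep="\t", index=False)


def write_sorted_reference(ref: SortedCellReference, path) -> None:
    out = ref.sample_meta.join(ref.beta)
    out.to_csv(path, sep="\t")


def read_sorted_reference(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Returns (beta, sample_meta)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta_cols = ["donor", "lineage", "phenotype"]
    meta = df[meta_cols]
    beta = df.drop(columns=meta_cols)
    return beta, meta


def write_cohort(cohort: SyntheticCohort, out_dir) -> dict[str, Path]:
    """Write every cohort table under ``out_dir``; returns the path map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": out_dir / "beta.tsv",
        "counts": out_dir / "counts.tsv",
        "covariates": out_dir / "covariates.tsv",
        "cpg_coords": out_dir / "cpg_coords.tsv",
        "gene_coords": out_dir / "gene_annotation.tsv",
    }
    write_matrix(cohort.beta, paths["beta"])
    write_matrix(cohort.counts, paths["counts"])
    write_covariates(cohort.covariates, paths["covariates"])
    write_cpg_coords(cohort.cpg_coords, paths["cpg_coords"])
    write_gene_coords(cohort.gene_coords, paths["gene_coords"])
    if cohort.genotypes is not None:
        paths["genotypes"] = out_dir / "genotypes.tsv"
        write_matrix(cohort.genotypes, paths["genotypes"])
    if cohort.replicate_pairs:
        paths["replicates"] = out_dir / "replicate_pairs.tsv"
        pd.DataFrame(cohort.replicate_pairs, columns=["sample", "replicate"]).to_csv(
            paths["replicates"], sep="\t", index=False)
    return paths


def read_cohort(out_dir) -> SyntheticCohort:
    out_dir = Path(out_dir)
    reps = []
    rep_path = out_dir / "replicate_pairs.tsv"
    if rep_path.exists():
        reps = [tuple(r) for r in
                pd.read_csv(rep_path, sep="\t").itertuples(index=False)]
    geno = None
    geno_path = out_dir / "genotypes.tsv"
    if geno_path.exists():
        geno = read_matrix(geno_path, dtype=int)
    return SyntheticCohort(
        beta=read_matrix(out_dir / "beta.tsv", dtype=float),
        counts=read_matrix(out_dir / "counts.tsv", dtype=int),
        covariates=read_covariates(out_dir / "covariates.tsv"),
        cpg_coords=read_cpg_coords(out_dir / "cpg_coords.tsv"),
        gene_coords=read_gene_coords(out_dir / "gene_annotation.tsv"),
        replicate_pairs=reps,
        genotypes=geno)
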