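"""Rule out genetic drivers of observed trans associations.

A CpG-gene trans association could be explained by a variant that is
simultaneously a cis-meQTL for the CpG and a trans-eQTL for the gene
(or, mirrored, a cis-eQTL for the gene and a trans-meQTL for the CpG).
This module intersects observed association pairs with already-
thresholded QTL catalogs, matching SNPs by ID.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd


@dataclass(frozen=True)
class QTLRecord:
    snp: str
    target: str
    kind: str       # methylation | expression
    relation: str   # cis | trans

    def __post_init__(self):
        for f in ("snp", "target", "kind", "relation"):
            if not getattr(self, f):
                raise ValueError(f"QTLRecord field {f!r} must be non-empty")


@dataclass
class CrosscheckResult:
    flagged: pd.DataFrame         # cpg, gene, shared_snps per direction
    n_cpgs_flagged: int
    n_genes_flagged: int
    n_cpgs_total: int
    n_genes_total: int


def load_qtl_table(path, kind: str, relation: str) -> list[QTLRecord]:
    """Read a TSV with columns snp, target; duplicates collapse to one
    record."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"snp", "target"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df = df.drop_duplicates(subset=["snp", "target"])
    return [QTLRecord(snp=r.snp, target=r.target, kind=kind, relation=relation)
            for r in df.itertuples()]


def _index_by_target(records: Iterable[QTLRecord]) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for r in records:
        out.setdefault(r.target, set()).add(r.snp)
    return out


def crosscheck(assoc_pairs: Sequence[tuple[str, str]],
               meqtls: Iterable[QTLRecord], eqtls: Iterable[QTLRecord],
               direction: str = "cpg_first") -> CrosscheckResult:
    """Flag association pairs potentially driven by a shared variant.

    ``cpg_first``: for each CpG collect its cis-meQTL SNPs, flag pairs
    whose gene carries any of those SNPs as a trans-eQTL.
    ``gene_first``: the mirror image with cis-eQTLs and trans-meQTLs.
    Supplied QTL records are filtered to the relevant kind/relation.
    """
    if direction == "cpg_first":
        cis = _index_by_target([r for r in meqtls
                                if r.kind == "methylation" and r.relation == "cis"])
        trans = _index_by_target([r for r in eqtls
                                  if r.kind == "expression" and r.relation == "trans"])
        first_of = lambda pair: pair[0]   # noqa: E731
        second_of = lambda pair: pair[1]  # noqa: E731
    elif direction == "gene_first":
        cis = _index_by_target([r for r in eqtls
                                if r.kind == "expression" and r.relation == "cis"])
        trans = _index_by_target([r for r in meqtls
                                  if r.kind == "methylation" and r.relation == "trans"])
        first_of = lambda pair: pair[1]   # noqa: E731
        second_of = lambda pair: pair[0]  # noqa: E731
    else:
        raise ValueError(f"unknown direction {direction!r}")

    rows = []
    for pair in assoc_pairs:
        shared = cis.get(first_of(pair), set()) & trans.get(second_of(pair), set())
        if shared:
            rows.append((pair[0], pair[1], ",".join(sorted(shared))))
    flagged = pd.DataFrame(rows, columns=["cpg", "gene", "shared_snps"])
    cpgs = {p[0] for p in assoc_pairs}
    genes = {p[1] for p in assoc_pairs}
    return CrosscheckResult(
        flagged=flagged,
        n_cpgs_flagged=flagged["cpg"].nunique(),
        n_genes_flagged=flagged["gene"].nunique(),
        n_cpgs_total=len(cpgs),
        n_genes_total=len(genes))


def summary_line(result: CrosscheckResult) -> str:
    return (f"{result.n_cpgs_flagged}/{result.n_cpgs_total} CpGs flagged, "
            f"{result.n_genes_flagged}/{result.n_genes_total} genes flagged")
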