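"""Plain-text readers and writers for the pipeline's tables and matrices.

Formats: pedigree as 7-column CSV (unknown parent encoded as 0); genotypes
as a PLINK-.raw-compatible whitespace table (FID/IID plus one 0/1/2 column
per SNP) and as a compact TSV; traits as TSV; symmetric matrices as dense
TSV with ID header row/column or as three-column lower-triangle sparse
text.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .popsim import GenotypeMatrix, Pedigree, TraitRecords
from .relmat import RelationshipMatrix

__all__ = [
    "write_pedigree_csv", "read_pedigree_csv",
    "write_genotypes_raw", "write_genotypes_tsv", "read_genotypes_tsv",
    "write_traits_tsv", "read_traits_tsv",
    "write_matrix_tsv", "read_matrix_tsv", "write_matrix_sparse",
]

PED_COLUMNS = ["animal", "sire", "dam", "order", "genotyped", "cohort", "sex"]


def write_pedigree_csv(ped: Pedigree, path: str | Path) -> None:
    ped.records[PED_COLUMNS].to_csv(path, index=False)


def read_pedigree_csv(path: str | Path) -> Pedigree:
    df = pd.read_csv(path, dtype={"animal": str, "sire": str, "dam": str})
    df["genotyped"] = df["genotyped"].astype(bool)
    ped = Pedigree(df)
    ped.validate()
    return ped


def write_genotypes_raw(geno: GenotypeMatrix, path: str | Path) -> None:
    """PLINK .raw-style: FID IID then one allele-count column per SNP."""
    df = pd.DataFrame(geno.counts, columns=geno.snp_ids)
    df.insert(0, "IID", geno.animal_ids)
    df.insert(0, "FID", geno.animal_ids)
    df.to_csv(path, sep=" ", index=False)


def write_genotypes_tsv(geno: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(geno.counts, index=pd.Index(geno.animal_ids, name="animal"),
                      columns=geno.snp_ids)
    df.to_csv(path, sep="\t")


def read_genotypes_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    counts = df.to_numpy(dtype=np.int8)
    freqs = counts.mean(axis=0) / 2.0
    return GenotypeMatrix(
        animal_ids=[str(a) for a in df.index],
        snp_ids=[str(s) for s in df.columns],
        counts=counts,
        freqs=freqs,
    )


def write_traits_tsv(traits: TraitRecords, path: str | Path) -> None:
    traits.table.to_csv(path, sep="\t", index=False)


def read_traits_tsv(path: str | Path) -> TraitRecords:
    df = pd.read_csv(path, sep="\t", dtype={"animal": str})
    df["included"] = df["included"].astype(bool)
    return TraitRecords(df)


def write_matrix_tsv(mat: RelationshipMatrix, path: str | Path) -> None:
    pd.DataFrame(mat.values, index=pd.Index(mat.animal_ids, name=mat.kind),
                 columns=mat.animal_ids).to_csv(path, sep="\t")


def read_matrix_tsv(path: str | Path, kind: str = "A") -> RelationshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return RelationshipMatrix([str(a) for a in df.index], df.to_numpy(float), kind)


def write_matrix_sparse(mat: RelationshipMatrix, path: str | Path, tol: float = 0.0) -> None:
    """Lower triangle as (id_i, id_j, value); entries with |value| <= tol skipped."""
    ids = mat.animal_ids
    with open(path, "w") as fh:
        fh.write("id_i\tid_j\tvalue\n")
        for i in range(len(ids)):
            for j in range(i + 1):
                v = mat.values[i, j]
                if abs(v) > tol or i == j:
                    fh.write(f"{ids[i]}\t{ids[j]}\t{v:.10g}\n")
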