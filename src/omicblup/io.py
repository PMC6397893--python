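"""Readers and writers for the plain-text formats the tool exchanges.

Genotypes come either from a minimal biallelic VCF (GT field only, parsed
with :mod:`cyvcf2`) or from a tab-separated line x marker dosage table.
Expression, phenotype and kernel matrices are tab-separated tables with a
header row of feature IDs and a first column of line IDs; missing values are
written as ``NA``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, GenotypeMatrix, KernelMatrix

logger = logging.getLogger("omicblup")

__all__ = [
    "read_genotypes",
    "read_expression",
    "read_phenotypes",
    "write_genotypes",
    "write_expression",
    "write_phenotypes",
    "read_kernel",
    "write_kernel",
]


def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Read genotypes from VCF or dosage TSV.

    ``format`` is ``"vcf"`` or ``"tsv"``; if ``None`` it is inferred from the
    file extension.  VCF dosages count the alternate allele; after centering,
    the genomic relationship matrix is invariant to which allele is counted,
    so the orientation is immaterial downstream.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if ".vcf" in path.suffixes or path.suffix == ".vcf" else "tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_genotype_tsv(path)
    raise ValueError(f"unknown genotype format {format!r} (expected 'vcf' or 'tsv')")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    line_ids = list(vcf.samples)
    dosages: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    marker_ids: list[str] = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {var.CHROM}:{var.POS} "
                f"(ALT={var.ALT}); only biallelic sites are supported"
            )
        gt = np.asarray(var.gt_types)  # 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        dose = np.choose(gt, [0.0, 1.0, np.nan, 2.0])
        dosages.append(dose)
        masks.append(gt == 2)
        mid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        marker_ids.append(mid)
    vcf.close()
    if not marker_ids:
        raise ValueError(f"no variant records in {path}")
    d = np.column_stack(dosages)
    m = np.column_stack(masks)
    return GenotypeMatrix.from_dosages(d, line_ids, marker_ids, mask=m)


def _read_genotype_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], dtype=str)
    values = np.full(df.shape, np.nan)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            if pd.isna(cell):
                continue
            try:
                v = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric dosage {cell!r} at line {df.index[i]!r}, "
                    f"marker {col!r}"
                ) from None
            if v not in (0.0, 1.0, 2.0):
                raise ValueError(
                    f"dosage {cell!r} outside {{0,1,2}} at line {df.index[i]!r}, "
                    f"marker {col!r}"
                )
            values[i, j] = v
    return GenotypeMatrix.from_dosages(
        values, [str(i) for i in df.index], [str(c) for c in df.columns]
    )


def write_genotypes(g: GenotypeMatrix, path: str | Path) -> None:
    d = g.dosages.copy()
    d[g.mask] = np.nan
    # integer formatting where dosages are integral (pre-imputation data)
    df = pd.DataFrame(d, index=g.line_ids, columns=g.marker_ids)
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.12g")


def read_expression(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValueError("no features: expression file has no gene columns")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValueError(
                f"non-numeric expression value {bad.iloc[0]!r} at line "
                f"{bad.index[0]!r}, gene {col!r}"
            )
    return ExpressionMatrix(
        df.to_numpy(dtype=float),
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
    )


def write_expression(x: ExpressionMatrix, path: str | Path) -> None:
    pd.DataFrame(x.values, index=x.line_ids, columns=x.gene_ids).to_csv(
        path, sep="\t", float_format="%.17g"
    )


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a line x trait TSV; returns a DataFrame indexed by line ID."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate line ID in phenotype file: {dup!r}")
    return df


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")


def write_kernel(k: KernelMatrix, path: str | Path) -> None:
    """Write a kernel as TSV with line IDs as header row and first column.

    Entries are written with 17 significant digits so a round trip
    reproduces them to better than 12 significant digits.
    """
    k.check_symmetric(tol=1e-8)
    df = pd.DataFrame(k.values, index=k.line_ids, columns=k.line_ids)
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_kernel(
    path: str | Path,
    label: str = "K",
    expected_ids: Sequence[str] | None = None,
) -> KernelMatrix:
    """Read a kernel TSV.

    If ``expected_ids`` is given, the kernel is re-ordered to that ID list;
    missing or extra IDs are errors.  Asymmetry beyond 1e-8 is an error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    if row_ids != col_ids:
        raise ValueError("kernel file row and column IDs differ")
    k = KernelMatrix(df.to_numpy(dtype=float), row_ids, label)
    k.check_symmetric(tol=1e-8)
    if expected_ids is not None:
        k = k.reorder(expected_ids)
    return k
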