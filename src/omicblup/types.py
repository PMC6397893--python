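"""Core data containers shared across the package.

All containers carry explicit line identifiers so that genotype, expression,
phenotype and kernel objects can be aligned unambiguously.  Matrices are plain
``numpy`` arrays; labels are Python lists of strings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("omicblup")

__all__ = [
    "GenotypeMatrix",
    "ExpressionMatrix",
    "StandardizedExpression",
    "KernelMatrix",
    "Dataset",
]


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} ID: {i!r}")
        seen.add(i)
    return ids


@dataclass
class GenotypeMatrix:
    """Line x marker allele-dosage matrix for inbred or outbred samples.

    Dosages count the tracked allele per marker (0, 1 or 2 copies; real-valued
    after mean imputation).  ``mask`` flags missing calls; ``freqs`` holds the
    tracked-allele frequency computed over non-missing calls only.
    """

    dosages: np.ndarray
    mask: np.ndarray
    line_ids: list[str]
    marker_ids: list[str]
    freqs: np.ndarray

    @classmethod
    def from_dosages(
        cls,
        dosages: np.ndarray,
        line_ids: Sequence[str],
        marker_ids: Sequence[str],
        mask: np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        dosages = np.asarray(dosages, dtype=float)
        if dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D line x marker array")
        if mask is None:
            mask = np.isnan(dosages)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != dosages.shape:
            raise ValueError("mask shape does not match dosages")
        line_ids = _check_unique(line_ids, "line")
        marker_ids = _check_unique(marker_ids, "marker")
        if dosages.shape != (len(line_ids), len(marker_ids)):
            raise ValueError("dosage shape does not match ID lists")
        freqs = _allele_frequencies(dosages, mask)
        return cls(dosages, mask, line_ids, marker_ids, freqs)

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def maf(self) -> np.ndarray:
        """Minor allele frequency per marker: min(p, 1 - p)."""
        return np.minimum(self.freqs, 1.0 - self.freqs)

    def subset(self, line_idx=None, marker_idx=None) -> "GenotypeMatrix":
        li = np.arange(self.n_lines) if line_idx is None else np.asarray(line_idx)
        mi = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        d = self.dosages[np.ix_(li, mi)]
        m = self.mask[np.ix_(li, mi)]
        return GenotypeMatrix.from_dosages(
            d,
            [self.line_ids[i] for i in li],
            [self.marker_ids[i] for i in mi],
            mask=m,
        )


def _allele_frequencies(dosages: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Tracked-allele frequency per marker over non-missing calls."""
    d = np.where(mask, np.nan, dosages)
    with np.errstate(invalid="ignore"):
        counts = np.nansum(d, axis=0)
        called = np.sum(~mask, axis=0)
    freqs = np.full(dosages.shape[1], np.nan)
    ok = called > 0
    freqs[ok] = counts[ok] / (2.0 * called[ok])
    return freqs


@dataclass
class ExpressionMatrix:
    """Line x gene expression-level matrix; no missing values permitted."""

    values: np.ndarray
    line_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.line_ids = _check_unique(self.line_ids, "line")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        if len(self.gene_ids) == 0:
            raise ValueError("no features: expression matrix has zero genes")
        if self.values.shape != (len(self.line_ids), len(self.gene_ids)):
            raise ValueError("expression shape does not match ID lists")
        if np.isnan(self.values).any():
            i, j = np.argwhere(np.isnan(self.values))[0]
            raise ValueError(
                f"missing expression value at line {self.line_ids[i]!r}, "
                f"gene {self.gene_ids[j]!r}"
            )

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def subset_lines(self, idx) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return ExpressionMatrix(
            self.values[idx], [self.line_ids[i] for i in idx], list(self.gene_ids)
        )


@dataclass
class StandardizedExpression:
    """Column-standardized expression matrix R (mean 0, sample sd 1 per gene).

    ``means`` and ``sds`` record the statistics used; genes with zero variance
    are dropped and listed in ``dropped_genes``.
    """

    values: np.ndarray
    line_ids: list[str]
    gene_ids: list[str]
    means: np.ndarray
    sds: np.ndarray
    dropped_genes: list[str] = field(default_factory=list)

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class KernelMatrix:
    """Labelled n x n symmetric PSD similarity matrix over lines.

    ``label`` is one of ``"G"`` (VanRaden genomic), ``"E"`` (linear
    expression) or ``"K"`` (Gaussian expression); user-supplied kernels may
    use any label.  ``metadata`` carries constructor details such as the
    VanRaden denominator or the Gaussian bandwidth.
    """

    values: np.ndarray
    line_ids: list[str]
    label: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.line_ids = _check_unique(self.line_ids, "line")
        n = len(self.line_ids)
        if self.values.shape != (n, n):
            raise ValueError("kernel must be square with one row per line ID")

    @property
    def n(self) -> int:
        return len(self.line_ids)

    def check_symmetric(self, tol: float = 1e-8) -> None:
        d = np.max(np.abs(self.values - self.values.T)) if self.n else 0.0
        if d > tol:
            raise ValueError(f"kernel is asymmetric: max |K_ij - K_ji| = {d:.3g}")

    def min_eigenvalue_ratio(self) -> float:
        """Smallest eigenvalue relative to the largest (PSD diagnostic)."""
        w = np.linalg.eigvalsh((self.values + self.values.T) / 2.0)
        top = max(w[-1], np.finfo(float).tiny)
        return w[0] / top

    def subset(self, idx) -> "KernelMatrix":
        idx = np.asarray(idx)
        return KernelMatrix(
            self.values[np.ix_(idx, idx)],
            [self.line_ids[i] for i in idx],
            self.label,
            dict(self.metadata),
        )

    def reorder(self, line_ids: Sequence[str]) -> "KernelMatrix":
        """Reorder to a given ID list; the ID sets must match exactly."""
        target = [str(i) for i in line_ids]
        missing = set(target) - set(self.line_ids)
        extra = set(self.line_ids) - set(target)
        if missing or extra:
            raise ValueError(
                f"kernel line IDs do not match dataset: missing={sorted(missing)}, "
                f"extra={sorted(extra)}"
            )
        pos = {lid: i for i, lid in enumerate(self.line_ids)}
        idx = np.array([pos[lid] for lid in target])
        return self.subset(idx)


@dataclass
class Dataset:
    """Aligned genotype / expression / phenotype bundle over common lines."""

    line_ids: list[str]
    genotypes: GenotypeMatrix | None = None
    expression: ExpressionMatrix | None = None
    phenotypes: pd.DataFrame | None = None

    @classmethod
    def aligned(
        cls,
        genotypes: GenotypeMatrix | None = None,
        expression: ExpressionMatrix | None = None,
        phenotypes: pd.DataFrame | None = None,
    ) -> "Dataset":
        """Intersect line IDs across the supplied components.

        Lines present in one component but not the others are dropped with a
        logged count; ordering follows the first supplied component.
        """
        id_sets = []
        if genotypes is not None:
            id_sets.append(list(genotypes.line_ids))
        if expression is not None:
            id_sets.append(list(expression.line_ids))
        if phenotypes is not None:
            id_sets.append([str(i) for i in phenotypes.index])
        if not id_sets:
            raise ValueError("at least one data component is required")
        common = set(id_sets[0])
        for ids in id_sets[1:]:
            common &= set(ids)
        if not common:
            raise ValueError("no lines shared across components")
        # Deterministic order: sorted IDs, so alignment is a pure function of
        # the ID sets regardless of input ordering.
        line_ids = sorted(common)
        for ids in id_sets:
            dropped = len(ids) - len(common)
            if dropped:
                logger.info("alignment dropped %d lines from a component", dropped)

        geno = expr = None
        if genotypes is not None:
            pos = {lid: i for i, lid in enumerate(genotypes.line_ids)}
            geno = genotypes.subset(line_idx=[pos[lid] for lid in line_ids])
        if expression is not None:
            pos = {lid: i for i, lid in enumerate(expression.line_ids)}
            expr = expression.subset_lines([pos[lid] for lid in line_ids])
        pheno = None
        if phenotypes is not None:
            pheno = phenotypes.copy()
            pheno.index = pheno.index.astype(str)
            pheno = pheno.loc[line_ids]
        return cls(line_ids=line_ids, genotypes=geno, expression=expr, phenotypes=pheno)

    def phenotype(self, trait: str) -> tuple[np.ndarray, list[str]]:
        """Return the trait vector and line IDs, excluding missing records."""
        if self.phenotypes is None:
            raise ValueError("dataset has no phenotypes")
        if trait not in self.phenotypes.columns:
            raise KeyError(
                f"unknown trait {trait!r}; available: {list(self.phenotypes.columns)}"
            )
        col = self.phenotypes[trait]
        keep = col.notna()
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("trait %s: excluded %d lines with missing phenotype", trait, n_drop)
        return col[keep].to_numpy(dtype=float), [str(i) for i in col.index[keep]]
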