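"""Quality filters, mean imputation and expression standardization.

Filter semantics follow the usual call-rate / minor-allele-frequency rules:
a marker is kept when its missing rate is at most ``max_missing`` AND its
MAF = min(p, 1-p) is at least ``min_maf`` (boundaries inclusive).  Lines are
filtered by call rate the same way.  Missing dosages can be replaced by the
per-marker mean dosage 2p (a deliberately simple stand-in for haplotype-based
imputation, which is out of scope).
"""

from __future__ import annotations

import logging

import numpy as np

from .types import ExpressionMatrix, GenotypeMatrix, StandardizedExpression

logger = logging.getLogger("omicblup")

__all__ = [
    "filter_markers",
    "filter_lines",
    "filter_genotypes",
    "impute_mean",
    "standardize_expression",
]


def filter_markers(
    g: GenotypeMatrix, max_missing: float = 0.05, min_maf: float = 0.01
) -> tuple[GenotypeMatrix, dict]:
    """Drop markers by missing rate and minor allele frequency.

    Returns the filtered matrix (frequencies recomputed) and a report with
    counts removed per criterion.  A marker failing both criteria is counted
    under the call-rate criterion.
    """
    if not 0 <= max_missing < 1:
        raise ValueError("max_missing must be in [0, 1)")
    if not 0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    miss_rate = g.mask.mean(axis=0)
    maf = g.maf
    fail_miss = miss_rate > max_missing
    fail_maf = ~fail_miss & ~(np.nan_to_num(maf, nan=-1.0) >= min_maf)
    keep = ~fail_miss & ~fail_maf
    if not keep.any():
        raise ValueError("no markers pass filters")
    report = {
        "markers_removed_callrate": int(fail_miss.sum()),
        "markers_removed_maf": int(fail_maf.sum()),
        "markers_retained": int(keep.sum()),
    }
    logger.info("filter_markers: %s", report)
    return g.subset(marker_idx=np.where(keep)[0]), report


def filter_lines(
    g: GenotypeMatrix, max_missing: float = 0.05
) -> tuple[GenotypeMatrix, dict]:
    """Drop lines whose genotype call rate is below ``1 - max_missing``."""
    if not 0 <= max_missing < 1:
        raise ValueError("max_missing must be in [0, 1)")
    miss_rate = g.mask.mean(axis=1)
    keep = miss_rate <= max_missing
    if not keep.any():
        raise ValueError("no lines pass filters")
    report = {"lines_removed": int((~keep).sum()), "lines_retained": int(keep.sum())}
    logger.info("filter_lines: %s", report)
    return g.subset(line_idx=np.where(keep)[0]), report


def filter_genotypes(
    g: GenotypeMatrix,
    max_missing_line: float = 0.05,
    max_missing_marker: float = 0.05,
    min_maf: float = 0.01,
) -> tuple[GenotypeMatrix, dict]:
    """Standard filtering pipeline: lines first, then markers.

    Frequencies are recomputed after each step, so the marker MAF filter sees
    the post-line-filter allele frequencies.
    """
    g1, rep_lines = filter_lines(g, max_missing_line)
    g2, rep_markers = filter_markers(g1, max_missing_marker, min_maf)
    return g2, {**rep_lines, **rep_markers}


def impute_mean(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing dosage by the marker mean dosage 2p.

    Post-imputation dosages may be non-integer; downstream centering handles
    real-valued dosages.  Preserves per-marker mean dosage exactly.
    """
    no_calls = (~g.mask).sum(axis=0) == 0
    if no_calls.any():
        bad = g.marker_ids[int(np.where(no_calls)[0][0])]
        raise ValueError(f"marker {bad!r} has zero non-missing calls; cannot impute")
    if not g.mask.any():
        return g
    d = g.dosages.copy()
    fill = np.broadcast_to(2.0 * g.freqs, d.shape)
    d[g.mask] = fill[g.mask]
    return GenotypeMatrix.from_dosages(
        d, list(g.line_ids), list(g.marker_ids), mask=np.zeros_like(g.mask)
    )


def standardize_expression(x: ExpressionMatrix) -> StandardizedExpression:
    """Column-standardize expression: r_ij = (x_ij - mean_j) / sd_j.

    The standard deviation uses the sample (n-1) denominator.  Genes with
    zero variance carry no between-line signal and are dropped with a
    warning; they are listed in the result's ``dropped_genes``.
    """
    if x.n_lines < 2:
        raise ValueError("standardization requires at least 2 lines")
    means = x.values.mean(axis=0)
    sds = x.values.std(axis=0, ddof=1)
    keep = sds > 0
    dropped = [g for g, k in zip(x.gene_ids, keep) if not k]
    if dropped:
        logger.warning("standardize_expression: dropped %d constant genes", len(dropped))
    if not keep.any():
        raise ValueError("all genes are constant; nothing to standardize")
    r = (x.values[:, keep] - means[keep]) / sds[keep]
    return StandardizedExpression(
        values=r,
        line_ids=list(x.line_ids),
        gene_ids=[g for g, k in zip(x.gene_ids, keep) if k],
        means=means[keep],
        sds=sds[keep],
        dropped_genes=dropped,
    )
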