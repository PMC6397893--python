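"""Relationship-kernel constructors.

Three kernels drive the prediction models:

* ``G`` — the VanRaden genomic relationship matrix ``ZZ' / (2 Σ p_i (1-p_i))``
  built from allele-frequency-centred dosages;
* ``E`` — the linear expression kernel ``RR'`` on column-standardized
  expression levels;
* ``K`` — the Gaussian kernel ``exp(-||r_i - r_j||^2 / h)`` on the same
  standardized expression, with bandwidth ``h``.

``G`` is invariant to which allele is counted at any marker (swapping labels
flips the sign of the corresponding Z column).  ``E`` is kept unscaled; any
scale difference is absorbed by the corresponding variance component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .types import GenotypeMatrix, KernelMatrix, StandardizedExpression

__all__ = [
    "CenteredGenotypes",
    "center_genotypes",
    "vanraden_g",
    "linear_expression_kernel",
    "gaussian_kernel",
    "mean_squared_distance",
    "default_bandwidth_grid",
]


@dataclass
class CenteredGenotypes:
    """Allele-frequency-centred dosage matrix Z with the frequencies used."""

    Z: np.ndarray
    freqs: np.ndarray
    line_ids: list[str]
    marker_ids: list[str]


def center_genotypes(g: GenotypeMatrix) -> CenteredGenotypes:
    """Centre dosages by twice the allele frequency: Z_ij = d_ij - 2 p_j.

    Homozygotes map to -2p and 2-2p; a heterozygote dosage 1 maps to 1-2p
    (the standard extension; fully inbred panels have none).  Missing calls
    must be imputed first.
    """
    if g.mask.any():
        raise ValueError("genotypes contain missing calls; run impute_mean first")
    Z = g.dosages - 2.0 * g.freqs
    return CenteredGenotypes(Z, g.freqs.copy(), list(g.line_ids), list(g.marker_ids))


def vanraden_g(z: CenteredGenotypes) -> KernelMatrix:
    """VanRaden genomic relationship matrix G = ZZ' / (2 Σ p_j (1 - p_j))."""
    denom = 2.0 * float(np.sum(z.freqs * (1.0 - z.freqs)))
    if denom <= 0:
        raise ValueError("zero denominator: all markers are monomorphic")
    G = (z.Z @ z.Z.T) / denom
    G = (G + G.T) / 2.0
    return KernelMatrix(G, list(z.line_ids), "G", {"denominator": denom})


def linear_expression_kernel(r: StandardizedExpression) -> KernelMatrix:
    """Linear expression kernel E = RR' (unscaled)."""
    E = r.values @ r.values.T
    E = (E + E.T) / 2.0
    return KernelMatrix(E, list(r.line_ids), "E", {"n_genes": r.n_genes})


def gaussian_kernel(r: StandardizedExpression, h: float) -> KernelMatrix:
    """Gaussian kernel K_ij = exp(-||r_i - r_j||^2 / h), diagonal exactly 1.

    ``h`` controls how fast similarity decays with the squared Euclidean
    distance between the standardized expression profiles of two lines.
    """
    if not h > 0:
        raise ValueError("bandwidth h must be strictly positive")
    d2 = squareform(pdist(r.values, metric="sqeuclidean"))
    K = np.exp(-d2 / h)
    np.fill_diagonal(K, 1.0)
    return KernelMatrix(K, list(r.line_ids), "K", {"bandwidth": float(h)})


def mean_squared_distance(r: StandardizedExpression) -> float:
    """Mean pairwise squared Euclidean distance between line profiles."""
    d2 = pdist(r.values, metric="sqeuclidean")
    if d2.size == 0:
        raise ValueError("need at least two lines")
    return float(d2.mean())


def default_bandwidth_grid(r: StandardizedExpression, n: int = 13) -> list[float]:
    """Data-adaptive log-spaced bandwidth grid from 0.1 to 100 x the mean
    pairwise squared distance of the standardized expression profiles."""
    d = mean_squared_distance(r)
    return list(np.geomspace(0.1 * d, 100.0 * d, n))
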