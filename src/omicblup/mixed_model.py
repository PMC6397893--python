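"""REML variance components, BLUP prediction and heritability estimators.

The models are linear mixed models with an intercept as the only fixed
effect and one or two kernel-structured random line effects:

    y = 1 mu + sum_k u_k + e,   u_k ~ N(0, sigma_k^2 K_k),  e ~ N(0, sigma_e^2 I)

so V = sum_k sigma_k^2 K_k + sigma_e^2 I.  Variance components are estimated
by restricted maximum likelihood with average-information updates and an
EM fallback whenever an AI step would leave the feasible region or decrease
the restricted log-likelihood.  Components are kept non-negative by
projection onto a small positive floor; estimates pinned at the floor are
reported with a boundary flag rather than dropped and refit.

Model vocabulary: GBLUP uses the genomic kernel G; TBLUP the linear
expression kernel E; RKHS the Gaussian expression kernel K; GTBLUP combines
G + E and GRBLUP combines G + K.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg

from .types import Dataset, KernelMatrix

logger = logging.getLogger("omicblup")

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "FitResult",
    "HeritabilityEstimate",
    "reml_fit",
    "blup_predict",
    "heritability",
    "build_model_kernels",
    "MODEL_KERNELS",
]

MODEL_KERNELS: dict[str, tuple[str, ...]] = {
    "gblup": ("G",),
    "tblup": ("E",),
    "rkhs": ("K",),
    "gtblup": ("G", "E"),
    "grblup": ("G", "K"),
}


@dataclass(frozen=True)
class ModelSpec:
    """A named prediction model and the ordered kernel labels it uses."""

    name: str
    kernels: tuple[str, ...]

    @classmethod
    def from_name(cls, name: str) -> "ModelSpec":
        key = name.lower()
        if key not in MODEL_KERNELS:
            raise ValueError(
                f"unknown model {name!r}; valid models: {sorted(MODEL_KERNELS)}"
            )
        return cls(key, MODEL_KERNELS[key])

    @property
    def needs_bandwidth(self) -> bool:
        return "K" in self.kernels


@dataclass
class VarianceComponents:
    """Per-kernel variances plus the residual variance (trait units squared)."""

    components: dict[str, float]
    residual: float

    @property
    def total(self) -> float:
        return sum(self.components.values()) + self.residual


@dataclass
class FitResult:
    """Converged (or flagged) REML fit for one trait and model."""

    mu: float
    varcomp: VarianceComponents
    blups: dict[str, np.ndarray]
    loglik: float
    iterations: int
    converged: bool
    boundary: dict[str, bool]
    kernel_labels: tuple[str, ...]
    line_ids: list[str]
    y: np.ndarray = field(repr=False, default=None)


@dataclass
class HeritabilityEstimate:
    """A variance-ratio heritability and the component sums that formed it.

    ``kind`` is ``hG2`` (SNP-based narrow sense, G only), ``HGT2`` (G + linear
    expression kernel), ``HGR2`` (G + Gaussian expression kernel) or ``Ho2``
    (general omics-augmented form with any non-G components summed).
    """

    kind: str
    value: float
    components: dict[str, float]


# ---------------------------------------------------------------------------
# REML core


def _loglik_state(y, Ks, theta, n):
    """Evaluate restricted log-likelihood and the projection pieces at theta.

    Returns (loglik, P, Py) with P the REML projection matrix for an
    intercept-only design.
    """
    V = theta[-1] * np.eye(n)
    for t, K in zip(theta[:-1], Ks):
        V += t * K
    try:
        c, low = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return None
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(c))))
    Vinv = linalg.cho_solve((c, low), np.eye(n), check_finite=False)
    a = Vinv.sum(axis=1)              # V^{-1} 1
    xvx = float(a.sum())              # 1' V^{-1} 1
    if xvx <= 0:
        return None
    P = Vinv - np.outer(a, a) / xvx
    Py = P @ y
    ll = -0.5 * (logdet_v + np.log(xvx) + float(y @ Py))
    return ll, P, Py, Vinv, a, xvx


def reml_fit(
    y: np.ndarray,
    kernels: KernelMatrix | Sequence[KernelMatrix],
    *,
    max_iter: int = 200,
    tol_loglik: float = 1e-6,
    tol_param: float = 1e-5,
) -> FitResult:
    """Estimate variance components by average-information REML.

    Parameters
    ----------
    y
        Phenotype vector; must have positive variance.
    kernels
        One or two :class:`KernelMatrix` objects over the same lines, in the
        model's kernel order (e.g. ``[G]`` for GBLUP, ``[G, K]`` for GRBLUP).

    Notes
    -----
    All components are initialised at ``var(y) / (n_kernels + 1)``.  An AI
    update is attempted each iteration; if it leaves the feasible region or
    fails to improve the restricted log-likelihood after step-halving, an EM
    update is used instead.  Convergence requires both the log-likelihood
    change below ``tol_loglik`` and the maximum relative parameter change
    below ``tol_param``.
    """
    if isinstance(kernels, KernelMatrix):
        kernels = [kernels]
    kernels = list(kernels)
    if not 1 <= len(kernels) <= 2:
        raise ValueError("reml_fit supports one or two kernels")
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 observations")
    vary = float(np.var(y, ddof=1))
    if vary <= 0:
        raise ValueError("zero phenotypic variance")
    labels = tuple(k.label for k in kernels)
    ids0 = kernels[0].line_ids
    Ks = []
    for k in kernels:
        if k.n != n:
            raise ValueError("kernel dimension does not match phenotype length")
        if k.line_ids != ids0:
            raise ValueError("kernels must share identical line ordering")
        k.check_symmetric(tol=1e-8)
        r = k.min_eigenvalue_ratio()
        if r < -1e-6:
            raise ValueError(
                f"kernel {k.label} is not positive semidefinite "
                f"(min/max eigenvalue ratio {r:.2e})"
            )
        Ks.append((k.values + k.values.T) / 2.0)

    n_par = len(Ks) + 1
    floor = 1e-8 * vary
    theta = np.full(n_par, vary / n_par)
    state = _loglik_state(y, Ks, theta, n)
    if state is None:
        raise ValueError("likelihood evaluation failed at initialization")
    ll = state[0]
    converged = False
    it = 0
    n_flat = 0  # consecutive iterations with negligible loglik change
    for it in range(1, max_iter + 1):
        _, P, Py, _, _, _ = state
        # scores and average-information matrix
        W = np.empty((n, n_par))
        trPK = np.empty(n_par)
        for k, K in enumerate(Ks):
            W[:, k] = K @ Py
            trPK[k] = float(np.sum(P * K))
        W[:, -1] = Py
        trPK[-1] = float(np.trace(P))
        score = -0.5 * (trPK - W.T @ Py)
        PW = P @ W
        AI = 0.5 * (W.T @ PW)

        theta_new = None
        state_new = None
        try:
            delta = np.linalg.solve(AI, score)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(AI, score, rcond=None)[0]
        if not np.all(np.isfinite(delta)):
            delta = None
        if delta is not None:
            step = 1.0
            for _ in range(8):
                cand = np.maximum(theta + step * delta, floor)
                cs = _loglik_state(y, Ks, cand, n)
                if cs is not None and cs[0] >= ll - 1e-10:
                    theta_new, state_new = cand, cs
                    break
                step *= 0.5
        if theta_new is None:
            # EM fallback: guaranteed uphill for interior components
            cand = theta + (theta**2 / n) * (W.T @ Py - trPK)
            cand = np.maximum(cand, floor)
            cs = _loglik_state(y, Ks, cand, n)
            if cs is None or cs[0] < ll - 1e-10:
                # no admissible improvement; stop at current point
                converged = True
                break
            theta_new, state_new = cand, cs

        ll_new = state_new[0]
        rel = np.max(np.abs(theta_new - theta) / np.maximum(theta, floor))
        n_flat = n_flat + 1 if abs(ll_new - ll) < tol_loglik else 0
        # parameters may keep sliding along a flat ridge when components are
        # unidentifiable; persistent loglik stagnation also counts as converged
        done = (n_flat >= 1 and rel < tol_param) or n_flat >= 3
        theta, state, ll = theta_new, state_new, ll_new
        if done:
            converged = True
            break

    if not converged:
        logger.warning("REML did not converge in %d iterations", max_iter)

    _, P, Py, Vinv, a, xvx = state
    mu = float(a @ y) / xvx
    resid = y - mu
    v_resid = Vinv @ resid
    blups = {
        lab: th * (K @ v_resid) for lab, th, K in zip(labels, theta[:-1], Ks)
    }
    boundary = {lab: bool(th <= floor * 4.0) for lab, th in zip(labels, theta[:-1])}
    boundary["residual"] = bool(theta[-1] <= floor * 4.0)
    varcomp = VarianceComponents(
        components={lab: float(th) for lab, th in zip(labels, theta[:-1])},
        residual=float(theta[-1]),
    )
    logger.info(
        "REML fit kernels=%s: loglik=%.6f iters=%d converged=%s components=%s "
        "residual=%.4g",
        labels, ll, it, converged, varcomp.components, varcomp.residual,
    )
    return FitResult(
        mu=mu,
        varcomp=varcomp,
        blups=blups,
        loglik=float(ll),
        iterations=it,
        converged=converged,
        boundary=boundary,
        kernel_labels=labels,
        line_ids=list(ids0),
        y=y.copy(),
    )


def blup_predict(
    fit: FitResult,
    full_kernels: Sequence[KernelMatrix],
    train_idx: np.ndarray,
    test_idx: np.ndarray,
) -> np.ndarray:
    """Predict genetic values for held-out lines from a train-only fit.

    For each kernel the held-out random effect is the cross-block BLUP
    ``u_test = sigma_k^2 K[test, train] V_train^{-1} (y_train - 1 mu)``; the
    predicted genetic value is ``mu + sum_k u_test``.  Equivalent to solving
    Henderson's mixed-model equations with the test records unobserved; no
    refit on the test lines is performed.
    """
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)
    full_kernels = list(full_kernels)
    if tuple(k.label for k in full_kernels) != fit.kernel_labels:
        raise ValueError("kernel labels/order do not match the fit")
    n_tr = train_idx.size
    V = fit.varcomp.residual * np.eye(n_tr)
    for k in full_kernels:
        V += fit.varcomp.components[k.label] * k.values[np.ix_(train_idx, train_idx)]
    resid = fit.y - fit.mu
    alpha = linalg.solve(V, resid, assume_a="pos")
    pred = np.full(test_idx.size, fit.mu)
    for k in full_kernels:
        cross = k.values[np.ix_(test_idx, train_idx)]
        pred += fit.varcomp.components[k.label] * (cross @ alpha)
    return pred


def heritability(fit: FitResult, kind: str | None = None) -> HeritabilityEstimate:
    """Variance-ratio heritability matching the fitted model.

    For a G-only fit this is the SNP-based narrow-sense heritability
    ``hG2 = sg2 / (sg2 + se2)``; for G plus a linear expression kernel
    ``HGT2 = (sg2 + st2) / (sg2 + st2 + se2)``; for G plus a Gaussian kernel
    the analogous ``HGR2``.  The general omics-augmented broad-sense form
    ``Ho2`` sums every non-G component into the omics variance; it reduces
    exactly to ``hG2`` when the omics variance is zero.
    """
    comps = fit.varcomp.components
    sg = comps.get("G", 0.0)
    omics = sum(v for lab, v in comps.items() if lab != "G")
    se = fit.varcomp.residual
    if sg + omics + se <= 0:
        raise ValueError("all variance components are zero; heritability undefined")
    if kind is None:
        if fit.kernel_labels == ("G",):
            kind = "hG2"
        elif fit.kernel_labels == ("G", "E"):
            kind = "HGT2"
        elif fit.kernel_labels == ("G", "K"):
            kind = "HGR2"
        else:
            kind = "Ho2"
    value = (sg + omics) / (sg + omics + se)
    used = {"genomic": sg, "omics": omics, "residual": se}
    return HeritabilityEstimate(kind=kind, value=float(value), components=used)


def build_model_kernels(
    dataset: Dataset, spec: ModelSpec, bandwidth: float | None = None
) -> list[KernelMatrix]:
    """Construct the kernels a model needs from a dataset's predictors.

    Genotypes are mean-imputed, centred and turned into the VanRaden G;
    expression is column-standardized and turned into the linear kernel E or
    the Gaussian kernel K (``bandwidth`` required for K; defaults to the mean
    pairwise squared distance of the standardized profiles).
    """
    from . import kernels as _k
    from . import preprocess as _pp

    out: list[KernelMatrix] = []
    r = None
    for lab in spec.kernels:
        if lab == "G":
            if dataset.genotypes is None:
                raise ValueError(f"model {spec.name} needs genotypes")
            g = _pp.impute_mean(dataset.genotypes)
            out.append(_k.vanraden_g(_k.center_genotypes(g)))
        else:
            if dataset.expression is None:
                raise ValueError(f"model {spec.name} needs expression data")
            if r is None:
                r = _pp.standardize_expression(dataset.expression)
            if lab == "E":
                out.append(_k.linear_expression_kernel(r))
            elif lab == "K":
                h = bandwidth if bandwidth is not None else _k.mean_squared_distance(r)
                out.append(_k.gaussian_kernel(r, h))
            else:
                raise ValueError(f"unknown kernel label {lab!r}")
    return out
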