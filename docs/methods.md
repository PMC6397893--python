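# Methods

## Model

All five prediction models are Gaussian linear mixed models over n inbred
lines with the intercept as the only fixed effect:

    y = 1μ + Σ_k u_k + e,   u_k ~ N(0, σ²_k K_k),   e ~ N(0, σ²_e I)

so that V = Σ_k σ²_k K_k + σ²_e I with one kernel (GBLUP, TBLUP, RKHS) or
two (GTBLUP = G + E, GRBLUP = G + K). Because every line contributes one
record and the only fixed effect is the mean, the restricted likelihood has
the closed form

    ℓ_R = −½ [ log|V| + log(1′V⁻¹1) + y′Py ],
    P = V⁻¹ − V⁻¹1 (1′V⁻¹1)⁻¹ 1′V⁻¹.

### Kernels

* **G** (VanRaden): Z holds dosages centred by twice the allele frequency;
  G = ZZ′ / 2Σ p(1−p). Heterozygote dosage 1 maps to 1−2p (the standard
  extension; fully inbred panels contain none, and the diagonal of G then
  sits near 2). G is invariant to which allele is counted at any marker —
  swapping labels flips the sign of one Z column — so VCF alternate-allele
  orientation is immaterial; this is covered by a test.
* **E** = RR′ on column-standardized expression (sample sd, n−1
  denominator; the choice only rescales E by a constant that σ²_t absorbs).
  E is not trace-normalized; under the n−1 convention trace(E) = (n−1)·m.
* **K**: Gaussian, K_ij = exp(−‖r_i−r_j‖²/h) with the squared Euclidean
  distance *divided* by the bandwidth. The division convention is the only
  one under which the empirically useful bandwidth range (from well below
  to well above the mean squared profile distance) produces non-degenerate
  kernels when profiles have thousands of standardized coordinates. The
  diagonal is set to exactly 1.

Constant expression columns carry no between-line information and are
dropped (with a report) before standardization. Missing dosages are
replaced by the per-marker mean 2p — a deliberately simple stand-in for
haplotype-based imputation, which preserves marker means exactly and whose
continuous output the centering handles.

## REML

Variance components are estimated by average-information (AI) REML:

* score_k = −½ (tr(P K_k) − y′P K_k P y); AI_jk = ½ y′P K_j P K_k P y.
* The AI step is accepted only if it stays in the feasible region and does
  not decrease ℓ_R; otherwise the step is halved (up to 8 times) and, if
  that fails, an EM update σ²_k ← σ²_k + σ⁴_k (y′P K_k P y − tr(P K_k))/n
  is used.
* Components are kept non-negative by projection onto a small floor
  (1e−8 · var(y)); an estimate pinned there is reported with a boundary
  flag rather than dropped and refit, and heritabilities use the pinned
  values.
* Initialization: every component at var(y)/(n_kernels + 1) — symmetric,
  scale-aware, reproducible. Likelihood evaluation uses one Cholesky of V
  per evaluation; kernels are symmetrized and checked PSD (smallest
  eigenvalue ≥ −1e−6 of the largest) on entry.
* Convergence: |Δℓ_R| < 1e−6 together with a maximum relative parameter
  change < 1e−5, within 200 iterations. When components are unidentifiable
  (e.g. two identical kernels, or K ≈ I confounded with the residual) the
  parameters can slide along a flat likelihood ridge forever, so three
  consecutive iterations of negligible ℓ_R change also count as converged —
  any point on such a ridge is a restricted-likelihood maximum. For two
  exchangeable kernels only the component sum is identified; the fit
  converges and the sum matches the single-kernel fit (tested).

The fitted model is scale-equivariant: fitting c·y multiplies every
component by c² and leaves heritabilities and predictive abilities
unchanged (tested at c = 3 to 1e−8).

### Prediction

Held-out lines are predicted from the train-only fit through kernel
cross-blocks: û_test = σ̂²_k K_k[test,train] V̂_train⁻¹ (y_train − 1μ̂),
prediction = μ̂ + Σ_k û_test. This equals solving Henderson's mixed-model
equations with the test records unobserved (tested against that oracle);
no refit touches test lines, and kernels are built once from all lines'
predictors — genotype and expression are predictors, not responses, so no
phenotype information leaks.

### Heritability

h²G = σ²g/(σ²g+σ²e) for the G-only model; H²GT and H²GR add the expression
component to numerator and denominator; the general omics-augmented form
H²o sums every non-G component and reduces exactly to h²G when the omics
variance is zero.

## Evaluation protocol

20 replicates of 5-fold cross-validation by default; each replicate is a
uniformly random partition with fold sizes differing by at most one, drawn
from a per-replicate stream `SeedSequence([master_seed, replicate])`, so
identical seeds give bit-identical results and all models share fold plans
(paired comparisons). One Pearson correlation is computed per test fold
(reps × k values; their mean is the reported predictive ability). Folds
with constant predictions have undefined correlations and are excluded
with a logged count, as are non-convergent fits.

Bandwidth search evaluates each grid value on the same fold plans and
returns the maximizer (ties to the smaller h). The default grid is
log-spaced over 0.1–100 × the mean pairwise squared distance of the
standardized profiles. The selected bandwidth is then reported on the same
folds it was selected on — a mildly optimistic protocol, stated here
because the alternative (nested CV) answers a different, more expensive
question.

Tukey's HSD treats the reps × k values per model as a one-way layout
(statsmodels' studentized-range implementation behind this module's
surface; an independent SciPy implementation cross-checks it in the
tests). The values within a panel share fold plans and one phenotype draw,
so they are positively dependent; the test is therefore indicative rather
than exact, and the calibration check described below accounts for the
dependence explicitly.

## Synthetic panels

The generator emulates a fully inbred reference panel: per marker an
allele frequency q ~ U[0.05, 0.5]; each line homozygous carrier with
probability q (dosages {0,2}; no linkage disequilibrium — unnecessary for
testing the estimators). Gene j's expression is Σ effects·centred dosages
over its causal markers, plus Σ effects·(products of centred dosages) over
its epistatic marker pairs, plus N(0, 1) noise (defaults: 5 cis markers, 2
pairs, unit effect scales). The product encoding is the point: a product of
centred dosages at independent loci is uncorrelated with every single
dosage, hence invisible to the additive kernel G but expressible through
expression kernels.

Phenotypes are additive (centred dosages × normal marker effects) +
mediated (standardized expression × normal gene effects) + residual, with
each term centred, made empirically orthogonal to its predecessors, and
rescaled so realized variance shares equal their targets exactly (default
0.40 / 0.30 / 0.30, inside the heritability range such panels show). The
orthogonalized rescaling slightly distorts effect-size distributions; in
exchange, estimators are judged against exact truth.

What passing tests on these panels do *not* show: robustness to linkage
disequilibrium, array-noise structure, sex-stratified architectures, or
expression measured far from the trait-relevant tissue/time. They show the
estimators and the evaluation machinery are correct under the model's own
assumptions.

## Test-design notes

* The brute-force REML oracle maximizes the closed-form ℓ_R on a dense
  200×200 grid over (0, 3·var(y)]²; since a single pass quantizes the
  variance ratio at ~1.5e−2, the fine agreement check re-grids around the
  running argmax (three zoom passes, still pure evaluation). Measured
  agreement with AI-REML: ~1e−6 on the ratio.
* Variance-component recovery under the two-kernel generative model uses a
  generative bandwidth of 0.5 × the mean squared expression distance. The
  Gaussian kernel's spectrum is informative there (effective rank ~45 at
  n = 400); at much larger h it degenerates toward the constant matrix
  (absorbed by the intercept), at much smaller h toward the identity
  (confounded with the residual), and σ²_v would be unidentifiable for any
  estimator.
* Null calibration: within one panel, all CV abilities share a single
  phenotype draw, and the realized alignment between that draw and the
  kernel's leading eigenvectors offsets every fold together (±0.15 at
  n = 120). The null check therefore averages over independent panels and
  computes the standard error across panel means.
* Problem sizes in the tests (panels of 30–400 lines, hundreds of markers
  and genes, a handful of CV replicates) are chosen so the full suite is a
  few minutes of single-core compute while every check retains the power
  it needs; the power calculations are noted beside the tests they size.

## Known limitations

* Only an intercept is supported as a fixed effect (matching the models
  the package implements); covariates must be pre-adjusted.
* No standard errors on heritabilities; boundary estimates make their
  sampling distribution non-standard, and resampling is out of scope.
* Mean imputation ignores linkage; panels with substantial missingness
  deserve a haplotype-aware imputer upstream.
* The VCF reader handles the minimal biallelic GT-only dialect, not the
  full specification.
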