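# Methods

## Mixed model and REML

The working model is `y = Xβ + Zu + e` with `u ~ N(0, A σ²_a)`, `A = 2K` on
the VanRaden scale, and `e ~ N(0, I σ²_e)`.  `X` always carries an intercept;
genotype principal components can be appended as fixed covariates (off by
default — with an intercept-only model any constant shift of the phenotype
moves only β̂, never û).  Missing phenotypes are dropped row-wise from `y`,
`X` and the incidence map; they are never imputed.

Writing δ = σ²_e/σ²_a, the covariance of the observed phenotypes is
σ²_a·H with H = Z·A·Z′ + δI.  One symmetric eigendecomposition of Z·A·Z′
(eigenvalues clipped at zero against round-off) turns the restricted
likelihood into a one-dimensional function of δ: for each δ the GLS fixed
effects, the residual quadratic form and the profiled
σ̂²_a = r′H⁻¹r/(n−q) come from vector operations in the rotated basis.  The
restricted log-likelihood is

```
l_R(δ) = −½[(n−q)·log(2π σ̂²_a) + (n−q) + log|H| + log|X′H⁻¹X| − log|X′X|]
```

with `q` the column rank of `X` (validated; a rank-deficient `X` is
rejected).  δ is maximized on a 100-point logarithmic grid over
[1e−5, 1e5] followed by bounded scalar minimization in the best bracket
(tolerance 1e−6 on log δ).  If the profile is flat to within 1e−6 — the
case when `A` is (proportional to) the identity, where the likelihood
depends on σ²_a and δ only through σ²_a(1+δ) — the fit is flagged
non-identifiable and the smallest δ in the domain is reported; a boundary
optimum is flagged the same way.  Heritability is reported as
σ̂²_a/(σ̂²_a+σ̂²_e) = 1/(1+δ̂), which is calibrated for the 2K kinship
normalization.

Fixed effects and BLUPs solve Henderson's equations; predictions for levels
without phenotypes (inference individuals, or groups containing none) use
the equivalent conditional form û = A Z′H⁻¹(y − Xβ̂) over the joint
relationship matrix, which coincides with the joint mixed-model-equation
solution and leaves reference BLUPs unchanged.  When `A` must be inverted
explicitly (the Henderson path) and is near-singular — pseudo-QTN kinship
from very few markers can be rank-deficient — a ridge of 1e−6·mean(diag A)
is added first; this preserves solutions to roughly five decimals while
guaranteeing solvability.

## Kinship

`2K = WW′/(2Σ pᵢ(1−pᵢ))`, where `pᵢ` is half the mean dosage of marker `i`
over non-missing calls and `W` is the column-centred dosage matrix.  Missing
dosages are centred to zero (mean imputation), which is unbiased with
respect to allele frequency.  Monomorphic markers contribute zero to both
numerator and denominator, so appending them never changes the matrix; a
fully monomorphic marker set is an error.  Allele frequencies are always
computed on the full individual set passed in (reference plus inference),
since kinship is built on everyone before any phenotype masking.

## SUPER BLUP

A single-marker mixed-model scan runs once on the reference individuals with
δ fixed from the marker-free null model (P3D): phenotype, covariates and
every marker are whitened by H^{-1/2} and each marker is tested by an
ordinary t-test (df = n−q−1) after projecting out the fixed effects.
Monomorphic or covariate-collinear markers receive p = 1.

Bins are half-open intervals [k·s, (k+1)·s) per chromosome on 1-based
positions.  Each non-empty bin is represented by its smallest-p marker (ties
to the smaller position); representatives are ranked by p (ties to genome
order) and the top `t` form the pseudo-QTN set, returned in genome order.
For each grid cell (s, t) the pseudo-QTN kinship is rebuilt and a full REML
fit re-estimates δ; the cell with the highest restricted likelihood wins,
ties resolving to smaller `t` then smaller `s`.  Default grids are
s ∈ {5·10⁴, 10⁵, 5·10⁵, 10⁶, 5·10⁶} bp and t ∈ {5, 10, 20, 50, 100, 200}
capped at m/10 — wide enough to span Mendelian to polygenic architectures at
the package's standard population sizes.  No LD-exclusion step is applied:
every selected marker enters the kinship, and forcing the pseudo-QTN set to
all markers reproduces gBLUP exactly.  The scan is run once per fit; there
is no re-iteration of the scan under the optimized kinship.

For a fixed `t` the number of distinct selected bins is non-increasing in
`s` only along nested bin-size sequences (s, 2s, 4s, ...); for arbitrary
size pairs the fixed bin origin can split a pair of markers that a smaller
size kept together (positions 550 and 650 share bin 1 at s = 400 but split
at s = 600).  The property is therefore stated — and tested — on doubling
sequences.

## Compressed BLUP

Individuals are clustered on `d(i,j) = max(K) − K_ij` with average linkage
(UPGMA; complete and Ward are options), using the kinship of all
individuals whether phenotyped or not.  The tree is cut into exactly `g`
groups; group labels follow first occurrence in individual order so results
are deterministic.  The group relationship matrix block-averages the
individual matrix; a group's self-relationship averages its full within
block including the diagonal, which makes the g = n grouping an exact
identity and keeps the matrix positive semi-definite (it is a congruence
transform of `K`).

`g` is selected by restricted likelihood over a geometric grid from 2 to n
with at most 30 levels, n always included (the likelihood at g = n equals
the gBLUP likelihood, so the optimized −2LL can never exceed gBLUP's).
g = 1 is excluded — a single group's BLUP is confounded with the overall
mean.  Likelihood ties resolve toward larger g, i.e. toward gBLUP.  Each
individual inherits its group's BLUP plus the fixed-effect part; groups
containing only unphenotyped individuals are predicted through their
kinship with the phenotyped groups.

A combined compressed-SUPER run (clustering on pseudo-QTN kinship) is
possible by passing a `SuperFit` kinship into `optimize_compression`; the
two optimizations are not run jointly.

## Simulator

Founder haplotypes are drawn at Hardy–Weinberg equilibrium with per-marker
allele frequencies uniform on (0.1, 0.9); each family has two independent
parents and produces full sibs by Mendelian transmission, with a gamete
switching parental strands between adjacent markers with probability 0.01.
Defaults: 80 families × 5 sibs (n = 400), 3000 markers on one 10⁸ bp
chromosome, positions uniform.  Traits sample a chosen number of QTNs
uniformly without replacement, draw standard-normal effects, multiply raw
(uncentred) dosages — any constant shift is absorbed by the intercept — and
add Gaussian residuals whose variance is set from the *observed*
breeding-value variance so the realized genetic fraction of the total
variance equals the target heritability; h² = 1 gives identically zero
residuals.  One master seed is split into independent streams for marker
map, founders, meiosis, QTN sampling, effects and residuals.

What the simulator does not emulate: population-level linkage
disequilibrium beyond sib-sharing (recombination acts per adjacent-marker
interval, not per bp), relatedness between families, selection, dominance
or epistasis, and multi-chromosome maps.  Passing tests on these data show
that the estimators recover what this generative model encodes — family
structure, architecture-dependent method ranking, heritability — not that
they reproduce any particular real population.

## Evaluation protocol

Five-fold cross-validation: individuals are randomly partitioned (sizes
differ by at most one); each fold in turn is the inference set whose
phenotypes are masked before any model step that touches `y` (for sBLUP the
scan and the (s, t) optimization re-run per fold on the reference only; for
cBLUP clustering uses everyone's genotypes but only reference phenotypes
enter the likelihood).  Accuracy is the Pearson correlation between
predictions and observed phenotypes of the inference fold — the
paper-compatible definition — averaged over folds per replicate and
reported as mean ± SE over replicates; for simulated traits the correlation
with true breeding values and the OLS slope of predictions on true breeding
values (shrinkage; below one for BLUP) are reported alongside.  Folds with
zero-variance predictions or observations are flagged and excluded from the
mean.  Replicates default to 10 at desk scale (configurable), and every
random choice descends from one master seed.

## Default study scales and known limitations

End-to-end checks run at n = 400–500 and m = 3000 with 10–20 replicate
traits, the package's standard study conditions.  At these scales:

* The kinship-source ordering (true QTNs ≥ pseudo-QTNs ≥ true QTNs + 1000
  non-QTN markers ≥ all markers) holds on mean CV accuracy pooled over
  h² ∈ {0.25, 0.5, 0.75} for 10-QTN traits.
* sBLUP's advantage over gBLUP is large and stable for few-QTN,
  high-heritability traits.
* Likelihood-guided compression is only as good as the likelihood surface:
  on deep families (40 × 10 sibs) at h² = 0.1 cBLUP matches gBLUP, and its
  −2LL profile peaks at an interior group number in most replicates at
  h² ≈ 0.2; on shallow families (80 × 5) at h² = 0.1 the per-fold selection
  of g is noisy enough that cBLUP can trail gBLUP by a few hundredths of
  accuracy.  Compression experiments therefore default to the deep-family
  population.
* The estimators' inductive `predict` on genotypes unseen at fit time
  rebuilds the joint kinship (and, for cBLUP, re-clusters at the fitted g
  and refits δ on reference phenotypes); the transductive protocol —
  unphenotyped rows passed with NaN y at fit time — is the primary,
  paper-style path and is what the CV harness uses.

Single-trait, single-variance-component models only; no prediction error
variances or reliabilities; no pedigree parsing (a pedigree-derived matrix
can be supplied as a `KinshipMatrix`); no VCF/PLINK readers (numeric TSV
and HapMap text only).
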