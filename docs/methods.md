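# Methods

This note documents the statistical models, the numerical choices and the
limits of what the synthetic experiments can show.

## Regularised CCA

Given centered views `X (n×p)` and `Y (n×q)`, the solver maximises
`u' C_xy v` subject to `u' M_x u = 1` and `v' M_y v = 1`, where
`M_x = (1-c_x) C_xx + c_x I` and covariances use an `n-1` divisor.
Centering happens within the fitting set only; holdout projections use the
training means (Pearson correlations are translation invariant, so this
only matters for deflation consistency).

Numerically, each view is reduced by an economy SVD `X = U S V'`; singular
values below `1e-10 ×` the largest are treated as zero.  In this basis
`M_x` is diagonal, and the problem reduces to the SVD of the whitened
cross-covariance `D_x^{-1/2} S_x U_x'U_y S_y D_y^{-1/2}/(n-1)` with
`D = (1-c) S²/(n-1) + c`.  Weights therefore always lie in the row space
of the training data — exact for `c > 0` and the canonical minimum-norm
solution at `c = 0` — and the cost scales with `n` even when `p ≫ n`.
At `c = 0` the solution coincides with classical CCA (verified against an
independent dense generalised-eigenvalue oracle), at `c = 1` with the SVD
of the cross-covariance (PLS limit).

Sign indeterminacy: `(u, v)` and `(−u, −v)` are the same model.  Each
fitted model is oriented so the behavioural loading of largest magnitude
on the training set is positive; split results are additionally aligned
to the first split by the sign of the concatenated loading dot product
before averaging.  The reported canonical correlation is always the plain
Pearson correlation of the scores, not the singular value of the
regularised problem.

Deflation is projection deflation per view: `X ← X − s (s'X)/(s's)` with
`s = Xu`, which guarantees `X_deflated · u = 0` on the deflating set and
orthogonal successive scores there.  Out-of-sample rows are deflated with
the row-space direction estimated on the optimisation set, keeping the
holdout leakage-free.

## Multiple-holdout framework

Splits are drawn at the family level: families are shuffled and added to
the holdout side until the target participant fraction (20%, then 20% of
the optimisation set for inner test sets) is met as closely as family
sizes allow; a family larger than the target is an error.  Five outer and
five inner splits are independent random draws, all derived
deterministically from the master seed.

Preprocessing order is fixed: participant-wise brain-size normalisation
(GMV by the TIV analogue, CT by mean CT, SA by total SA) first, then OLS
residualisation of age, gender and optional site dummies.  Within
`run_framework` the residualisation is estimated on each outer split's
optimisation set and applied unchanged to its holdout set.  (The
standalone `fit_preprocess` / `apply_preprocess` operations support any
fit/apply slices, e.g. per inner split; fitting at the optimisation level
keeps deflation well defined across the inner loop while still
guaranteeing that holdout rows never influence the model — a property the
test suite enforces with a poisoning sentinel.)

Hyperparameter selection uses two criteria per grid cell: the mean
inner-test correlation and the mean pairwise Pearson similarity of
weights across inner-split models (sign-aligned to the first model; u and
v similarities averaged).  The published selection rule states only that
the combination with the highest test correlation and stability is taken;
as a concrete, weighting-free realisation the cells are ranked separately
on each criterion and the best average rank wins, ties broken toward
larger `c_x + c_y`.  The default grid `{0, 0.3, 0.6, 0.9, 0.99, 1}` per
view is log-dense near 1 where high-dimensional views need shrinkage.
Models are never averaged across splits — only loadings and scores are.

Scores for downstream genetics are the per-split full-data projections
averaged over splits and standardised; because selection effects can
inflate heritability, a holdout-only variant (scores from the splits in
which the participant was held out; undefined for participants never held
out under the independent random splits) is provided as a sensitivity
pair.

## Permutation inference

Families are exchangeability blocks.  A valid permutation (a) permutes
whole blocks only among blocks with identical composition signatures (the
multiset of member types MZ/DZ/non-twin) and (b) permutes members within
a block only within member type; MZ and DZ members are deliberately
distinct types.  For all-singleton samples this is a uniform permutation
(verified by a chi-square uniformity test); for two MZ-pair families plus
a singleton the valid orbit has exactly 8 elements (verified by
enumeration).  Optimisation and holdout rows are permuted independently.
Hyperparameters stay frozen at their selected values under permutation.

The p-value counts strictly greater null correlations (ties favour the
observed statistic; a `geq` rule is available), divided by the number of
permutations and floored at `1/n_perm`, so the smallest reportable
corrected p at 1000 permutations and 5 splits is 0.005.  An unbiased
`(count+1)/(n_perm+1)` estimator is available as a config option and is
the right choice for calibration studies at small permutation counts: with
the floor estimator and strict inequality, a corrected p below 0.05 is
unreachable at 100 permutations, so type-I-error experiments use
`add_one`.  The omnibus decision rejects when the minimum corrected p is
strictly below α.

## Spin test

Surface parcel centroids live on each hemisphere's unit sphere with the
right hemisphere mirroring the left.  Each spin applies a uniform random
rotation to the left hemisphere and its mirror conjugate to the right,
then reassigns values by nearest original centroid (lowest index on ties;
duplicates permitted).  The rotated map is the loading map; reference
maps stay fixed.  The exceedance rule is two-sided on magnitude
(`|r_null| ≥ |r_obs|`) so that strong negative similarities are
detectable; the literal one-sided rule is a config option.  Volumetric
blocks are never spin-tested.  Cross-cohort comparison of two result
lists corrects over the full family `n_dims_a × n_dims_b × 3` (behaviour,
CT, SA).

## AE variance decomposition

The kinship matrix `2Φ` uses the coefficient universe {self 1, MZ 1,
DZ/full-sibling 0.5, unrelated 0} and is block-diagonal by family.  Each
family block is eigendecomposed once; in the rotated basis the univariate
covariance is diagonal and the bivariate covariance splits into 2×2
blocks per eigencoordinate, so likelihood evaluations are `O(n)`.  Fixed
effects are profiled out by GLS at every evaluation.  Optimisation is
bound-constrained L-BFGS-B on log-variances (and `atanh` correlations),
with multiple starts and a `1e-8` tolerance on the log-likelihood.
The LRT against `σ²_A = 0` uses the 50:50 point-mass/χ²(1) boundary
mixture; the interior tests of `ρ_g = 0` and `ρ_e = 0` use plain χ²(1).
The model is AE only — no shared-environment (C) component, matching the
narrow-sense heritability definition; household/site random effects are
excluded (site enters as fixed-effect dummies).

## Synthetic cohorts

The generator plants `k` latent dimensions.  Per dimension, an
additive-genetic component with covariance `2Φ` (MZ co-twins share it
fully, DZ/siblings half: `a_i = √½ c_fam + √½ m_i` with MZ co-twins
sharing `m`) is mixed with an independent environmental component so the
latent variate has heritability `h2_target`; the behaviour-side variate
correlates `rho` with the brain-side variate through equally weighted
genetic and environmental channels.  Observed features are
`signal_strength × latent × pattern + age/gender effects + N(0, noise_sd²)`,
with brain rows then multiplied by per-participant lognormal size factors
(TIV, mean-CT, total-SA analogues).  Requesting `rho = 1` with a nonzero
noise floor is rejected as infeasible.

Defaults are the study conditions: ages uniform on 22–37 (young-adult
style) with a 36–100 option, gender Bernoulli(½), families of 3–6 members
containing one twin pair with MZ:DZ ≈ 292:323 (or all singletons for the
aging-cohort style), and a 10% coefficient of variation on size factors.
`signal_strength = 5` with unit noise puts the per-view score-latent
correlation at `5/√26 ≈ 0.98`, so the population canonical correlation of
the observed views is `rho × 25/26` — the mild attenuation any
feature-noise model implies, and the reason holdout correlations
concentrate slightly below the planted `rho`.

Brain loading patterns are spatially smooth: Gaussian fields with
covariance `exp(−d/ℓ)` in great-circle distance `d`, length-scale
`ℓ = 0.5` rad by default — enough autocorrelation that a spatially
unaware permutation test is visibly anti-conservative, which is exactly
what the spin test must protect against.  Surface parcels use a Fibonacci
lattice (near-equal cell areas) under a seeded random rotation; the GMV
block follows the study layout of up to 200 cortical parcels with the
remainder subcortical/cerebellar.  Patterns across dimensions are
orthonormalised; behavioural scores are continuous Gaussian (their real
counterparts are of mixed type — a stated limitation).

What the synthetic experiments do **not** show: robustness to mixed-type
or skewed behavioural variables, to residual site effects beyond linear
dummies, to non-linear confound effects, to measurement artefacts in real
parcellations, or to family structures outside {MZ pair, DZ pair,
full siblings, singletons}.

## Problem sizes used in validation

The automated experiments use desk-scale cohorts chosen to keep Monte
Carlo error well below the effect sizes being checked: oracle equivalence
on 100 random small instances; parameter recovery on 20 cohorts of
n = 800 with 70 brain + 12 behaviour features; omnibus type-I error on
200 null cohorts of n = 200 with 100 permutations each (add-one
estimator); spin calibration on 500 map pairs at 100 parcels per
hemisphere with 300 rotations; twin-model recovery on 100 replicates of
300+300 pairs (univariate) and 30 replicates of 400+400 pairs
(bivariate); boundary-null calibration on 200 replicates of 100+100
pairs.  The acceptance script uses n = 600 with 1000 permutations per
split.

## Known limitations

* Inner-loop deconfounding is inherited from the optimisation set rather
  than refitted per inner split; the holdout contract is unaffected.
* The p-value floor makes the framework's corrected p-values
  conservative at small permutation counts; use `add_one` for
  calibration work.
* The spin test operates at parcel level (centroid spins with
  duplicates), not vertex level, and assumes mirror-symmetric atlases.
* The AE optimiser can place `ρ` estimates at the `±0.99999` bound when
  traits are numerically identical; this is reported as-is.
* `run_framework` holds per-split copies of the preprocessed data in
  memory; at very large `n × p` a chunked implementation would be needed.
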