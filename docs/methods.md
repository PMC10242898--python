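# Methods

## The model

`cotfam` implements a biometric structural model for *extended family
units* in a children-of-twins design: two adult siblings (the "linking"
siblings), their spouses, and up to two children per nuclear family.  The
design leverages the fact that the offspring of monozygotic twins are, to
their parent's co-twin, genetically like half-siblings: comparing
aunt/uncle–child associations across sibling classes that share 100%, 50%
or 25% of segregating genes separates genetic from environmental routes of
intergenerational transmission.

### Parental generation

Each adult's latent phenotype (here: stable neuroticism) is standardized,

    N = a·A + c·C + e·E,   a² + c² + e² = 1,

with additive-genetic (A), shared-environment (C, default 0) and unique
(E) standard-normal factors.  Linking siblings' A factors correlate with
the genome share α of their class (MZ 1, DZ/full sibs 0.5, half sibs
0.25); their C factors correlate 1 when c is enabled.  N is measured by
two indicators `y_i = μ_i + λ_i·N + ε_i`, `Var(ε_i) = θ_i`.  By default
the measurement model is shared between mothers and fathers; a switch
frees loadings, residuals and intercepts by parental sex.  A
single-indicator configuration is obtained by marking the second-indicator
columns missing and fixing `λ2, θ2, μ2`.

### Assortative mating

Spousal resemblance is parameterized by correlations between spouses'
factors: `rho_A` for the additive factors and `rho_E` for the unique
environments, with the spouse's factor constructed conditionally
(`A_sp = rho_A·A_s + noise`).  The phenotypic partner correlation is the
derived quantity

    d = rho_A·a² + rho_E·e²,

splitting into a genetic covariance component `r_g = rho_A·a²` and an
environmental component `r_e = rho_E·e²`.  The conditional construction
makes every in-law covariance closed-form (`rho_A·α·a²` for
sibling-in-law, `rho_A²·α·a²` for co-in-law pairs) and keeps the simulator
and the covariance algebra consistent by construction.  Whether the
original family of models used factor correlations or a copath is a
design freedom; this parameterization reproduces the partner-correlation
decomposition with two free parameters and is self-consistent.  The
parental generation is *not* assumed to be at assortative-mating
equilibrium; the factor correlations describe the observed couples.

### Children

A child's outcome (free scale, deliberately not standardized) is

    O = μ_o + β_sex·sex + β_parity·parity
        + p_m·N_mother + p_f·N_father + g·G_t
        + a_c·A_ch + c_c·C_nuc + e_c·E_ch,

where the transmitted genotype is the mid-parent breeding value plus
segregation noise, `G_t = (a·A_m + a·A_f)/2 + S`, `Var(S) = a²/2`.  Under
assortment `Var(G_t) = a²(2+rho_A)/2`, full siblings share
`(a²/2)(1+rho_A)` and cousins `(α·a²/4)(1+rho_A)²`.  The child-specific
additive factor correlates 0.5 between full siblings and α/4 between
cousins — the standard kinship coefficient *ignoring* assortment, because
child-specific loci are by definition uncorrelated with the parental trait
being assorted on.  The nuclear-family environment `C_nuc` is shared
within, independent across, nuclear families.  Covariates (child sex,
coded girl = 1, and parity 0–3) enter the mean only.

### Pathway decomposition

A model-implied parent–child covariance is a sum of path-traced terms,
classified by a single rule: a term belongs to the **assortment** slice
iff its path traverses at least one spousal correlation edge; the
parent's own direct path is **direct**; the parent's own transmitted
half `g·a²/2` is **genetic** even under assortment.  For the mother:
direct `p_m`, genetic `g·a²/2`, assortment `p_f·d + g·rho_A·a²/2`
(fathers symmetric).  Dividing by the implied child SD (parent latent SD
is 1) gives correlation slices that sum to the total exactly.  Percentage
CIs use the delta method on the fitted parameter covariance; a
resampling alternative was considered and not included, since refitting
per resample costs more than the quantity warrants here.

### Assortment algebra

With a constant breeding-value correlation m between mates the additive
variance follows `V(t+1) = V0/2 + V(t)(1+m)/2`, rising from the
random-mating base V0 to the equilibrium `V0/(1−m)`.  The
`EQUILIBRIUM` inflation mode reports `100·(1/(1−r_g) − 1)` percent;
`ONE_GENERATION` reports `100·m/2`.  Both are exposed because the two
readings of a printed "genetic correlation between spouses" (covariance
component vs breeding-value correlation) coincide only when a² is the
denominator's reference; the recursion test pins the equilibrium formula
to its fixed point.

## Estimation

Each unit contributes the Gaussian log-density of its observed subvector
under the sub-selected implied moments (full-information ML; families
participating with one child are simply missing the second child's slot).
Records are grouped by (structure, missingness pattern); each group's
padded 12×12 covariance is factorized once.  Three implementations of the
objective exist and are pinned together by tests: an ungrouped per-record
reference, a vectorized grouped numpy path, and a compiled (numba) kernel
used in the optimizer's inner loop (agreement ~1e-10).

The five mean parameters (`μ1, μ2, μ_o, β_sex, β_parity`) enter the mean
structure linearly and are profiled out exactly by GLS at each objective
evaluation, leaving 13 covariance-structure parameters for the outer
optimizer: BFGS on an unconstrained scale (log for variances and
variance-like paths, atanh for correlations, logit for the latent
heritability share a²), with an L-BFGS-B fallback when the line search
degrades.  Multi-start (default 5, jitter SD 0.25 on the transformed
scale, seeded) guards against local optima; replicate simulation studies
use a single start from a moment-based neutral start, which proved
sufficient at their sample sizes.  Convergence requires a finite optimum
and a gradient below `1e-5` per observed data point (scale-free in n);
the relative −2LL tolerance of the fallback is 1e-10.  Non-convergence is
flagged on the result, never silently dropped.

Wald intervals are symmetric on the unconstrained scale and mapped back
(hence asymmetric and always in-domain for bounded parameters); profile
likelihood (χ²(1) cutoff, bracketing + Brent) is the reference interval
method, with the Wald interval as a flagged fallback and domain bounds
clipped and flagged.  The Hessian is a central finite difference on the
transformed scale.

Constrained fits in the nested model family (no direct maternal path, no
direct paternal path, neither, no genetic transmission, no assortment)
start from the full-model solution, guaranteeing non-negative
likelihood-ratio statistics; transmission paths are interior parameters,
so the standard χ² reference applies with no boundary mixture.

## The simulator

`simulate_table` draws latent factors with exactly the covariance
structure above and emulates the sampling frame of a large
pregnancy-cohort study: 11,088 units by default; sibling-class mix 10% MZ,
15% DZ, 60% full siblings, 15% half siblings (per-class counts are not
published for the emulated study; the mix is configurable); each linking
sibling is the mother of their nuclear family with probability 0.5;
48.9% girls; parity 0–3 with probabilities (0.45, 0.35, 0.15, 0.05); one
or two children per nuclear family (`two_child_fraction = 0.18`, chosen
so the cohort averages ~2.35 children per unit); family-level outcome
response 0.70 (all-or-none per unit) and 5% item-level adult missingness,
both MCAR.  Covariate effects default to small nonzero values so those
code paths are always exercised.

What the simulator does **not** emulate: cohort self-selection
(participation bias), informative or family-structure-dependent
missingness, rater effects (the same informant reporting on herself and
the child), ordinal item-level measurement, and sex-specific genetic
transmission.  Passing tests therefore demonstrate internal consistency
of model, likelihood and estimator under the stated sampling frame — not
robustness to those real-data complications.

## Verification experiments and problem sizes

* **Generator/algebra oracle** — 10⁶ units of one fixed structure class
  (DZ, mother/father roles, two children each, complete data, seed 0);
  every empirical mean and covariance entry within 3 Monte-Carlo SEs of
  the implied value.  This is the package's single most important test.
* **Parameter recovery** — 50 replicates of 2,000 units at the reference
  parameters with default missingness (seeds 20000–20049): latent-scale
  parameters show |median bias| < 0.02 and mapped-Wald 95% coverage
  within [88%, 100%].  The child-variance components a_c/c_c/e_c are
  excluded from this check: their A/C trade-off is weakly identified at
  this design size (the emulated study makes the same caveat), their
  Wald-type intervals cover at ~84–86%, and per-replicate profiling is
  computationally disproportionate.  They do not influence the
  intergenerational estimates.
* **LRT calibration** — 1,000 replicates of 500 complete-data units
  simulated with g = 0 (seeds 30000–30999); the 1-df test of g rejects at
  5% within [3%, 7%].  Complete data are used because MCAR missingness
  does not affect test validity and the calibration is about the χ²
  reference, not the missing-data machinery.
* **Decomposition** — slices sum to the total by construction and match a
  path-knockout oracle (differencing implied covariances with path groups
  removed) to 1e-6.

## Known limitations

* The genetic-transmission path g is weakly identified at a few thousand
  units (sampling SD ≈ 0.3 at n = 2,000 under the default design); its
  estimate at realistic cohort sizes carries wide intervals, as in the
  emulated study.
* Child-specific A/C/E components are poorly separated (see above);
  interpret their point estimates cautiously.
* No sandwich/robust standard errors and no sampling-design weights.
* The assortment parameterization is one of several observationally
  similar choices (factor correlations vs copath); quantities reported on
  the d / r_g / r_e scale are invariant to that choice, internal factor
  correlations are not.
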