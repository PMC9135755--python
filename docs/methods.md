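# Methods

## Statistical models

### Phylogenetic generalized least squares

Species-level log-log allometry is fitted as `y = Xβ + ε`,
`ε ~ N(0, σ² V(λ))`, where the base covariance `C` has entries equal to
the shared root-to-ancestor path length of each species pair under
Brownian motion, and `V(λ)` scales the off-diagonal entries of `C` by
Pagel's λ ∈ [0, 1] (λ = 0: star phylogeny, independent tips; λ = 1: full
Brownian structure). Estimation whitens through the Cholesky factor of
`V`; coefficient covariance is `σ̂² (XᵀV⁻¹X)⁻¹` with
`σ̂² = RSS_V / (n − p)`. λ maximizes the *restricted* likelihood by
default (less biased σ² at the sample sizes typical of comparative
datasets, a few dozen species); a switch gives full ML. Reported residuals
are ordinary (`y − Xβ̂`, response units), because the downstream
residual-association construction regresses these per-trait residuals on
each other — itself with the same phylogenetic engine — mirroring the
two-stage "regress each trait on size, then associate the residuals"
design. Degrees of freedom are reported as `n − p` (mean parameters only);
the run log records `n` and `p` per model so df bookkeeping is always
traceable.

OLS fits (used for individual-level data, optionally with treatment-coded
species dummies, reference level = alphabetically first species) go
through statsmodels; nested models are compared with the
extra-sum-of-squares F statistic on (whitened, for GLS) residual sums of
squares.

### Standardized major axis

Within one group, the SMA slope is `b = sign(s_xy)·√(s_yy/s_xx)` and the
elevation `a = ȳ − b·x̄`; the slope CI uses the standard F-based
construction `b(√(B+1) ± √B)` with `B = F₁₋α;1,n−2 (1−r²)/(n−2)`. SMA
(not major axis) is the default because both variables carry biological
variation; an `ma` switch exists.

Across g groups, the common slope minimizes the likelihood-ratio statistic
`LR(b) = −Σ (nᵢ − 2.5) ln(1 − r²_rf,i(b))`, where `r_rf,i` is the
within-group correlation of residual scores `y − b x` and fitted-axis
scores `y + b x`; each term vanishes at the group's own SMA slope, and
`LR(b̂)` is referred to chi-square with g − 1 df (the `nᵢ − 2.5` weight is
the usual small-sample correction for grouped SMA likelihoods). The slope
variance is taken from the numerical curvature of the LR profile at its
minimum (`var(b̂) = 2 / LR''(b̂)`, central differences), i.e. observed
information — validated empirically by the null-distribution study below.

Equal elevations are tested with a Wald statistic on
`aᵢ = ȳᵢ − b̂_c x̄ᵢ` using
`V = diag(s²_r,i (nᵢ−1)/(nᵢ−2) / nᵢ) + var(b̂_c)·x̄x̄ᵀ`
(the `(nᵢ−1)/(nᵢ−2)` factor puts the residual variance on its correct
n − 2 df since the slope is estimated; the rank-one term propagates the
shared slope uncertainty, producing the right correlation between group
elevations). The statistic is the GLS quadratic form for "all elevations
equal", chi-square with g − 1 df. This construction is exactly invariant
to adding a constant to x (elevations shift by `−b·c` uniformly; the
contrast removes it, and `x̄x̄ᵀ` only enters through contrasts), which the
test suite asserts to 1e−8.

Pairwise elevation comparisons re-estimate a common slope per pair by
default (matching how grouped-SMA tools behave when handed two groups); a
flag reuses the globally estimated slope. Raw pairwise p values are
reported, with Holm-adjusted values alongside — adjusted values are
informational, not substituted into the classification.

## Trade-off framework

* **Conditional association** — `A ~ size + B`; the partial coefficient
  on B is the test. Negative and significant is consistent with a
  trade-off.
* **Residual association** — residuals of `A ~ size` regressed on
  residuals of `B ~ size`, same engine at both stages.
* **Shift classification** — given both structures' pairwise elevation
  matrices, each species pair is labelled with precedence
  `inverse > single_structure > minor > same_direction > none`: *inverse*
  requires opposite-signed shifts both at least `min_shift` (default 0.1
  log units; a `strict` flag additionally demands both pairwise tests
  significant, and both counts are always reported, along with the count
  under the alternative order of applying the minor-shift exclusion);
  *single_structure* means exactly one structure's test is significant;
  *minor* absorbs pairs with a sub-threshold shift in either structure.
* **Ratio diagnostics** — `ratio_size_test` regresses the log ratio on a
  (log) size variable; a significant coefficient means the ratio retains
  allometric signal. `ratio_scenarios` decomposes a target ratio into
  three allocation histories (both traits move, split in log space —
  default equally, the figure-style presentation does not fix the split
  so it is a parameter; numerator only; denominator only), each exact to
  machine precision. Ratios are always formed on the raw scale.
* **Elevation-difference correlation** — Pearson correlation of the two
  structures' upper-triangle pairwise Δ-elevations. Always emitted with
  caveats: the g(g−1)/2 pairs share species and are not independent, so
  this is exploratory only.

For imaginal-disc-style data the size control is constructed as
total − focal portions on the raw scale before logging, giving an
allometric control independent of both focal structures.

## Synthetic data

The generator emulates the data-generating assumptions of the analyses:
a pure-birth tree (depth normalized to 1; the clock is run on past the
last birth so no tip branch has zero length), log₁₀ size evolving as BM,
and focal traits `log T = α + β·log size + shift + ε` with `(ε_A, ε_B)`
bivariate, SDs `(σ_A, σ_B)` and correlation ρ. In the default
*phylogenetic* residual mode the deviations themselves evolve as
bivariate BM on the tree — a trade-off, if present, is heritable, which
is what a conserved developmental constraint predicts; *independent* mode
draws them per tip to separate phylogenetic from tip-level signal.
Defaults: 59 species (the breadth of the widest target dataset), BM rate
0.1 on log₁₀ size (tip SD ≈ 0.32, about a twofold spread around the
median — a realistic interspecific size range for a fly clade), slopes
0.75 (the hypo-allometric exponents the target analyses report), residual
SD 0.1 log₁₀ units, five individuals per species with within-species SD
0.05 for individual-level data (sample sizes of 4–8 per species are what
such datasets actually contain). Random streams are spawned per trait and
keyed per species, so adding a trait or species never perturbs existing
draws; identical configs are bit-reproducible.

Presets encode the study conditions: `tradeoff_strong` (ρ = −0.7),
`independent` (ρ = 0), `hyperallometric_no_tradeoff` (β_A = 1.3, ρ = 0 —
the ratio-trap scenario), `conserved_slope_shifted_elevations` (six
species, shared slope, elevation shifts up to 0.5).

What the simulator does **not** emulate: measurement error beyond
additive log-scale noise, non-Brownian evolution (OU, rate shifts),
missing data patterns, unequal per-species sample sizes, or correlation
between the size trait and the residual deviations. Passing tests
therefore demonstrate that the estimators do what they claim under their
own assumptions — not that any particular empirical dataset satisfies
those assumptions.

## Numerical choices

* λ optimization: bounded Brent on [0, 1], tolerance 1e−6; if an interval
  endpoint attains at least the interior optimum the boundary value is
  reported (boundary estimates are common and meaningful: λ̂ = 1 is pure
  BM, λ̂ = 0 a star phylogeny).
* Common slope: the LR statistic is minimized over `b = sign·exp(t)` with
  `t` bracketed ±6 around the pooled SMA slope (pooled within-group
  variances fix the sign), bounded Brent, tolerance 1e−12 on the
  statistic; non-convergence raises with the last iterate.
* Zero covariance in SMA: slope sign set positive with a logged warning.
* Groups with n = 3 are allowed but flagged `minimal-n` in outputs.
* Elevation tests warn (not fail) when the common-slope test rejects at
  0.05, since elevation comparisons presume slope homogeneity.
* Log base: 10 by default, natural log by a switch; slopes and test
  statistics are base-invariant, intercepts are not, and the base is
  recorded on every table and fit.
* Missing data are dropped per model (not globally), and each fit reports
  its own n and residual df.
* Rank-deficient designs raise, naming the collinear columns found by
  pivoted QR.

## Validation study sizes

The acceptance harness recomputes, at one seed: exactness checks
(machine precision); null calibration of the common-slope and elevation
tests with 6 groups × 30 observations × 1000 replicates (mean elevation
Wald ≈ 5 with rejection near the 5% level); PGLS slope recovery at
β ∈ {0.5, 0.75, 1.0} with 59 tips × 500 replicates; ML-λ recovery with
100 tips × 200 replicates; and the framework contrast at 59 tips × 500
replicates per scenario. These sizes give Monte-Carlo standard errors of
well under one percentage point on the rates while the whole run stays
around half a minute.

## Known limitations

* The grouped-SMA tests are asymptotic; at 30 observations per group the
  elevation test runs slightly liberal (empirically ~5–7% at nominal 5%),
  consistent with the behaviour of the standard tooling it mirrors.
* The published phylogenetic statistics this package targets were
  produced by an MCMC sampler; ML/REML PGLS reproduces them only
  approximately. SMA and OLS quantities are exact-algorithm and should
  match printed values to their precision.
* No Ornstein–Uhlenbeck or multi-rate models, no measurement-error
  models, no Bayesian model comparison; trees are user input (no
  inference), Newick only.
* Inference stops at association: fitness consequences or selective
  causes of any detected pattern are outside what these data can support.
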