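# Methods

## The estimation problem

Constant-effort autumn ringing produces long capture series in which the
morphometrics (body weight, third-primary length) and the capture date are
always recorded but the discrete labels — sex and age class — often are not,
and the chance that they are missing depends on what the bird is.  In the
Black Redstart setting that motivates this package, dull female-like birds
(adult and young females plus the ~90% of young males with *cairei* plumage)
can rarely be sexed, while young males with the adult-male-like *paradoxus*
plumage are sexed essentially always.  Complete-case analyses are therefore
either biased (pooling everything, ignoring class structure) or wasteful and
imprecise (keeping only fully identified birds).  The package instead fits
the joint model of morphometrics and labels and lets MCMC impute the missing
labels at every iteration.

## Model

For capture *i* with age-sex class g(i) ∈ {young female, young male, adult
female, adult male}, centered day d and centered year t:

* (Weight, Primary) is bivariate normal with mean
  (w0_g + w1·d + w2·t, p0_g + p1·d + p2·t) and a class covariance Σ_g;
* Sex ~ Bernoulli(invlogit(s0 + s1·d + s2·t)), 1 = male;
* Age ~ Bernoulli(invlogit(a0 + a1·d + a2·t)), 1 = adult.

Day is centered on the season midpoint (so intercepts refer to a mid-season
bird) and year on the study midpoint year, in units of days and years: every
slope reads directly as a per-day or per-year change (g/day, mm/year, logit
units/year, ...).

**Covariance parameterization.** The default treats the four class
covariance matrices as free 2×2 matrices with independent
inverse-Wishart(scale 10⁻⁴·I, df 3) priors — the conjugate choice — and
reports per-class correlations ρ_g plus their posterior mean as a summary
"ρ".  A variant sharing a single correlation across classes (class standard
deviations with half-normal(5) priors, ρ ~ Uniform(−1, 1), Metropolis
updates on log-sds and atanh ρ) is available via `MCMCConfig(shared_rho=True)`;
on well-behaved data the two agree closely because each class is rich enough
to pin its own correlation.

**Priors** (all weakly informative on the scale of the data): w0_g ~
N(16 g, 5²), p0_g ~ N(65 mm, 5²), every day/year slope ~ N(0, 1), s0 and a0
~ N(0, 2²).

**Plumage constraint.** Paradoxus is by definition a first-year male
plumage, so a recorded paradoxus label restricts the admissible completions
of that record to the young-male class.  "Female-colored" is deliberately
*not* used as evidence (the protocol applies it to males and females alike).

## Sampler

Each sweep of the kernel:

1. **Labels.** Every record with at least one missing label draws a class
   from its full conditional: the class-g morphometric density times the two
   Bernoulli label probabilities, normalized over the classes admissible
   under the observed labels and the plumage constraint (vectorized over
   records).
2. **Mean structure.** The 12 regression coefficients (w0 1–4, w1, w2,
   p0 1–4, p1, p2) are drawn jointly from their conjugate multivariate
   normal given the completed labels and current covariances, assembled from
   per-class sufficient statistics.
3. **Covariances.** Conjugate inverse-Wishart draws per class (default), or
   the Metropolis shared-ρ block (variant).
4. **Logistic blocks.** Coordinate-wise adaptive random-walk Metropolis for
   (s0, s1, s2) and (a0, a1, a2) on the Bernoulli likelihood of the
   completed labels with the normal priors; Robbins–Monro adaptation of the
   per-coordinate proposal scales toward acceptance ≈ 0.35, frozen at the
   end of burn-in (so the post-burn-in kernel is a fixed Markov kernel).

Production schedule: 2 chains × 6000 iterations, 2000 burn-in, thinning by
2 → 4000 saved draws; a documented desk-scale schedule (2 × 3000, burn
1000) is used by the replicated studies below.  Saved draws include the
completed class of every record, which is what the downstream analysis
consumes.

**Initialization.** Class means/covariances from complete-case records,
logistic coefficients from a ridge-stabilized (MAP) complete-case logistic
fit, and missing labels from the admissible class nearest in Mahalanobis
distance.  Chains are overdispersed by jittering the logistic coefficients
by ±2 complete-case standard errors; jittering by prior standard deviations
instead would strand a random-walk sampler far outside the posterior for the
entire burn-in, so the overdispersion is calibrated to the complete-case
information.  A class with no attributable record at initialization raises
immediately (the model cannot anchor its intercepts).  Gross morphometric
outliers (> 6 pooled SD) are logged but retained.

**Label-switching** is not an issue: class identities are anchored by the
records with observed labels (adults are mostly sexed and aged), so the
mixture never permutes.

**Correctness evidence.** The transition kernel passes a Geweke-style
successive-conditional test (alternating data regeneration with single
kernel sweeps reproduces the prior marginals of regression, logistic and
covariance parameters on a tiny instance with moderate priors); the density
and label-posterior primitives match independent textbook-formula oracles to
1e-10; with complete labels the posterior centers on the complete-data MLE;
and the inverse-Wishart sampler reproduces its analytic mean.

## Diagnostics

Convergence uses the potential scale reduction factor with the
sampling-variability and degrees-of-freedom corrections (the classic
corrected PSRF; the implementation reproduces R's `coda::gelman.diag` to
6 decimals on fixed chains).  A run is flagged non-converged when any scalar
parameter's R-hat exceeds 1.1; the flag is attached to the draws, not fatal.
Summaries are posterior means with 2.5%/97.5% quantiles (linear
interpolation of order statistics, R's default quantile type); effective
sample sizes come from arviz.

## Synthetic campaigns

The generator emulates a fixed-window constant-effort station:

* Per year, a Poisson number of captures (mean `mean_captures_per_year`)
  receives days from the passage-date normal truncated to the window — the
  exact equivalent of thinning a scaled Poisson passage stream by the
  in-window mass, with the yearly passage mean drifting by
  `phenology_shift` days/year (default 0.2, later).  Window default: 20 days
  starting 30 September, passage sd 8 days, passage mean 5 days after the
  window opens; none of these are identified by the published material, so
  they are package defaults exposed in the spec object.
* Conditional on the captured (integer) day and year, labels and
  morphometrics are drawn from exactly the fitted model's likelihood, so the
  model is correctly specified for these tables — the premise under which
  nominal interval coverage can be expected at all.
* Among young males, paradoxus plumage occurs with a year-logit-linear
  probability; paradoxus birds get additive effects on weight, primary
  length and (optionally) day.  Field-protocol labeling: females and cairei
  young males are "female_colored", adult males carry no plumage record.
* Masking hides sex/age independently per record with class-specific
  percentages — except that paradoxus records always keep their sex.  This
  reproduces the informative mechanism the model exists for: missingness
  depends on the (possibly hidden) class itself.  The fitted likelihood
  ignores that mechanism, exactly as the original analysis does; the
  coverage study below is the empirical demonstration that, at these rates
  and sample sizes, the approximation does not materially bias the
  estimates.  True labels are retained in shadow columns for evaluation
  only.

**Scenario presets.**  Scenarios 1–3 share a 30-year campaign of ~300
captures/year (reduced-mode overrides exposed): scenario 1 uses missing-sex
90/80/30/10% and missing-age 40/40/40/10% by class; scenario 2 makes all
young birds unsexable (100/100); scenario 3 equalizes the class
morphometric means.  Their generative truth sets the within-season gradients
to the published real-data estimates (s1 = 0.032, a1 = 0.122, w1 = 0.027,
p1 = −0.014), *no* year trend in the morphometrics (w2 = p2 = 0), and
positive year trends in the male and adult shares (s2 = a2 = 0.05):
together with the phenology shift this realizes the composition drift that
makes the naive pooled model (LM1) "discover" a year trend in primary
length that is not there.  Class intercepts (females < males, young <
adult: p0 = 63/67/64/68 mm, w0 = 15.5/16.0/15.7/16.3 g, sds 1 g/1.5 mm,
ρ = 0.5) are simulator defaults chosen to match the published orderings and
typical Black Redstart morphometrics; only the orderings, not the values,
are constrained by the source material.

The **subigerberg** preset mirrors the real 1980–2013 campaign: 34 years,
~323 captures/year, the published slope estimates as generative truth
(s1 = 0.032, s2 = −0.046, a1 = 0.122, a2 = 0.017, w1 = 0.027, w2 = 0.011,
p1 = −0.014, p2 = 0.015), the paradoxus fraction anchored at 7.6% (1980) and
18.1% (2013), paradoxus effects +0.25 g / +0.62 mm / 0 days, and
class-specific missingness (sex 95/90/40/15%, age 8/8/8/3%) chosen so the
overall missing fractions reproduce the reported ~80% (sex) and ~7% (age)
given the class mix implied by a0 = −1.5.

## Replicated studies

`run_study` repeats simulate → mask → fit, summarizes the eight slope
parameters, and fits two baselines per replicate with the same centering:
LM1 (OLS of weight or primary length on day + year over all records) and
LM2 (the same restricted to records positively identified as young
females).  Reported per parameter: coverage (fraction of replicates whose
95% interval contains the truth), bias (mean estimate − truth) with its
Monte-Carlo standard error, and mean interval width; baselines additionally
report the fraction of replicates rejecting zero in each direction.
Replicates failing the R-hat check are excluded from coverage with
disclosure.  Replicate seeds derive from the master seed through a
counter-based SeedSequence scheme, so any replicate reruns independently and
the whole study is byte-reproducible.

**Problem sizes.**  The package's desk-scale study runs 50 replicates of
10-year campaigns at ~150 captures/year with the 2 × 3000 schedule (the
acceptance script and test suite use exactly this, with fixed master
seeds); the full-size study (100 replicates, 30 × 300, 2 × 6000) is the
same code via `redstart simstudy`.  Study properties are statistical and
scale-free: interval coverage is nominal at either size, and the LM1
wrong-sign year trend is already significant in the majority of desk-scale
replicates.

The downstream recovery study (20 desk-scale subigerberg replicates) runs
the full selection/fit/sim/pool chain per replicate on 80 evenly spaced
posterior draws — pooled estimates stabilize well below that, and the
per-draw mixed-model fits dominate the cost.  When fewer than ~2000 draws
are pooled, several coefficient vectors are simulated per fitted draw (so
the pooled sample stays ≥ 2000): empirical 2.5%/97.5% quantiles from only
~80 points are biased inward and would understate the pooled intervals; at
the full 4000-draw schedule one simulation per draw is used, matching the
original procedure.  With labels fixed across
draws the pooling provably degenerates to the single fit plus simulation
noise (tested), and pooled intervals recover the generating +0.25 g /
+0.62 mm effects while the timing interval straddles zero, reproducing the
null timing finding structurally.

## Numerical choices

* Bivariate normal densities, their 2×2 inversions and the Bartlett-based
  inverse-Wishart draws are computed in closed form (validated against
  scipy); label sampling uses max-subtracted exponentials.
* The mixed models use REML via statsmodels; when the year variance
  component collapses to the singular boundary the model is refitted as the
  fixed-effects OLS it then equals.  Draws whose young-male subset contains
  a single plumage level are skipped and counted.
* The timing model uses raw capture days by default; a corrected-day
  variant (subtracting 0.2 days/year, so 10 Oct 2000 ≙ 6 Oct 1980) is
  exposed and gives quantitatively similar results.
* Per-draw coefficient simulation symmetrizes the fit covariance and uses
  an SVD-based multivariate-normal draw to tolerate semidefinite matrices.

## Limitations

* The masking mechanism is missing-not-at-random by class while the fitted
  likelihood assumes ignorability.  The replicated study shows the
  practical consequence: interval coverage stays at the nominal level for
  every slope, but small systematic biases (well under 10% of the
  parameter values, concentrated in the logistic day-gradients, e.g. a
  slight attenuation of the within-season sex gradient) survive averaging
  over replicates.  They are a property of the method under this
  missingness design, not of the implementation — they vanish when masking
  is switched off — and removing them would require modeling the
  missingness mechanism itself.
* The generator omits weather-driven effort gaps, recaptures and unequal
  within-season effort; passing tests demonstrate correctness of the method
  under its own assumptions, not robustness to effort artifacts in real
  series.
* The paradoxus morphometric shifts make the young-male class a slight
  two-component mixture that the model approximates by a single normal; at
  the published effect sizes (≤ 0.62 mm against a 1.5 mm sd) the
  approximation is invisible in the checks.
* Year enters all linear predictors linearly; long series with nonlinear
  trends would need basis expansion, which the design deliberately omits.
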