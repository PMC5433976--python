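# redstart

Bayesian analysis of autumn bird-ringing captures with missing sex and age
labels, built around the Black Redstart (*Phoenicurus ochruros*) ringing
problem: at a constant-effort autumn station, most dull ("female-colored")
birds cannot be sexed in the field, while young males that molted into the
adult-male-like **paradoxus** plumage are easy to sex.  Because the
probability that a capture's sex is recorded depends on what the bird is,
simply dropping unsexed records biases any comparison of the paradoxus type
with its dull **cairei** counterpart.  This package fits the joint model that
treats the missing labels as unknowns, runs the simulation study that
validates the approach against naive baselines, and propagates label
uncertainty into downstream plumage-type comparisons.

## The model

Each first-capture *i* has day `Day_i` (centered mid-season), year `Year_i`
(centered on the study midpoint), body weight and third-primary length, and
belongs to one of four age-sex classes *g*: young female (1), young male (2),
adult female (3), adult male (4).

```
(Weight_i, Primary_i) ~ MVN( (w0_g + w1 Day_i + w2 Year_i,
                              p0_g + p1 Day_i + p2 Year_i),  Sigma_g )

Sex_i ~ Bernoulli( invlogit(s0 + s1 Day_i + s2 Year_i) )    (1 = male)
Age_i ~ Bernoulli( invlogit(a0 + a1 Day_i + a2 Year_i) )    (1 = adult)
```

Weakly informative priors: `w0_g ~ N(16, 5²)` g, `p0_g ~ N(65, 5²)` mm, all
day/year slopes `N(0, 1)`, logit intercepts `N(0, 2²)`, and an
inverse-Wishart(10⁻⁴ I, df 3) on each class covariance.  A Gibbs-within-
Metropolis sampler alternates imputing every missing sex/age label from its
full conditional (the class-specific morphometric likelihood times the two
Bernoulli label probabilities) with conjugate draws of the mean structure and
covariances and adaptive random-walk updates of the logistic blocks.  Records
with paradoxus plumage are constrained to the young-male class.

On top of the fitted model, the plumage analysis repeats for every saved
posterior draw: select the (observed-or-imputed) young males, fit a linear
model of capture day on year + plumage type and mixed models of weight /
primary length on day + year + plumage type with a random year intercept,
then draw one coefficient vector from each fit's sampling distribution.
Pooling these draws yields effect estimates whose intervals carry both label
and estimation uncertainty.

## Worked example

Simulate a campaign from the "subigerberg" preset (generative truth: the
paradoxus fraction among young males rising 7.6% → 18.1%, paradoxus birds
+0.25 g and +0.62 mm, no timing difference; ~80% of records unsexed), fit the
model, and pool the plumage effects:

```sh
redstart simulate --scenario subigerberg --seed 11 --out captures.csv \
    --n-years 12 --captures-per-year 200
# wrote 2409 captures to captures.csv
redstart fit --table captures.csv --out posterior --iters 2000 --burn 800 --seed 12
# saved 1200 draws to posterior
redstart analyze --table captures.csv --posterior posterior --seed 13 \
    --out effects.json --n-draws 100
# paradoxus - cairei: timing -0.76 d [-1.73, 0.24], weight +0.293 g, primary +0.856 mm
```

The analysis report (`effects.json`) shows the pooled weight contrast
0.29 g [0.09, 0.50] and primary-length contrast 0.86 mm [0.54, 1.18] — both
intervals comfortably off zero (directional support ≥ 0.998) and consistent
with the generating +0.25 g / +0.62 mm at this modest campaign size — while
the timing contrast straddles zero, matching the generating null.  The
paradoxus fraction at the first study year is estimated at 7.6%
[5.1%, 10.7%] against a generating 7.6%.

The same pipeline is scriptable from Python (`redstart.simulate_captures`,
`redstart.run_mcmc`, `redstart.analyze_plumage_effects`), and
`redstart simstudy --scenario 1 --reps 100 --seed 1 --out study/` runs the
full coverage/bias evaluation against the LM1/LM2 baselines.

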