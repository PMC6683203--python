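# Methods

## The experiment being modelled

`sublethal` re-implements, as a tested pipeline, a joint Bayesian analysis of
a two-generation split-brood experiment on the Colorado potato beetle
(*Leptinotarsa decemlineata*). Second-instar larvae (n = 245) were randomised
to a water control or a sublethal deltamethrin exposure for 24 h and reared
individually through larval, pupal and adult stages. Fourteen control males
were each mated to four unrelated females — two control, two
insecticide-exposed — giving 56 families whose offspring (n = 842) were
re-randomised to their own treatments. The split-brood structure separates
the maternal (transgenerational) treatment from paternal identity; the
questions are whether an individual's own sublethal exposure and its
mother's exposure change survival, development time, body mass and body
composition.

## Model

A single joint model covers the whole experiment, factorised into
independent submodel *blocks*, one per outcome:

* **Stage-conditional mortality.** Survival is analysed per life stage
  (24 h exposure window, remaining larval period, pupal stage, adult stage)
  with a logistic regression whose response is *death* (death = 1).  An
  individual enters stage *k*'s design matrix only if it survived all
  earlier stages, so the stage likelihoods are products of independent
  Bernoulli terms and the joint likelihood factorises exactly.  Because the
  response is death, survival odds ratios are `exp(-coefficient)`; the
  `odds_ratio_summary` API requires the caller to state the direction.
* **Development time** (egg hatch to emergence, days) is log-normal: a
  normal model on `log(days)` including the Jacobian term, so submodel
  log-likelihoods are comparable.
* **Body masses** (emergence, day 7/10/14, mg) are normal.
* **Composition fractions** (relative lipid, water, dry mass) are beta
  distributed with a logistic link on the mean and a free precision φ.

Covariates per block follow the published layout: own treatment (`within`),
maternal treatment (`trans`, generation 2 only), sex (`male`), the dam's
10-day body mass (uncentered, mg), the gen-1 pre-treatment larval mass
(24 h block only), and the `within x trans` and `male x trans` interactions.
The gen-2 adult mortality block carries no treatment interaction — too few
deaths remained to estimate one.  Reference levels are control = 0,
female = 0.  There are no family random effects; maternal covariates carry
the between-family structure.

**Model reduction.** The full model is fitted first; every *non-treatment*
interaction whose 95% interval contains zero is removed and the model
refitted.  Interactions between the two treatments are always kept (they
are the substantive question), and main effects are never removed.

## Priors

The original analysis's parametric prior forms are not available, so the
defaults are the package's own weakly-informative choices, configurable via
`PriorSpec`:

| parameter class                       | default                          |
|---------------------------------------|----------------------------------|
| logit/log-scale intercepts            | Normal(0, 10²)                   |
| logit/log-scale slopes & interactions | Normal(0, 2.5²), **autoscaled**  |
| mg-scale (normal-family) coefficients | Normal(0, 100²)                  |
| residual scales σ                     | Half-Normal(10)                  |
| beta precisions φ                     | Gamma(0.01, 0.01)                |

Autoscaling divides a slope's prior scale by the predictor's sample SD, in
the style of rstanarm's defaults: a balanced binary treatment indicator gets
an effective scale of ~5, while the uncentered mg-scale maternal-mass slope
gets ~2.5/18 ≈ 0.14 per mg.  The scale choices matter here and were
validated by recovery calibration: a 10-unit normal prior is *not* weakly
informative for mg-scale masses (it visibly shrinks a 165 mg intercept),
hence the wide normal-family scale; a 10-unit scale on logit slopes lets
posterior means inflate away from zero in rare-event stages (~6–30 deaths;
the quasi-separation pathology), while a flat unscaled 2.5 both over-shrinks
the larger treatment effects and is meaninglessly wide (±2.5 *per mg*) for
mass covariates — per-SD scaling resolves all three at once.  Explicit
overrides are never autoscaled; `PriorSpec.from_summaries` converts any
posterior summary table into normal priors — this is how a gen-1 posterior
is carried forward as the gen-2 prior.

## Sampler

`sample_posterior` is an adaptive Metropolis-within-Gibbs sampler written
in-repo.  One proposal block per submodel holds its coefficients plus the
log residual scale (or log precision, with the Jacobian included in the
target).  Each block uses a Gaussian random walk whose covariance is learned
during burn-in: states are recorded every 10th iteration and the proposal is
periodically rebuilt as `2.38²/d` times the empirical covariance (with a
small diagonal guard), while a Robbins–Monro recursion tunes a global step
toward 30% acceptance.  Covariance adaptation matters: the treatment main
effects and their interaction are strongly correlated, and a diagonal
proposal leaves effective sample sizes near 80 where the adaptive proposal
reaches ~900 at the same schedule.  Continuous mass covariates are centered
internally (priors are evaluated, and draws reported, on the natural scale)
to decorrelate slopes from intercepts; this is a pure reparametrization.

Initialisation is at prior means with a small jitter, except scale
parameters, which start at the response's sample SD — with mg-scale data a
prior-mean scale start would merely lengthen burn-in without changing the
target.  Schedules: the `desk_scale` default is 20,000 burn-in then 2,000
retained draws at stride 10; `publication_scale` reproduces the original run
(2,000,000 burn-in, every 500th of 5,000,000 further iterations, one chain).
A single chain is the default; `n_chains` is configurable and chains are
concatenated with their count recorded for split-chain ESS.

**Missing-covariate imputation.** Dams weighed at day 10 provide their
offspring's maternal-mass covariate; dams that died during the adult stage
have no 10-day mass.  Each missing mass is a latent variable updated every
sweep by a Metropolis step whose target combines the gen-1 10-day-mass model
(its prior) with every gen-2 likelihood term the mass enters — information
flows between generations in both directions.  The same latent-mass density
is added to the gen-1 mass block's own Metropolis ratio so that all updates
target one joint distribution.  Proposals for all missing dams are made
jointly and accepted per dam (their offspring sets are disjoint, so the
acceptance factorises).

**Diagnostics** (`diagnostics`) report per-parameter ESS (via `arviz`),
autocorrelation to lag 50, and flag parameters with ESS < 100 — that
threshold is this package's convention, not a published one.  Constant
(degenerate) traces are flagged rather than raising.

**Posterior predictive checks** draw a retained parameter vector (with its
matching imputed masses), re-simulate the cohort holding observed covariates
fixed, and tabulate stage-wise death counts and trait means against the
observed data, reporting the replicate mean, SD and 2.5%/97.5% quantiles per
statistic.  The default is 10 replicates, as in the original analysis.

## Synthetic-cohort generator

The generator *is* the generative model above, plus the experiment's design:
exact-split treatment allocation; a truncated Normal(4 mg, 1 mg)
pre-treatment larval mass (unreported in the study; chosen so that the
published 24 h mortality logit with its mass slope reproduces the reported
95–97% survival); sex Bernoulli(0.5) at emergence (no sex ratio was
reported); dams and sires drawn from emerged adults, sires from control
males only.  Default parameter values are the published posterior means;
unreported residual scales default to σ = 0.08 log-days for development
time, 12 mg (emergence) and 18 mg (later masses) for bodies, and φ = 100
for the three fractions — values a rearing dataset of this species would
plausibly produce, fixed once.

Missing maternal mass arises mechanistically: a dam that dies during the
adult stage is never weighed at day 10, and her offspring's covariate is
blank.  Her *latent* mass is still drawn from the gen-1 mass model and
drives her offspring's fates — exactly the quantity the sampler imputes.
Fractions are drawn independently from their three beta submodels; the
weighing identities are then back-filled (fresh = day-14 mass,
dry = dry-fraction × fresh, lean = dry − lipid-fraction × fresh, clipped at
zero in the rare tail where the independent draws cross).  The published
water-content formula is arithmetically negative as written and the three
intercepts satisfy no exact identity, so no identity is enforced; water
content exists only as its own beta outcome.  Boundary smoothing
`y -> (y(n-1)+0.5)/n` is applied identically when simulating and when
fitting beta outcomes.

At the published mortality levels, a 245-larva cohort fails to supply
14 sires + 56 dams in roughly 10–15% of realisations; the convenience
simulator redraws such cohorts from a fresh substream (the real experiment
was, by construction, feasible), while `mate_design` itself raises an
explicit shortfall error with counts.  This conditioning slightly favours
low-mortality gen-1 realisations; exact-quadrature checks put the induced
bias on mortality intercepts well inside half a posterior SD.

What the generator does **not** emulate: family random effects beyond the
maternal covariates, fecundity/egg counts, overwintering, sex-ratio
distortion, measurement error in weighings, and any real-data quirks of the
undeposited original data.  Passing recovery tests therefore demonstrate
that the *inference machinery* is calibrated under the model, not that the
model is right for real beetles.

## Experiment problem sizes

The recovery experiment fits the eight mortality blocks plus the gen-1
10-day-mass block (the imputation prior).  The joint likelihood factorises
over blocks, so omitting the other trait blocks leaves the survival
posteriors unchanged while keeping 50 replicate fits at the published
sample sizes inside a coffee break.  The posterior-predictive
self-consistency experiment uses 10 seeds × 10 replicates at the published
sizes with the same working schedule.

## Numerical notes and limitations

* Beta means are clipped to `[1e-12, 1-1e-12]` before forming Beta
  parameters; death indicators are validated to be exactly 0/1.
* The HPD ("shortest interval") implementation scans contiguous windows of
  `ceil(level·n)` order statistics; equal-tailed quantiles are the default
  for table reproduction since the published columns are labelled
  2.5%/97.5%, with HPD available everywhere.
* The dagger ("moderate effect") mark is operationalised as a sign
  probability in [0.90, 0.975) with an interval still containing zero; the
  band is configurable because the original mark was never defined.
* Posterior means at rare-event stages carry intrinsic skew bias; exact
  grid quadrature on simulated cohorts puts it at −0.1 to −0.2 logits for
  the stage intercepts and up to ~0.55 posterior SDs for treatment
  coefficients identified by only ~2–6 deaths (the adult stages, where the
  exposed arm sees no deaths at all in roughly a third of realisations).
  This is a property of the posterior mean under these event counts, not of
  the sampler: recovery experiments will flag those few coefficients as
  biased no matter how long the chain runs.
* With a single chain, ESS-based MC errors rely on within-chain mixing;
  run two chains for a split-chain check when in doubt.
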