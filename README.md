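# sublethal

Bayesian life-history analysis of **sublethal insecticide stress across two
generations** in the Colorado potato beetle (*Leptinotarsa decemlineata*),
packaged as a reusable, tested pipeline together with a synthetic-cohort
generator that emulates the original split-brood experiment — so every stage
of the inference can be validated by parameter recovery even though the raw
beetle data were never deposited.

## Who this is for

Ecotoxicologists and biostatisticians analysing stage-structured life-history
experiments with within- and transgenerational (maternal) treatments:
stage-conditional survival, development time, body mass and body-composition
outcomes, missing maternal covariates, and publication-style posterior
summaries (credible intervals, significance flags, survival odds ratios).

## The model

One joint model, factorised over outcome blocks:

* **Survival** at each life stage *s* (24 h exposure window, larval, pupal,
  adult), conditional on surviving earlier stages, with **death = 1**:

  `logit P(death_s) = β₀ + β_w·within + β_g·trans + β_m·maternal_mass (+ β_wg·within×trans)`

  so the survival odds ratio for a coefficient β is `exp(−β)`.
* **Development time**: `log(days) ~ Normal(Xγ, σ²)` (Jacobian included).
* **Body masses** (mg): `Normal(Xγ, σ²)`.
* **Lipid / water / dry-mass fractions**: `Beta(μφ, (1−μ)φ)` with
  `logit μ = Xγ`.

Missing maternal 10-day masses are imputed *inside* the MCMC sweep from the
gen-1 mass model (their prior) times the gen-2 likelihood terms they enter,
letting information flow between generations. The sampler is an adaptive
Metropolis-within-Gibbs with per-block covariance-learned proposals. After a
full fit, non-treatment interactions whose 95% interval contains zero are
dropped and the model refitted; treatment interactions are always kept.

See [`docs/methods.md`](docs/methods.md) for priors, adaptation, the
generator's assumptions and known limitations.

## Worked example

Simulate a cohort at the published design (245 gen-1 larvae, 14 sires × 4
dams, 842 offspring), fit the survival blocks, and report the maternal-
exposure effect on total larval survival:

```python
import sublethal as sl

params = sl.reference_parameters()          # published posterior means
individuals, families = sl.simulate_cohort(sl.CohortDesign(), params, seed=1)
frame = sl.cohort_to_frame(individuals)

draws = sl.sample_posterior(frame, sl.survival_specs(),
                            config=sl.McmcConfig.desk_scale(seed=1))
summary = sl.summarize(draws)
row = summary[summary.parameter == "g2_surv_larval:trans"].iloc[0]
print(f"trans coefficient: {row['mean']:.2f} "
      f"[{row['lo']:.2f}, {row['hi']:.2f}] flag={row['flag']}")

rep = sl.odds_ratio_summary(draws.param("g2_surv_larval:trans"), "survival")
print(f"survival OR (maternal exposure): {rep.point:.2f} "
      f"[{rep.lo:.2f}, {rep.hi:.2f}], P(OR>1)={rep.p_greater_1:.3f}")
```

```
trans coefficient: -0.57 [-0.99, -0.18] flag=star
survival OR (maternal exposure): 1.78 [1.20, 2.69], P(OR>1)=0.997
```

The cohort was simulated with the published transgenerational coefficient
−0.56, i.e. a true survival odds ratio of exp(0.56) ≈ 1.75 for offspring of
insecticide-exposed mothers: the fit recovers it (point estimate 1.78 with
95% interval [1.20, 2.69]; the star flag marks an interval excluding zero).
The same machinery is exposed on the command line:

```bash
sublethal simulate --seed 1 --out run/          # cohort.csv + design.yaml
sublethal fit --cohort run/cohort.csv --seed 1 --out run/
sublethal recover --seed 1 --out run/           # simulate-and-refit study
```

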