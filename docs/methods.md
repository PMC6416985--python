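# Methods

`recapture` estimates the size of a hidden population — people who
inject drugs (PWID) — from the overlap structure of four incomplete
administrative registries: a causes-of-death registry (DR), a police
misdemeanour registry (PB), and two classes of health-insurance claims
(overdose treatment, HIF-T; dependence treatment, HIF-F).  This note
describes the models, the synthetic data used to validate them, the
numerical choices, and the limits of what the test suite demonstrates.

## 1. Data model and linkage

Person-level extracts carry date of birth, sex, initials, an event date,
a county, and (for DR and PB) a registry-internal person identifier.
Records are linked deterministically by a composite study ID
`YYYYMMDD_S_II` (date of birth, sex, uppercased initials); the format is
a package convention, the linkage rule is not probabilistic.  Per
calendar year, each linked person contributes one capture history: four
binary indicators, age in completed years at July 1 (person-years
younger than 15 are excluded), and the county of the earliest-dated
record of the year, mapped to Harju / Ida-Viru / other.  Ties on the
event date are broken by a fixed source priority DR > PB > HIF-T >
HIF-F.  Where two people share a study ID within DR or PB (their
internal IDs distinguish them), both count in that source's totals but
only the person with the earliest event is cross-linked to the other
sources — cell totals are invariant to which one.  The insurance
registries have no internal identifier, so collisions there merge; the
synthetic generator exposes the collision rate through the initials
alphabet so this limitation is testable.  Events dated after a linked
person's death are dropped, and no history is produced after the death
year.

## 2. Contingency tables and censoring

Histories are aggregated per year into a 2^4 table of capture-pattern
counts, optionally stratified by sex × age group (15–44 / 45+) × county
(12 strata, 192 cells).  The all-zero pattern is structurally
unobservable and is stored explicitly as a missing cell.  Because the
police registry records many people who are not population members,
cells fed *only* by PB are treated as left-censored: the true member
count is at most the observed count, which is retained as the censoring
bound.  A bound of zero degenerately forces the true count to zero.

## 3. Maximum-likelihood estimator

The observed cells (censored cells included as-is — this estimator
deliberately ignores over-coverage) are fitted by Poisson log-linear
models with source main effects and a subset of the six pairwise source
interactions.  Backward elimination starts from all six interactions and
greedily drops the term whose removal lowers AIC most, stopping when no
drop helps; ties are broken by lexicographic term order, and exhaustive
enumeration of the 64-model space is available as a cross-check.  The
missing cell is predicted from the fitted model and added to the
observed total.  Confidence intervals use a log-normal approximation on
the predicted unobserved count (delta method on its log), keeping the
lower bound above the observed total.  A predicted unobserved count
below half a person collapses the interval to the observed total, with a
warning.  On two-source tables with independence terms the estimator
reduces exactly to Lincoln–Petersen n1·n2/m, which the tests assert to
numerical precision.

## 4. Bayesian model-averaged estimator

Three variants: (1) no censoring, no covariates; (2) censoring, no
covariates; (3) censoring and covariates.  The model space is all
hierarchical Poisson log-linear models between main effects only and
main effects plus all pairwise interactions — 2^6 = 64 models without
covariates, 2^21 with (all pairwise interactions among the seven
factors, including covariate×covariate ones; the lattice is restricted
to pairwise terms, so hierarchy reduces to "mains always present").

**Prior.**  The intercept has an improper flat prior.  All other design
columns are centred and receive the generalised hyper-g prior
β | σ², m ~ N(0, σ²·n·(X̃ᵀX̃)⁻¹) with σ² ~ Inverse-Gamma(a, b),
a = b = 10⁻³, where X̃ holds the centred non-intercept columns of model
m and n is the number of table cells.  Keeping the intercept out of the
shared scale is essential: it sits at log-cell-count magnitude, and
letting it inflate σ² makes the interaction priors arbitrarily diffuse,
which vetoes true dependence terms through a Lindley–Bartlett effect.
The model prior is uniform.

**Sampler.**  A Metropolis-within-Gibbs scheme:

1. *Data augmentation.*  Missing cells are drawn from Poisson(μ); each
   censored cell from a Poisson truncated at its bound, by vectorised
   rejection with an exact inverse-CDF fallback when the bound sits far
   below the mean.  Imputations respect the bound by hard assertion.
2. *Coefficients.*  A random-walk Metropolis step preconditioned by a
   fixed per-model Fisher estimate; a single global log step size is
   tuned toward 35% acceptance during burn-in only and frozen after.
3. *Scale.*  σ² is conjugate: Inverse-Gamma(a + p̃/2, b + β̃ᵀX̃ᵀX̃β̃/(2n)).
4. *Model move.*  A reversible jump adds or drops one interaction.  The
   destination model's full coefficient vector is proposed from a
   multivariate-t (df = 7) approximation centred at the Laplace mode of
   its conditional posterior given the current augmented data and σ².
   Because the penalised Poisson posterior is strictly log-concave, the
   mode is a unique function of (model, y, σ²); the IWLS fit that finds
   it is warm-started from the model's last mode purely as an
   accelerator.  Forward and reverse proposal densities are therefore
   exact and the acceptance ratio includes them, the prior normalising
   constants of both models, and the add/drop selection probabilities.
   For single-model (fixed-model) chains the same machinery runs as an
   independence refresh move, which removes most of the random-walk
   autocorrelation.

N is recorded every iteration as the sum of all true cell counts
(observed + imputed censored + imputed missing; per-stratum sums are
kept when stratified).  Summaries discard the first 10% of iterations:
the posterior median, the shortest-window 95% highest posterior density
interval (ties toward the lower window), model probabilities as visit
frequencies, and a posterior-predictive p-value — the fraction of
iterations in which replicated observed-cell data are more discrepant
(χ² = Σ(y−μ)²/μ over non-censored, non-missing cells) than the real
data.  A split-chain scale-reduction diagnostic on log N (threshold
1.05) can trigger re-running with a longer chain, by default in steps of
the original length up to three times it, mirroring the practice of
prolonging unconverged chains to a fixed cap.

**Validation.**  The sampler was checked three ways: (i) on a two-source
toy with a fixed model, the posterior mean of the missing cell matches
deterministic grid integration (σ² integrated analytically to a
multivariate-t prior) within 1%; (ii) on four-source tables, the
reversible-jump model-averaged abundance matches an independent
exhaustive 64-model enumeration (inner Laplace over β, outer quadrature
over σ²) to under 1% per dataset; (iii) the truncated-Poisson sampler
matches the analytic truncated pmf by χ² test at 10⁵ draws.

## 5. Synthetic data generator

The generator is first-class, tested code that defines the study
conditions for every downstream check.  A member's joint annual capture
pattern over the four sources is drawn from a log-linear model on the
2^4 pattern space, so pairwise interaction coefficients *are* log odds
ratios and the simulation truth lies inside the estimators' model class
— parameter recovery is then a sharp test.  Defaults:

* population 2,000 members per year (deaths are replaced by recruits),
  years 2010–2015;
* main effects giving annual member capture probabilities of roughly
  0.06 (DR), 0.11 (PB), 0.05 (HIF-T), 0.38 (HIF-F), which at N = 2000
  reproduce the order of magnitude of the real registries' counts;
* a sparse conditional dependence structure — HIF-T:HIF-F log 6,
  DR:HIF-T log 2.5, DR:PB log 1.6, PB:HIF-F log 1.3 — plus shared
  covariate capture gradients (health registries and mortality elevated
  in Ida-Viru, insurance claims elevated for women, mortality rising
  with age).  Together these put every pooled pairwise member odds ratio
  above 1 in the 1.05–7 range.  The structure is deliberately sparse:
  with six weak interactions no model-selection estimator can recover N
  at this scale (the probability limit of every plausible submodel is
  20–40% low), whereas under the sparse truth the infinite-data fit of
  the true model returns N exactly and plausible submodels sit 3–14%
  low;
* DR capture is death: other same-year events strictly precede the death
  date, and the person is removed from later years;
* over-coverage: contaminants appear in PB and only PB, with
  demographics from the same pools as members (so linkage cannot
  separate them); their number is derived from the target member
  fraction among PB captures, default 0.13 — i.e. 87% contamination;
* identities: date of birth consistent with the drawn age group at
  mid-year, two-letter initials from a configurable alphabet (collision
  rate control), optional collision-free mode for exact round-trip
  tests;
* an optional per-member frailty on all main effects, off by default —
  the estimation model has no such term, so the default keeps the
  generator inside the fitted class.

What the generator does **not** emulate: migration, diagnosis codes and
billing detail, within-year population turnover other than death,
secular trends in capture rates, and contamination of the three health
sources.  Passing recovery tests therefore demonstrate internal
consistency of generator + estimator under these idealised conditions,
not unbiasedness on real registries.

## 6. Dependence diagnostics, prevalence, rounding

Inter-registry dependence is screened with the three-source design: for
each choice of a "population" registry, the 2×2 table of the two
remaining "sampling" registries is formed within the population
registry's person-years; the single-binary-predictor logistic MLE equals
the cross-product odds ratio, reported with a Wald CI and a
Haldane–Anscombe 0.5 correction for zero cells (flagged).  Four
population choices × three pairs give twelve ratios, pooled over
2010–2015 by default with a per-year option.  Note that under heavy PB
over-coverage the within-PB ratios are inflated by design — contaminants
load the (0,0) cell — and conditioning on a small registry can push a
ratio below 1 (a collider effect); both are visible in the synthetic
diagnostics and are properties of the design, not defects.

Prevalence is 100·N̂ / (mid-year general population), with interval
endpoints transformed identically.  The packaged denominator file is a
synthetic stand-in (approximate mid-year populations to the nearest
thousand, aged 15+ and 15–44); any CSV with year, age band and
population columns is accepted.  Presentation values are rounded to the
nearest hundred, halves up.

## 7. Problem sizes used by the test suite

The suite favours fixed seeds and scales: recovery uses 50 replicates of
the one-year default conditions with 20,000-iteration chains; the
over-coverage contrast uses 3 replicates per variant; posterior
predictive calibration uses 100 replicates with 4,000-iteration chains;
the grid-integration check uses a 96³ grid and a 50,000-iteration chain.
The acceptance script runs the full six-year pipeline with
20,000-iteration chains per variant-year.  These lengths were chosen so
the whole suite runs on a single CPU in well under half an hour;
production analyses should use chains of 500,000 iterations as the
convergence-extension helper assumes.

## 8. Known limitations

* The measured small-sample behaviour of Bayesian model averaging at the
  default study conditions is conservative: weakly identified positive
  dependence terms are averaged out, so posterior medians of N sit
  roughly 15–20% below the truth and 95% HPDI coverage falls short of
  nominal (about 70% over 50 replicates of the default one-year
  conditions).  This is a property of
  the exact posterior — the reversible-jump results match exhaustive
  enumeration — and of the information content of four lists of this
  size, not a sampler artefact.  The over-coverage *contrast* is far
  larger than this bias (uncensored estimates are several-fold inflated),
  which is the substantive conclusion the pipeline supports.
* ML confidence intervals use a log-normal approximation; profile
  likelihood intervals are not implemented.
* The covariate model space treats county as a single 2-degree-of-freedom
  factor; interactions add or drop both columns together.
* Linkage assumes the composite identifier is error-free (no fuzzy
  matching), as the deterministic design requires.
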