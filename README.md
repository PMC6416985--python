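# recapture

Multiple systems estimation (capture-recapture) of a hidden
population's size from linked administrative registries, with explicit
handling of an **over-covered** source.

## The problem

How many people inject drugs in a country, when no survey can reach
them?  Four incomplete administrative lists each "capture" part of the
population every year: opioid-related deaths (DR), police drug
misdemeanours (PB), and health-insurance claims for overdose treatment
(HIF-T) and dependence treatment (HIF-F).  Linking the lists by a
composite identifier (date of birth, sex, initials) yields, per person
and calendar year, a capture pattern over the four sources; the overlap
structure identifies the number never captured.  The catch: most people
in the police list are *not* members of the target population — about
87% over-coverage — and ignoring that inflates the estimate several
fold.

## The models

Cell counts `y` of the stratified 2⁴ contingency table are Poisson with
log-linear means over source indicators (and optionally sex, age group
15–44/45+, and county):

* **ML estimator** — Poisson regression on the observed cells, backward
  AIC elimination over the six pairwise source interactions; the
  unobservable all-zero cell is predicted from the fit, with a
  log-normal confidence interval on the unobserved count.  On two
  sources this is exactly Lincoln–Petersen `n₁n₂/m`.
* **Bayesian estimator** — model averaging over all hierarchical
  log-linear models between main effects and all pairwise interactions,
  under a generalised hyper-g prior
  (`β | σ², m ~ N(0, σ²·n·(XᵀX)⁻¹)`, `σ² ~ IG(10⁻³, 10⁻³)`, flat
  intercept, centred columns), sampled by Metropolis-within-Gibbs with
  a reversible-jump move between models and data augmentation for the
  missing cells.  Cells fed only by the police source are treated as
  **left-censored** (true count ≤ observed), imputed from a truncated
  Poisson.  Three variants: (1) no censoring, no covariates; (2)
  censoring only; (3) censoring + covariates.
* A synthetic four-registry generator with known truth (log-linear
  joint capture model, death handling, demographic identities,
  injectable over-coverage) makes every stage testable end to end.

See `docs/methods.md` for the full model, sampler and validation
details.

## Worked example

```python
import recapture as rc
from recapture.bayes_estimator import sample_with_extension
from recapture.diagnostics_report import denominator_for

cfg = rc.SimulationConfig(true_population_size=2000, years=[2012], seed=42)
sim = rc.simulate_population(cfg)              # four extracts + truth
hist = rc.link_records(sim.extracts)           # person-year histories
flat = rc.build_contingency_table(hist, 2012)
strat = rc.build_contingency_table(hist, 2012, ("sex", "age_group", "county"))
cens_flat, cens_strat = (rc.mark_censored_cells(t) for t in (flat, strat))

fit = rc.backward_aic_selection(flat)
lo, hi = rc.ml_abundance_ci(fit)
print(rc.round_to_hundred(fit.abundance), rc.round_to_hundred(lo), rc.round_to_hundred(hi))

for variant, tab in ((1, cens_flat), (2, cens_flat), (3, cens_strat)):
    draws, report = sample_with_extension(tab, variant=variant, n_iter=20_000, seed=1)
    est = rc.bma_abundance(draws)
    print(variant, est.median, est.hpdi, rc.bayesian_p_value(draws))
```

Output (the simulated truth is 2,000 members; PB carries ~1,450
non-member contaminants):

```
person-year histories: 2516
ML:         N = 13300  (95% CI 11400-15700)
Bayesian 1: N = 12691 (95% HPDI 9619-14740), p = 0.45, chain 60000, rhat 1.045
Bayesian 2: N = 2478 (95% HPDI 1573-4595), p = 0.48, chain 60000, rhat 1.079
Bayesian 3: N = 2504 (95% HPDI 1662-4574), p = 0.48, chain 60000, rhat 1.110
prevalence (ages 15+): 0.23%
```

Reading it: the ML fit and the uncensored Bayesian variant swallow the
contaminated police counts whole and report ~13,000 — more than six
times the true population.  The censored variants treat the police-only
cells as upper bounds and recover the truth within their intervals; the
posterior-predictive p-values near 0.5 indicate adequate fit.  The
prevalence line divides the variant-3 median by the packaged mid-year
population denominator.

The same pipeline is scriptable from a shell:

```sh
recapture simulate --out data/
recapture link --extracts data/ --out hist.csv
recapture tabulate --histories hist.csv --year 2012 --covariates --out table.csv
recapture fit-ml   --table table.csv
recapture fit-bayes --table table.csv --variant 3 --iters 500000 --seed 1
recapture report --histories hist.csv --years 2010-2015 --out results/
```

Externally published capture-frequency tables (one row per year ×
gender × age group × county × pattern × count) can be ingested with
`rc.read_capture_frequencies` and fed to the same estimators.

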