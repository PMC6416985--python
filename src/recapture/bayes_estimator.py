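"""Bayesian model-averaged log-linear capture-recapture with censoring.

Cell counts of the (possibly stratified) 2^4 contingency table are
modelled as Poisson with log-linear means.  The model space runs from
the main-effects-only model to the model with all pairwise interactions
(among the four source indicators, and — when covariates are on — also
sex, age group and county); every model is hierarchical and contains all
main effects.  Coefficients carry a generalised hyper-g prior: the intercept gets an
improper flat prior, the design columns are centred, and

    beta_m | sigma^2, m  ~  N(0, sigma^2 * n * (X_m' X_m)^{-1}),
    sigma^2              ~  Inverse-Gamma(a, b),      a = b = 1e-3,

where X_m collects the centred non-intercept columns of model m and n is
the number of table cells, so the prior is unit-information at sigma^2 =
1 and the inverse-gamma layer makes it heavy-tailed.  Keeping the
intercept out of the shared scale matters: cell means put the intercept
at log-count magnitude, and letting it drive sigma^2 would make the
interaction priors arbitrarily diffuse and veto true dependence terms
(a Lindley-Bartlett effect).

Sampling is a Metropolis-within-Gibbs scheme with a reversible-jump move
across models:

1. data augmentation — the structurally missing all-zero cells are drawn
   from Poisson(mu), and left-censored cells (an over-covered source's
   "only" cells) from a truncated Poisson at their observed bound;
2. a random-walk Metropolis update of beta, preconditioned by a fixed
   per-model Fisher estimate, with a global step size tuned to a 30-50%
   acceptance rate during burn-in only;
3. a conjugate inverse-gamma Gibbs update of sigma^2;
4. a reversible-jump add/drop of one pairwise interaction: the whole
   coefficient vector of the destination model is proposed from a
   multivariate-t approximation centred at the Laplace mode of its
   conditional posterior, so forward and reverse proposal densities are
   available exactly; single-model chains use the same machinery as an
   independence refresh move.

The population size N is the sum of all true cell counts, recorded every
iteration; model-averaged summaries are medians and shortest-window 95%
highest posterior density intervals over post-burn-in draws, and fit is
checked by a posterior predictive chi-squared p-value.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from scipy.stats import poisson as poisson_dist

from .config import SOURCES
from .tabulation import (
    FLAG_CENSORED,
    FLAG_MISSING,
    StratifiedContingencyTable,
)

logger = logging.getLogger(__name__)

#: canonical factor order: the four sources, then the covariates
FACTOR_ORDER = (*SOURCES, "sex", "age_group", "county")

_ETA_MAX = 50.0  # cap on the linear predictor; exp(50) ~ 5e21


@dataclass
class PriorConfig:
    """Hyper-parameters of the generalised hyper-g prior.

    ``a`` and ``b`` are the shape and rate of the inverse-gamma prior on
    the coefficient scale sigma^2; the defaults 1e-3 are non-informative.
    The model prior is uniform over the hierarchical model space.
    """

    a: float = 1e-3
    b: float = 1e-3

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("prior parameters a and b must be positive")


@dataclass(frozen=True)
class ModelSpace:
    """Hierarchical log-linear model space between two nested extremes."""

    factors: tuple[str, ...]
    optional_terms: tuple[tuple[str, str], ...]

    @property
    def n_models(self) -> int:
        return 2 ** len(self.optional_terms)

    def models(self):
        """Iterate every model as a frozenset of optional terms."""
        for r in range(len(self.optional_terms) + 1):
            for combo in itertools.combinations(self.optional_terms, r):
                yield frozenset(combo)


def enumerate_model_space(covariates: bool = False) -> ModelSpace:
    """All hierarchical models from main effects to all pairwise interactions.

    With covariates off the factors are the four source indicators and
    there are 2^6 = 64 models; with covariates on, sex, age group and
    county join the factor list and every pairwise interaction among the
    seven factors is optional.
    """
    factors = FACTOR_ORDER if covariates else tuple(SOURCES)
    pairs = tuple(
        (factors[i], factors[j])
        for i in range(len(factors))
        for j in range(i + 1, len(factors))
    )
    return ModelSpace(factors=factors, optional_terms=pairs)


# ----------------------------------------------------------------------
# prior density (exposed for direct checks)


def log_prior(beta, sigma2: float, X, prior: PriorConfig | None = None) -> float:
    """Log density of (beta, sigma^2) under the generalised hyper-g prior.

    ``X`` is the full design matrix of the model (all table cells by all
    its columns).  Raises on a rank-deficient design, naming the
    offending columns.
    """
    prior = prior or PriorConfig()
    X = np.asarray(X, dtype=float)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    n, p = X.shape
    xtx = X.T @ X
    rank = np.linalg.matrix_rank(xtx)
    if rank < p:
        # columns whose removal restores full rank
        bad = []
        for j in range(p):
            keep = [k for k in range(p) if k != j]
            if np.linalg.matrix_rank(xtx[np.ix_(keep, keep)]) == rank:
                bad.append(j)
        raise np.linalg.LinAlgError(f"design matrix rank-deficient; collinear columns {bad}")
    sign, logdet = np.linalg.slogdet(xtx)
    quad = float(beta @ xtx @ beta)
    lp_beta = (
        -0.5 * p * math.log(2 * math.pi * sigma2 * n)
        + 0.5 * logdet
        - quad / (2 * n * sigma2)
    )
    a, b = prior.a, prior.b
    lp_sigma = a * math.log(b) - gammaln(a) - (a + 1) * math.log(sigma2) - b / sigma2
    return lp_beta + lp_sigma


# ----------------------------------------------------------------------
# truncated Poisson


def sample_truncated_poisson(mu: float, bound, rng: np.random.Generator) -> int:
    """Draw from Poisson(mu) conditioned on the value being <= bound.

    Uses rejection when the untruncated distribution already puts most
    of its mass below the bound, and exact inverse-CDF sampling on the
    renormalised pmf otherwise.  ``bound`` may be ``np.inf``.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    if np.isinf(bound):
        return int(rng.poisson(mu))
    bound = int(bound)
    if bound < 0:
        raise ValueError("bound must be a non-negative integer")
    if bound == 0:
        return 0
    if poisson_dist.cdf(bound, mu) >= 0.25:
        for _ in range(64):
            x = int(rng.poisson(mu))
            if x <= bound:
                return x
    # inverse CDF on the truncated support
    ks = np.arange(bound + 1)
    logpmf = ks * math.log(mu) - mu - gammaln(ks + 1)
    pmf = np.exp(logpmf - logpmf.max())
    cdf = np.cumsum(pmf)
    u = rng.random() * cdf[-1]
    return int(np.searchsorted(cdf, u))


# ----------------------------------------------------------------------
# draws containers


@dataclass
class PosteriorDraws:
    """Raw MCMC output of :func:`mcmc_sample`."""

    N: np.ndarray  # total abundance per iteration
    sigma2: np.ndarray
    model_index: np.ndarray
    chi2_obs: np.ndarray
    chi2_rep: np.ndarray
    model_catalog: list  # index -> sorted tuple of optional terms
    n_iter: int
    burn_in: float
    variant: int
    seed: int
    accept_beta: float
    accept_rj: float
    n_observed: int  # total over observed (non-censored) cells
    strata_labels: list | None = None
    N_strata: np.ndarray | None = None  # (n_iter, n_strata) when stratified

    @property
    def n_burn(self) -> int:
        return int(self.burn_in * self.n_iter)

    def post_burn(self, arr: np.ndarray) -> np.ndarray:
        return arr[self.n_burn :]


@dataclass
class AbundanceEstimate:
    """Model-averaged posterior summary of the population size."""

    median: float
    hpdi: tuple[float, float]
    p_value: float | None
    acceptance_rate: float
    chain_length: int
    variant: int
    model_probabilities: dict = field(default_factory=dict)
    mean: float | None = None


def hpdi(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Shortest window containing ``level`` of the sorted draws.

    Ties in window width are broken toward the lower window.
    """
    x = np.sort(np.asarray(draws, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("no draws")
    k = max(1, int(np.ceil(level * n)))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


# ----------------------------------------------------------------------
# sampler internals


class _Problem:
    """Precomputed table geometry and design column blocks."""

    def __init__(self, table, variant: int):
        if variant not in (1, 2, 3):
            raise ValueError("variant must be 1, 2 or 3")
        if isinstance(table, StratifiedContingencyTable):
            if variant == 3:
                if not table.strata:
                    raise ValueError("variant 3 needs a covariate-stratified table")
            elif table.strata:
                table = table.collapse()
            cells = table.cells
            strata = table.strata if variant == 3 else ()
        else:
            cells = table
            strata = tuple(c for c in ("sex", "age_group", "county") if c in table.columns)
            if variant != 3:
                strata = ()
        self.cells = cells.reset_index(drop=True)
        self.variant = variant
        self.strata = strata
        self.n_cells = len(self.cells)
        self.sources = tuple(s for s in SOURCES if s in self.cells.columns)

        flag = self.cells["flag"].to_numpy()
        self.is_missing = flag == FLAG_MISSING
        self.is_censored = (flag == FLAG_CENSORED) if variant >= 2 else np.zeros(
            self.n_cells, bool
        )
        self.is_obs = ~self.is_missing & ~self.is_censored
        counts = self.cells["count"].to_numpy(dtype=float)
        self.y_obs = np.where(self.is_missing, 0.0, counts)
        self.bounds = counts[self.is_censored].astype(int)
        self.n_observed = int(self.y_obs[self.is_obs].sum())

        # design column blocks keyed by term
        blocks: dict = {"__intercept__": np.ones((self.n_cells, 1))}
        for s in self.sources:
            blocks[s] = self.cells[s].to_numpy(dtype=float)[:, None]
        if variant == 3:
            if "sex" in strata:
                blocks["sex"] = (self.cells["sex"] == "F").to_numpy(float)[:, None]
            if "age_group" in strata:
                blocks["age_group"] = (self.cells["age_group"] == "45+").to_numpy(float)[
                    :, None
                ]
            if "county" in strata:
                blocks["county"] = np.column_stack(
                    [
                        (self.cells["county"] == "Ida-Viru").to_numpy(float),
                        (self.cells["county"] == "other").to_numpy(float),
                    ]
                )
        self.factors = tuple(f for f in FACTOR_ORDER if f in blocks)
        self.main_terms = ["__intercept__"] + list(self.factors)
        self.optional_terms = tuple(
            (self.factors[i], self.factors[j])
            for i in range(len(self.factors))
            for j in range(i + 1, len(self.factors))
        )
        for fa, fb in self.optional_terms:
            A, B = blocks[fa], blocks[fb]
            prod = np.einsum("ni,nj->nij", A, B).reshape(self.n_cells, -1)
            blocks[(fa, fb)] = prod
        # centre every non-intercept column (products are formed from the
        # raw indicators first); the intercept then carries the scale and
        # stays outside the g-prior
        for t, B in blocks.items():
            if t != "__intercept__":
                blocks[t] = B - B.mean(axis=0)
        self.blocks = blocks

        if strata:
            key = self.cells[list(strata)].astype(str).agg("|".join, axis=1)
            self.strata_labels = sorted(key.unique())
            self.strata_index = key.map(
                {lab: i for i, lab in enumerate(self.strata_labels)}
            ).to_numpy()
        else:
            self.strata_labels = None
            self.strata_index = None

    def model_terms(self, active: frozenset) -> list:
        return self.main_terms + [t for t in self.optional_terms if t in active]

    def design(self, active: frozenset) -> np.ndarray:
        return np.concatenate(
            [self.blocks[t] for t in self.model_terms(active)], axis=1
        )

    def term_slices(self, active: frozenset) -> dict:
        slices = {}
        start = 0
        for t in self.model_terms(active):
            w = self.blocks[t].shape[1]
            slices[t] = slice(start, start + w)
            start += w
        return slices


class _ModelCache:
    """Per-model design products and fixed proposal preconditioners."""

    def __init__(self, problem: _Problem, w0: np.ndarray):
        self.problem = problem
        self.w0 = w0  # fixed Fisher weights for the beta proposal
        self._store: dict = {}

    def get(self, active: frozenset) -> dict:
        key = frozenset(active)
        if key not in self._store:
            X = self.problem.design(key)
            n = self.problem.n_cells
            xtx = X.T @ X
            # flat prior on the intercept: only the centred non-intercept
            # block enters the g-prior precision
            prior_prec = np.zeros_like(xtx)
            prior_prec[1:, 1:] = xtx[1:, 1:]
            sign, logdet = np.linalg.slogdet(xtx[1:, 1:]) if X.shape[1] > 1 else (1.0, 0.0)
            if sign <= 0:
                raise np.linalg.LinAlgError("rank-deficient model design")
            fisher = (X * self.w0[:, None]).T @ X + prior_prec / n
            cov = np.linalg.inv(fisher)
            cov = (cov + cov.T) / 2
            self._store[key] = {
                "X": X,
                "xtx": xtx,
                "prior_prec": prior_prec,
                "logdet_prior": logdet,
                "chol_prop": np.linalg.cholesky(cov),
                "p": X.shape[1],
                "p_prior": X.shape[1] - 1,
                "slices": self.problem.term_slices(key),
            }
        return self._store[key]


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    eta = np.minimum(eta, _ETA_MAX)
    return float(y @ eta - np.exp(eta).sum())


def _log_prior_beta(beta: np.ndarray, info: dict, sigma2: float, n: int) -> float:
    # flat intercept (constant, identical across models) plus the g-prior
    # normal density of the non-intercept coefficients
    quad = float(beta @ info["prior_prec"] @ beta)
    return (
        -0.5 * info["p_prior"] * math.log(2 * math.pi * sigma2 * n)
        + 0.5 * info["logdet_prior"]
        - quad / (2 * n * sigma2)
    )


def _ridge_irls(X: np.ndarray, y: np.ndarray, pen: np.ndarray, n_iter: int = 50) -> np.ndarray:
    """Poisson IRLS with a Gaussian precision penalty (for initialisation)."""
    beta = np.zeros(X.shape[1])
    beta[0] = math.log(max(y.mean(), 0.1))
    for _ in range(n_iter):
        eta = np.minimum(X @ beta, _ETA_MAX)
        mu = np.exp(eta)
        H = (X * mu[:, None]).T @ X + pen
        g = X.T @ (y - mu) - pen @ beta
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta


def mcmc_sample(
    table,
    variant: int = 3,
    prior: PriorConfig | None = None,
    n_iter: int = 500_000,
    seed: int = 0,
    burn_in: float = 0.10,
    fixed_model: frozenset | None = None,
    rj_every: int = 1,
) -> PosteriorDraws:
    """Run the Metropolis-within-Gibbs sampler on one contingency table.

    Parameters
    ----------
    table
        A :class:`StratifiedContingencyTable` (stratified for variant 3,
        collapsed otherwise) or a plain cell DataFrame.
    variant
        1 — censored cells treated as fully observed, no covariates;
        2 — censoring respected, no covariates;
        3 — censoring respected, covariates in the model.
    prior
        Hyper-g prior configuration (defaults a = b = 1e-3).
    n_iter
        Total iterations; the first ``burn_in`` fraction is discarded by
        the summary functions and used to tune the step size.
    seed
        Root seed; identical inputs give an identical draw sequence.
    fixed_model
        Restrict the chain to a single model (a frozenset of optional
        pairwise terms); disables the reversible-jump move.

    Returns
    -------
    PosteriorDraws with the abundance N recorded at every iteration.
    """
    prior = prior or PriorConfig()
    problem = _Problem(table, variant)
    n = problem.n_cells
    rng = np.random.default_rng(seed)

    if problem.y_obs[problem.is_obs].sum() == 0:
        raise ValueError("table has no observed counts; refusing to estimate")

    # initial fit on fully observed cells only (mains-only model)
    active = frozenset() if fixed_model is None else frozenset(fixed_model)
    X_init = problem.design(frozenset())
    obs = problem.is_obs
    beta0 = _ridge_irls(
        X_init[obs], problem.y_obs[obs], X_init.T @ X_init / n
    )
    mu0 = np.exp(np.minimum(X_init @ beta0, _ETA_MAX))
    cache = _ModelCache(problem, w0=mu0)

    info = cache.get(active)
    X = info["X"]
    beta = _ridge_irls(X[obs], problem.y_obs[obs], info["xtx"] / n)
    sigma2 = 1.0
    y = problem.y_obs.copy()
    y[problem.is_censored] = np.minimum(problem.bounds, np.round(mu0[problem.is_censored]))
    y[problem.is_missing] = np.round(mu0[problem.is_missing])

    eta = np.minimum(X @ beta, _ETA_MAX)

    do_rj = fixed_model is None and len(problem.optional_terms) > 0
    n_burn = int(burn_in * n_iter)
    log_step = math.log(2.38 / math.sqrt(max(info["p"], 1)))
    target_acc = 0.35

    N_draws = np.empty(n_iter)
    sigma2_draws = np.empty(n_iter)
    model_draws = np.empty(n_iter, dtype=np.int32)
    chi2_obs_draws = np.empty(n_iter)
    chi2_rep_draws = np.empty(n_iter)
    model_catalog: list = []
    model_ids: dict = {}
    if problem.strata_labels is not None:
        N_strata = np.empty((n_iter, len(problem.strata_labels)), dtype=np.float32)
    else:
        N_strata = None

    acc_beta = acc_rj = n_rj = 0
    cens_idx = np.flatnonzero(problem.is_censored)
    miss_idx = np.flatnonzero(problem.is_missing)
    obs_idx = np.flatnonzero(problem.is_obs)
    y_obs_vec = problem.y_obs[obs_idx]

    for it in range(n_iter):
        mu = np.exp(np.minimum(eta, _ETA_MAX))

        # -- 1. data augmentation ------------------------------------
        if len(miss_idx):
            y[miss_idx] = rng.poisson(np.maximum(mu[miss_idx], 1e-12))
        if len(cens_idx):
            mu_c = np.maximum(mu[cens_idx], 1e-12)
            draws = rng.poisson(mu_c)
            bad = draws > problem.bounds
            for _ in range(16):  # vectorised rejection; almost always done in 1-2 rounds
                if not bad.any():
                    break
                draws[bad] = rng.poisson(mu_c[bad])
                bad = draws > problem.bounds
            for j in np.flatnonzero(bad):  # rare: bound far below the mean
                draws[j] = sample_truncated_poisson(mu_c[j], problem.bounds[j], rng)
            assert (draws <= problem.bounds).all()
            y[cens_idx] = draws
        ll = _loglik(y, eta)

        # -- 2. beta random-walk Metropolis ---------------------------
        L = info["chol_prop"]
        prop = beta + math.exp(log_step) * (L @ rng.standard_normal(info["p"]))
        eta_prop = X @ prop
        ll_prop = _loglik(y, eta_prop)
        dquad = float(
            prop @ info["prior_prec"] @ prop - beta @ info["prior_prec"] @ beta
        )
        log_alpha = ll_prop - ll - dquad / (2 * n * sigma2)
        accepted = math.log(rng.random()) < log_alpha
        if accepted:
            beta, eta, ll = prop, np.minimum(eta_prop, _ETA_MAX), ll_prop
            acc_beta += 1
        if it < n_burn:
            log_step += 2.0 / math.sqrt(it + 1.0) * (
                (1.0 if accepted else 0.0) - target_acc
            ) * 0.1

        # -- 3. sigma^2 Gibbs ----------------------------------------
        quad = float(beta @ info["prior_prec"] @ beta)
        shape = prior.a + info["p_prior"] / 2.0
        rate = prior.b + quad / (2.0 * n)
        sigma2 = rate / rng.gamma(shape)

        # -- 4. reversible jump / independence refresh ---------------
        if do_rj and (it % rj_every == 0):
            n_rj += 1
            jumped, active, info, X, beta, eta, ll = _rj_move(
                problem, cache, rng, y, active, info, X, beta, eta, ll, sigma2, prior
            )
            if jumped:
                acc_rj += 1
        elif fixed_model is not None:
            # single-model chains: an independence Metropolis move from the
            # Laplace approximation breaks the random-walk autocorrelation
            centre, Lc, logdet = _laplace_fit(info, y, sigma2, n)
            prop = _laplace_draw(centre, Lc, rng)
            eta_prop = X @ prop
            ll_prop = _loglik(y, eta_prop)
            dlp = _log_prior_beta(prop, info, sigma2, n) - _log_prior_beta(
                beta, info, sigma2, n
            )
            dq = _laplace_logq(beta, centre, Lc, logdet) - _laplace_logq(
                prop, centre, Lc, logdet
            )
            if math.log(rng.random()) < ll_prop - ll + dlp + dq:
                beta, eta, ll = prop, np.minimum(eta_prop, _ETA_MAX), ll_prop

        # -- 5. record ------------------------------------------------
        N_draws[it] = y.sum()
        sigma2_draws[it] = sigma2
        key = frozenset(active)
        if key not in model_ids:
            model_ids[key] = len(model_catalog)
            model_catalog.append(tuple(sorted(key)))
        model_draws[it] = model_ids[key]
        mu_obs = np.exp(np.minimum(eta[obs_idx], _ETA_MAX))
        mu_obs = np.maximum(mu_obs, 1e-12)
        chi2_obs_draws[it] = float(((y_obs_vec - mu_obs) ** 2 / mu_obs).sum())
        y_rep = rng.poisson(mu_obs)
        chi2_rep_draws[it] = float(((y_rep - mu_obs) ** 2 / mu_obs).sum())
        if N_strata is not None:
            N_strata[it] = np.bincount(
                problem.strata_index, weights=y, minlength=len(problem.strata_labels)
            )

    post = slice(n_burn, None)
    n_post = n_iter - n_burn
    acc_rate = acc_beta / n_iter
    if not (0.05 < acc_rate < 0.95):
        logger.warning("beta acceptance rate %.2f outside (0.05, 0.95)", acc_rate)
    return PosteriorDraws(
        N=N_draws,
        sigma2=sigma2_draws,
        model_index=model_draws,
        chi2_obs=chi2_obs_draws,
        chi2_rep=chi2_rep_draws,
        model_catalog=model_catalog,
        n_iter=n_iter,
        burn_in=burn_in,
        variant=variant,
        seed=seed,
        accept_beta=acc_rate,
        accept_rj=(acc_rj / n_rj) if n_rj else float("nan"),
        n_observed=problem.n_observed,
        strata_labels=problem.strata_labels,
        N_strata=N_strata,
    )


def _laplace_fit(info: dict, y: np.ndarray, sigma2: float, n: int):
    """Deterministic Laplace centre of p(beta | y, sigma^2, m).

    Initialised from the data only (not the chain state), so the implied
    proposal density depends on (model, y, sigma^2) alone, which keeps
    the trans-model kernel reversible.  Returns the mode, the Cholesky
    factor of the precision, and the log determinant of the precision.
    """
    X = info["X"]
    pr = info["prior_prec"] / (n * sigma2)
    p = info["p"]
    # the penalised Poisson log-posterior is strictly concave, so the mode
    # is unique and independent of the start; warm-starting from the last
    # mode seen for this model only saves Newton steps
    warm = info.get("warm")
    if warm is not None:
        beta = warm.copy()
    else:
        beta = np.zeros(p)
        beta[0] = math.log(max(y.mean(), 0.1))
    for _ in range(40):
        eta = np.minimum(X @ beta, _ETA_MAX)
        mu = np.exp(eta)
        H = (X * mu[:, None]).T @ X + pr
        g = X.T @ (y - mu) - pr @ beta
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        # dampen to keep the update stable when far from the mode
        nstep = float(np.max(np.abs(step)))
        if nstep > 3.0:
            step *= 3.0 / nstep
        beta = beta + step
        if nstep < 3e-8:
            break
    eta = np.minimum(X @ beta, _ETA_MAX)
    mu = np.exp(eta)
    H = (X * mu[:, None]).T @ X + pr
    L = np.linalg.cholesky(H)
    logdet_H = 2.0 * float(np.log(np.diag(L)).sum())
    info["warm"] = beta.copy()
    return beta, L, logdet_H


_PROPOSAL_DF = 7.0  # multivariate-t proposals: heavy enough tails to avoid
#                     independence-sampler stickiness in the skewed posterior


def _laplace_draw(centre: np.ndarray, L: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    p = len(centre)
    z = rng.standard_normal(p)
    g = rng.chisquare(_PROPOSAL_DF)
    return centre + np.linalg.solve(L.T, z) / math.sqrt(g / _PROPOSAL_DF)


def _laplace_logq(beta: np.ndarray, centre: np.ndarray, L: np.ndarray, logdet_H: float) -> float:
    dev = L.T @ (beta - centre)
    p = len(beta)
    df = _PROPOSAL_DF
    return (
        gammaln((df + p) / 2.0)
        - gammaln(df / 2.0)
        - 0.5 * p * math.log(df * math.pi)
        + 0.5 * logdet_H
        - 0.5 * (df + p) * math.log1p(float(dev @ dev) / df)
    )


def _rj_move(problem, cache, rng, y, active, info, X, beta, eta, ll, sigma2, prior):
    """One reversible jump between neighbouring hierarchical models.

    An add/drop of a single pairwise interaction is proposed; the entire
    coefficient vector of the destination model is drawn from a Laplace
    (Gaussian) approximation to its conditional posterior given the
    current augmented data and sigma^2.  Because the approximation is
    centred by a deterministic, state-independent fit, the forward and
    reverse proposal densities are both available in closed form.
    """
    n = problem.n_cells
    addable = [t for t in problem.optional_terms if t not in active]
    droppable = len(active)
    p_add = 0.5 if (addable and droppable) else (1.0 if addable else 0.0)
    go_add = rng.random() < p_add

    if go_add:
        term = addable[rng.integers(len(addable))]
        new_active = frozenset(active | {term})
        n_add, n_drop_new = len(addable), len(new_active)
        p_rev = 0.5 if len(problem.optional_terms) > n_drop_new else 1.0
        log_j = math.log(p_rev / n_drop_new) - math.log(p_add / n_add)
    else:
        if not droppable:
            return False, active, info, X, beta, eta, ll
        drop_list = sorted(active)
        term = drop_list[rng.integers(len(drop_list))]
        new_active = frozenset(active - {term})
        p_drop = 1.0 - p_add if addable else 1.0
        n_add_new = len(problem.optional_terms) - len(new_active)
        p_rev = 0.5 if len(new_active) else 1.0
        log_j = math.log(p_rev / n_add_new) - math.log(p_drop / droppable)

    info_new = cache.get(new_active)
    centre_new, L_new, logdet_new = _laplace_fit(info_new, y, sigma2, n)
    beta_new = _laplace_draw(centre_new, L_new, rng)
    eta_new = info_new["X"] @ beta_new
    ll_new = _loglik(y, eta_new)
    lp_new = _log_prior_beta(beta_new, info_new, sigma2, n)
    lp_old = _log_prior_beta(beta, info, sigma2, n)
    log_q_fwd = _laplace_logq(beta_new, centre_new, L_new, logdet_new)
    centre_old, L_old, logdet_old = _laplace_fit(info, y, sigma2, n)
    log_q_rev = _laplace_logq(beta, centre_old, L_old, logdet_old)
    log_alpha = (ll_new + lp_new) - (ll + lp_old) + log_j + log_q_rev - log_q_fwd
    if math.log(rng.random()) < log_alpha:
        return True, new_active, info_new, info_new["X"], beta_new, np.minimum(
            eta_new, _ETA_MAX
        ), ll_new
    return False, active, info, X, beta, eta, ll


# ----------------------------------------------------------------------
# summaries


def bma_abundance(
    draws: PosteriorDraws, level: float = 0.95, min_draws: int = 1000
) -> AbundanceEstimate:
    """Model-averaged posterior median and shortest-window HPDI of N.

    Model posterior probabilities are reversible-jump visit frequencies
    over the post-burn-in draws and sum to one.
    """
    N = draws.post_burn(draws.N)
    if len(N) < min_draws:
        raise ValueError(f"only {len(N)} post-burn-in draws; need >= {min_draws}")
    median = float(np.median(N))
    lo, hi = hpdi(N, level)
    if not (lo <= median <= hi):
        logger.warning("median outside the HPDI; posterior may be multimodal")
    models = draws.post_burn(draws.model_index)
    counts = np.bincount(models, minlength=len(draws.model_catalog))
    probs = counts / counts.sum()
    model_probs = {
        draws.model_catalog[i]: float(probs[i])
        for i in np.argsort(-probs)
        if probs[i] > 0
    }
    return AbundanceEstimate(
        median=median,
        hpdi=(lo, hi),
        p_value=None,
        acceptance_rate=draws.accept_beta,
        chain_length=draws.n_iter,
        variant=draws.variant,
        model_probabilities=model_probs,
        mean=float(np.mean(N)),
    )


def bayesian_p_value(draws: PosteriorDraws) -> float:
    """Posterior predictive p-value from the chi-squared discrepancy.

    The fraction of post-burn-in iterations in which replicated data are
    more discrepant from the current fit than the observed data are;
    censored and missing cells are excluded from the discrepancy sum.
    """
    rep = draws.post_burn(draws.chi2_rep)
    obs = draws.post_burn(draws.chi2_obs)
    return float(np.mean(rep >= obs))


@dataclass
class ConvergenceReport:
    rhat: float
    converged: bool
    threshold: float
    recommended_extension: int
    capped: bool


def split_rhat(x: np.ndarray, n_splits: int = 4) -> float:
    """Potential scale reduction over equal segments of one chain."""
    x = np.asarray(x, dtype=float)
    m = n_splits
    seg = len(x) // m
    if seg < 2:
        return float("nan")
    chains = x[: seg * m].reshape(m, seg)
    means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    B = seg * means.var(ddof=1)
    if W <= 0:
        return 1.0
    var_hat = (seg - 1) / seg * W + B / seg
    return float(math.sqrt(var_hat / W))


def convergence_check(
    draws: PosteriorDraws,
    threshold: float = 1.05,
    extend_by: int = 500_000,
    max_total: int = 1_500_000,
) -> ConvergenceReport:
    """Split-chain scale-reduction diagnostic on log N.

    If the diagnostic exceeds ``threshold`` the report recommends
    extending the chain by ``extend_by`` iterations, honouring the cap
    ``max_total`` on total chain length.
    """
    logN = np.log(np.maximum(draws.post_burn(draws.N), 1.0))
    rhat = split_rhat(logN)
    converged = not (np.isfinite(rhat) and rhat > threshold)
    extension = 0
    capped = False
    if not converged:
        room = max_total - draws.n_iter
        extension = min(extend_by, max(room, 0))
        capped = extension < extend_by
    return ConvergenceReport(
        rhat=rhat,
        converged=converged,
        threshold=threshold,
        recommended_extension=extension,
        capped=capped,
    )


def sample_with_extension(
    table,
    variant: int,
    prior: PriorConfig | None = None,
    n_iter: int = 500_000,
    seed: int = 0,
    threshold: float = 1.05,
    extend_by: int | None = None,
    max_total: int | None = None,
    **kwargs,
) -> tuple[PosteriorDraws, ConvergenceReport]:
    """Run the sampler, re-running longer while the diagnostic fails.

    The chain is extended in steps of ``extend_by`` (default: the
    initial length) up to ``max_total`` (default: three times the
    initial length), mirroring the practice of prolonging unconverged
    chains up to a fixed cap.
    """
    extend_by = extend_by or n_iter
    max_total = max_total or 3 * n_iter
    total = n_iter
    while True:
        draws = mcmc_sample(table, variant=variant, prior=prior, n_iter=total, seed=seed, **kwargs)
        report = convergence_check(
            draws, threshold=threshold, extend_by=extend_by, max_total=max_total
        )
        if report.converged or report.recommended_extension == 0:
            return draws, report
        total += report.recommended_extension
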