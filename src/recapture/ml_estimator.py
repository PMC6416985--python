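"""Maximum-likelihood Poisson log-linear capture-recapture.

The observed cells of a 2^k contingency table (censored cells treated as
fully observed — this estimator deliberately ignores over-coverage) are
fitted by a Poisson log-linear model with source indicators as main
effects and an optional subset of the pairwise source interactions.
The structurally missing all-zero cell is predicted from the fitted
model and added to the observed total to give the abundance estimate;
backward elimination over the interaction terms picks the model with the
lowest AIC.  On a two-source table with independence terms this is
exactly the Lincoln-Petersen estimator n1*n2/m.

Confidence intervals use a log-normal approximation on the estimated
number of unobserved people (delta method on the log of the predicted
missing count), which keeps the lower bound above the observed total.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .config import SOURCES
from .tabulation import FLAG_MISSING, StratifiedContingencyTable

logger = logging.getLogger(__name__)

ALL_PAIRS: tuple[tuple[str, str], ...] = tuple(
    (SOURCES[i], SOURCES[j]) for i in range(4) for j in range(i + 1, 4)
)


@dataclass
class MLFit:
    """A fitted Poisson log-linear model and its abundance estimate."""

    sources: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...]
    coefficients: pd.Series
    cov_params: pd.DataFrame
    fitted: np.ndarray  # means of the observed cells, in cell order
    deviance: float
    aic: float
    n_observed: int
    missing_estimate: float
    se_log_missing: float
    converged: bool
    aic_trace: list = field(default_factory=list)

    @property
    def abundance(self) -> float:
        return self.n_observed + self.missing_estimate


def _as_cells(table) -> pd.DataFrame:
    if isinstance(table, StratifiedContingencyTable):
        if table.strata:
            table = table.collapse()
        return table.cells
    return table


def marginalize_sources(table, keep: tuple[str, ...]) -> pd.DataFrame:
    """Reduce a table to a subset of sources.

    A person is observed in the reduced study only if captured by a kept
    source; cells whose kept-pattern is all zero are pooled into the
    structurally missing cell, exactly as if the dropped sources had
    never been consulted.
    """
    cells = _as_cells(table)
    keep = tuple(keep)
    for s in keep:
        if s not in SOURCES:
            raise ValueError(f"unknown source {s!r}")
    obs = cells[cells["flag"] != FLAG_MISSING]
    grouped = obs.groupby(list(keep), sort=False)["count"].sum().reset_index()
    grid = pd.DataFrame(
        [[(p >> i) & 1 for i in range(len(keep))] for p in range(2 ** len(keep))],
        columns=list(keep),
    )
    grid = grid.merge(grouped, on=list(keep), how="left")
    grid["count"] = grid["count"].fillna(0.0)
    zero = grid[list(keep)].sum(axis=1) == 0
    grid.loc[zero, "count"] = np.nan
    grid["flag"] = np.where(zero, FLAG_MISSING, "observed")
    return grid


def _design(cells: pd.DataFrame, sources, interactions) -> pd.DataFrame:
    X = pd.DataFrame({"intercept": np.ones(len(cells))}, index=cells.index)
    for s in sources:
        X[s] = cells[s].to_numpy(dtype=float)
    for a, b in interactions:
        X[f"{a}:{b}"] = (cells[a] * cells[b]).to_numpy(dtype=float)
    return X


def fit_poisson_loglinear(
    table,
    interactions: tuple[tuple[str, str], ...] = (),
    sources: tuple[str, ...] | None = None,
) -> MLFit:
    """Fit one Poisson log-linear model to the observed cells.

    ``table`` is an unstratified :class:`StratifiedContingencyTable` (a
    stratified one is collapsed first) or a cell DataFrame from
    :func:`marginalize_sources`.  ``interactions`` lists pairwise source
    interaction terms; main effects for every source are always present.
    """
    cells = _as_cells(table)
    sources = tuple(sources) if sources is not None else tuple(
        s for s in SOURCES if s in cells.columns
    )
    interactions = tuple(tuple(p) for p in interactions)
    for a, b in interactions:
        if a not in sources or b not in sources:
            raise ValueError(f"interaction ({a}, {b}) outside sources {sources}")
    obs = cells[cells["flag"] != FLAG_MISSING]
    miss = cells[cells["flag"] == FLAG_MISSING]
    y = obs["count"].to_numpy(dtype=float)

    converged = True
    for s in sources:
        if (y * obs[s].to_numpy()).sum() == 0:
            logger.warning("source %s has a zero margin; fit flagged", s)
            converged = False

    X = _design(obs, sources, interactions)
    model = sm.GLM(y, X, family=sm.families.Poisson())
    try:
        res = model.fit(maxiter=200, tol=1e-10)
        converged = converged and bool(res.converged)
    except Exception as err:  # zero margins can break IRLS outright
        logger.warning("Poisson fit failed (%s)", err)
        beta = pd.Series(np.zeros(X.shape[1]), index=X.columns)
        return MLFit(
            sources=sources,
            interactions=interactions,
            coefficients=beta,
            cov_params=pd.DataFrame(
                np.full((X.shape[1],) * 2, np.nan), index=X.columns, columns=X.columns
            ),
            fitted=np.full(len(obs), np.nan),
            deviance=np.nan,
            aic=np.inf,
            n_observed=int(np.nansum(y)),
            missing_estimate=np.nan,
            se_log_missing=np.nan,
            converged=False,
        )

    X0 = _design(miss, sources, interactions)
    mu0 = np.exp(X0.to_numpy() @ res.params.to_numpy())
    missing_estimate = float(mu0.sum())
    if missing_estimate > 0:
        grad = (mu0[:, None] * X0.to_numpy()).sum(axis=0) / missing_estimate
        se_log = float(np.sqrt(grad @ res.cov_params().to_numpy() @ grad))
    else:
        se_log = np.nan
    return MLFit(
        sources=sources,
        interactions=interactions,
        coefficients=res.params,
        cov_params=res.cov_params(),
        fitted=np.asarray(res.fittedvalues, dtype=float),
        deviance=float(res.deviance),
        aic=float(res.aic),
        n_observed=int(y.sum()),
        missing_estimate=missing_estimate,
        se_log_missing=se_log,
        converged=converged,
    )


def backward_aic_selection(
    table, sources: tuple[str, ...] | None = None
) -> MLFit:
    """Greedy backward elimination of pairwise interactions by AIC.

    Starts from the model with all pairwise interactions; at each step
    the single interaction whose removal lowers AIC the most is dropped
    (ties broken by lexicographic term order); stops when no removal
    lowers AIC.  If the full model fails to fit, falls back to the
    main-effects model (flagged unconverged).
    """
    cells = _as_cells(table)
    srcs = tuple(sources) if sources is not None else tuple(
        s for s in SOURCES if s in cells.columns
    )
    pairs = tuple(p for p in ALL_PAIRS if p[0] in srcs and p[1] in srcs)
    current = fit_poisson_loglinear(cells, pairs, srcs)
    trace = [(current.interactions, current.aic)]
    if not np.isfinite(current.aic):
        logger.warning("full model failed; falling back to main effects")
        fallback = fit_poisson_loglinear(cells, (), srcs)
        fallback.converged = False
        fallback.aic_trace = trace + [((), fallback.aic)]
        return fallback
    while current.interactions:
        candidates = []
        for drop in sorted(current.interactions):
            remaining = tuple(p for p in current.interactions if p != drop)
            fit = fit_poisson_loglinear(cells, remaining, srcs)
            candidates.append((fit.aic, drop, fit))
        best_aic, _, best_fit = min(candidates, key=lambda t: (t[0], t[1]))
        if best_aic < current.aic:
            current = best_fit
            trace.append((current.interactions, current.aic))
        else:
            break
    current.aic_trace = trace
    return current


def exhaustive_aic_selection(
    table, sources: tuple[str, ...] | None = None
) -> MLFit:
    """Minimum-AIC model over all subsets of the pairwise interactions."""
    cells = _as_cells(table)
    srcs = tuple(sources) if sources is not None else tuple(
        s for s in SOURCES if s in cells.columns
    )
    pairs = tuple(p for p in ALL_PAIRS if p[0] in srcs and p[1] in srcs)
    best = None
    for r in range(len(pairs) + 1):
        for subset in itertools.combinations(pairs, r):
            fit = fit_poisson_loglinear(cells, subset, srcs)
            key = (fit.aic, len(subset), subset)
            if best is None or key < best[0]:
                best = (key, fit)
    return best[1]


def ml_abundance_ci(fit: MLFit, level: float = 0.95) -> tuple[float, float]:
    """Confidence interval for abundance from the log-normal approximation.

    The interval is computed on the log of the estimated unobserved
    count and shifted by the observed total, so it is asymmetric and its
    lower bound never falls below the number of people actually seen.
    A missing-cell estimate of (numerically) zero collapses the interval
    to the observed total, with a warning.
    """
    if not np.isfinite(fit.missing_estimate):
        raise ValueError("cannot form a CI from an unconverged fit")
    if fit.missing_estimate < 0.5 or not np.isfinite(fit.se_log_missing):
        # fewer than half a person predicted unobserved: the boundary case
        # where the interval collapses onto the observed total
        logger.warning("missing-cell estimate ~0; interval degenerate")
        return float(fit.n_observed), float(fit.n_observed)
    z = norm.ppf(0.5 + level / 2.0)
    log_m = np.log(fit.missing_estimate)
    lo = fit.n_observed + np.exp(log_m - z * fit.se_log_missing)
    hi = fit.n_observed + np.exp(log_m + z * fit.se_log_missing)
    return float(lo), float(hi)
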