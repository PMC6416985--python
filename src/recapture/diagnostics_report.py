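"""Dependence diagnostics, prevalence computation and result tables.

Pairwise dependence between the four registries is screened the way
three-source designs do it: pick one registry as the 'population', and
within the people it captured regress capture by one 'sampling' registry
on capture by the other — a single-binary-predictor logistic regression,
whose maximum-likelihood odds ratio is exactly the 2x2 cross-product
ratio.  Four population choices times three sampling pairs give twelve
odds ratios.

Abundance estimates are converted to prevalence against mid-year
general-population denominators and rounded to the nearest hundred for
presentation.
"""

from __future__ import annotations

import importlib.resources
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import SOURCES

logger = logging.getLogger(__name__)


@dataclass
class DependenceResult:
    population: str
    source_a: str
    source_b: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    n: int
    continuity_corrected: bool


def dependence_odds_ratios(
    histories: pd.DataFrame,
    years: tuple[int, int] | None = None,
    per_year: bool = False,
) -> pd.DataFrame:
    """Twelve inter-registry dependence odds ratios with 95% Wald CIs.

    For each population source and each pair of the remaining sources,
    the 2x2 capture table is formed within the population source's
    person-years (pooled over ``years`` unless ``per_year``).  Zero
    cells get a Haldane-Anscombe 0.5 correction, flagged in the output.
    """
    h = histories
    if years is not None:
        h = h[(h["year"] >= years[0]) & (h["year"] <= years[1])]
    groups = h.groupby("year") if per_year else [(None, h)]
    rows = []
    for year, grp in groups:
        for pop in SOURCES:
            inside = grp[grp[pop] == 1]
            others = [s for s in SOURCES if s != pop]
            for i in range(3):
                for j in range(i + 1, 3):
                    sa, sb = others[i], others[j]
                    a = int(((inside[sa] == 1) & (inside[sb] == 1)).sum())
                    b = int(((inside[sa] == 1) & (inside[sb] == 0)).sum())
                    c = int(((inside[sa] == 0) & (inside[sb] == 1)).sum())
                    d = int(((inside[sa] == 0) & (inside[sb] == 0)).sum())
                    corrected = 0 in (a, b, c, d)
                    aa, bb, cc, dd = (
                        (a + 0.5, b + 0.5, c + 0.5, d + 0.5) if corrected else (a, b, c, d)
                    )
                    orr = (aa * dd) / (bb * cc)
                    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
                    z = norm.ppf(0.975)
                    row = {
                        "population": pop,
                        "source_a": sa,
                        "source_b": sb,
                        "odds_ratio": orr,
                        "ci_low": orr * math.exp(-z * se),
                        "ci_high": orr * math.exp(z * se),
                        "n": len(inside),
                        "continuity_corrected": corrected,
                    }
                    if per_year:
                        row["year"] = year
                    rows.append(row)
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# prevalence


@dataclass
class PrevalenceEstimate:
    abundance: float
    denominator: float
    percent: float
    interval_percent: tuple[float, float] | None = None


def prevalence(
    estimate, denominator: float, interval: tuple[float, float] | None = None
) -> PrevalenceEstimate:
    """Prevalence (%) of an abundance estimate against a denominator.

    ``estimate`` may be a number, or any object with a ``median`` (and
    optionally ``hpdi``) or ``abundance`` attribute; interval endpoints
    are transformed identically to the point estimate.
    """
    if denominator is None or not denominator > 0:
        raise ValueError("denominator must be positive")
    n_hat = estimate
    if hasattr(estimate, "median"):
        n_hat = estimate.median
        if interval is None and getattr(estimate, "hpdi", None) is not None:
            interval = estimate.hpdi
    elif hasattr(estimate, "abundance"):
        n_hat = estimate.abundance
    pct = 100.0 * float(n_hat) / denominator
    ipct = None
    if interval is not None:
        ipct = (100.0 * interval[0] / denominator, 100.0 * interval[1] / denominator)
    return PrevalenceEstimate(
        abundance=float(n_hat), denominator=float(denominator), percent=pct,
        interval_percent=ipct,
    )


def round_to_hundred(x: float) -> int:
    """Nearest multiple of 100, halves rounding up; idempotent."""
    if x < 0:
        raise ValueError("x must be non-negative")
    return int(math.floor(x / 100.0 + 0.5) * 100)


def load_denominators(path=None) -> pd.DataFrame:
    """Mid-year general-population denominators by year and age band.

    With no ``path``, loads the packaged synthetic stand-in
    (``denominators_synthetic.csv``): approximate Estonian mid-year
    population figures reconstructed to the nearest thousand, shipped so
    the pipeline runs end to end.  Supply your own CSV (columns
    ``year``, ``age_band``, ``population``) for real analyses.
    """
    if path is None:
        ref = importlib.resources.files("recapture.data").joinpath(
            "denominators_synthetic.csv"
        )
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    required = {"year", "age_band", "population"}
    if not required <= set(df.columns):
        raise ValueError(f"denominator file needs columns {sorted(required)}")
    return df


def denominator_for(denoms: pd.DataFrame, year: int, age_band: str = "15+") -> float:
    sub = denoms[(denoms["year"] == int(year)) & (denoms["age_band"] == age_band)]
    if sub.empty:
        raise ValueError(f"no denominator for year {year}, age band {age_band}")
    return float(sub["population"].iloc[0])


# ----------------------------------------------------------------------
# result assembly and optional plots


def results_table(records: list[dict]) -> pd.DataFrame:
    """Tidy year x variant estimate table from result records.

    Each record needs ``year``, ``variant``, ``estimate`` and interval
    bounds; rounded columns are added for presentation.
    """
    df = pd.DataFrame(records)
    for col in ("estimate", "ci_low", "ci_high"):
        if col in df.columns:
            df[f"{col}_rounded"] = df[col].map(
                lambda v: round_to_hundred(v) if np.isfinite(v) else np.nan
            )
    return df


def plot_estimates(results: pd.DataFrame, path) -> None:
    """Estimate series with intervals, one line per variant (optional)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for variant, grp in results.groupby("variant"):
        grp = grp.sort_values("year")
        ax.plot(grp["year"], grp["estimate"], marker="o", label=str(variant))
        if {"ci_low", "ci_high"} <= set(grp.columns):
            ax.fill_between(grp["year"], grp["ci_low"], grp["ci_high"], alpha=0.15)
    ax.set_xlabel("year")
    ax.set_ylabel("estimated population size")
    ax.legend(title="estimator")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
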