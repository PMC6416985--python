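"""Stratified 2^4 contingency tables with censoring and structural zeros.

Capture histories are aggregated into one count per capture pattern and
covariate stratum.  The all-zero pattern — people captured by no source —
is structurally unobservable and is stored explicitly with a ``missing``
flag rather than omitted, so no stage can mistake it for an observed
zero.  Cells fed only by an over-covered source (PB by default) can be
flagged left-censored: the true member count in such a cell is known
only to be at most the observed count, which is kept as the censoring
bound.

Tables serialise to a long-format CSV, one row per (year, covariates,
pattern, count, flag), the layout used for published capture-frequency
supplements, so externally supplied frequency tables can be ingested
directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AGE_GROUPS, COUNTIES, SEXES, SOURCES

logger = logging.getLogger(__name__)

COVARIATE_LEVELS = {
    "sex": SEXES,
    "age_group": AGE_GROUPS,
    "county": COUNTIES,
}

FLAG_OBSERVED = "observed"
FLAG_CENSORED = "censored"
FLAG_MISSING = "missing"


@dataclass
class StratifiedContingencyTable:
    """Counts per (capture pattern x covariate stratum) for one year.

    ``cells`` has one row per cell with the four source indicator
    columns, any stratification columns, ``count`` (NaN for the missing
    cell) and ``flag``.  For censored cells ``count`` holds the
    censoring bound (the observed, possibly contaminated, count).
    """

    year: int | None
    strata: tuple[str, ...]
    cells: pd.DataFrame
    age_band: str = "15+"

    def __post_init__(self) -> None:
        n_strata = self.n_strata
        if len(self.cells) != 16 * n_strata:
            raise ValueError(
                f"expected {16 * n_strata} cells, got {len(self.cells)}"
            )
        counts = self.cells.loc[self.cells["flag"] != FLAG_MISSING, "count"]
        if (counts < 0).any() or (counts != counts.round()).any():
            raise ValueError("cell counts must be non-negative integers")
        zero = self.cells[list(SOURCES)].sum(axis=1) == 0
        if not (self.cells.loc[zero, "flag"] == FLAG_MISSING).all():
            raise ValueError("the all-zero pattern must be flagged missing")

    @property
    def n_strata(self) -> int:
        n = 1
        for cov in self.strata:
            n *= len(COVARIATE_LEVELS[cov])
        return n

    @property
    def observed_total(self) -> int:
        obs = self.cells["flag"] != FLAG_MISSING
        return int(self.cells.loc[obs, "count"].sum())

    def source_margin(self, source: str) -> int:
        obs = self.cells["flag"] != FLAG_MISSING
        return int((self.cells.loc[obs, "count"] * self.cells.loc[obs, source]).sum())

    def collapse(self) -> "StratifiedContingencyTable":
        """Sum out the covariate strata, keeping flags consistent."""
        if not self.strata:
            return self
        grouped = (
            self.cells.groupby(list(SOURCES), sort=False)["count"].sum().reset_index()
        )
        out = _empty_grid(())
        merged = out.drop(columns="count").merge(grouped, on=list(SOURCES), how="left")
        merged.loc[merged[list(SOURCES)].sum(axis=1) == 0, "count"] = np.nan
        censored = self.cells.loc[self.cells["flag"] == FLAG_CENSORED, list(SOURCES)]
        merged["flag"] = FLAG_OBSERVED
        merged.loc[merged[list(SOURCES)].sum(axis=1) == 0, "flag"] = FLAG_MISSING
        if len(censored):
            pat = censored.drop_duplicates()
            key = merged[list(SOURCES)].apply(tuple, axis=1)
            cens_keys = set(pat.apply(tuple, axis=1))
            merged.loc[key.isin(cens_keys), "flag"] = FLAG_CENSORED
        return StratifiedContingencyTable(
            year=self.year, strata=(), cells=merged, age_band=self.age_band
        )


def _empty_grid(strata: tuple[str, ...]) -> pd.DataFrame:
    """Full cross product of strata levels and the 16 patterns, counts 0."""
    pieces = [pd.DataFrame({cov: list(COVARIATE_LEVELS[cov])}) for cov in strata]
    patterns = pd.DataFrame(
        [[(p >> i) & 1 for i in range(4)] for p in range(16)], columns=list(SOURCES)
    )
    grid = patterns
    for piece in reversed(pieces):
        grid = piece.merge(grid, how="cross")
    grid = grid.copy()
    grid["count"] = 0.0
    grid["flag"] = FLAG_OBSERVED
    grid.loc[grid[list(SOURCES)].sum(axis=1) == 0, "count"] = np.nan
    grid.loc[grid[list(SOURCES)].sum(axis=1) == 0, "flag"] = FLAG_MISSING
    return grid


def build_contingency_table(
    histories: pd.DataFrame,
    year: int,
    strata_spec: tuple[str, ...] | None = None,
    age_band: str = "15+",
) -> StratifiedContingencyTable:
    """Aggregate capture histories for one year into a contingency table.

    Parameters
    ----------
    histories
        Output of :func:`recapture.linkage.link_records`.
    year
        Calendar year to tabulate.
    strata_spec
        ``None`` for a plain 16-cell table, or a tuple of covariate names
        (maximally ``("sex", "age_group", "county")`` giving 12 strata of
        16 cells each).
    age_band
        ``"15+"`` (all adults) or ``"15-44"``.

    Histories with covariate values outside the known levels are rejected
    and logged.  Counts of retained histories are conserved exactly.
    """
    strata = tuple(strata_spec) if strata_spec else ()
    for cov in strata:
        if cov not in COVARIATE_LEVELS:
            raise ValueError(f"unknown covariate {cov!r}")
    if age_band not in ("15+", "15-44"):
        raise ValueError("age_band must be '15+' or '15-44'")
    h = histories[histories["year"] == int(year)].copy()
    h = h[h["age_midyear"] >= 15]
    if age_band == "15-44":
        h = h[h["age_midyear"] <= 44]
    for cov in strata:
        bad = ~h[cov].isin(COVARIATE_LEVELS[cov])
        if bad.any():
            logger.warning(
                "rejecting %d histories with unknown %s values", int(bad.sum()), cov
            )
            h = h[~bad]
    grid = _empty_grid(strata)
    if len(h):
        counts = (
            h.groupby(list(strata) + list(SOURCES), sort=False)
            .size()
            .rename("n")
            .reset_index()
        )
        grid = grid.merge(counts, on=list(strata) + list(SOURCES), how="left")
        grid["count"] = np.where(
            grid["flag"] == FLAG_MISSING, np.nan, grid["count"] + grid["n"].fillna(0.0)
        )
        grid = grid.drop(columns="n")
    table = StratifiedContingencyTable(
        year=int(year), strata=strata, cells=grid, age_band=age_band
    )
    assert table.observed_total == len(h)
    return table


def mark_censored_cells(
    table: StratifiedContingencyTable, source: str = "PB"
) -> StratifiedContingencyTable:
    """Flag every ``source``-only cell (per stratum) as left-censored.

    The censoring bound is the observed count itself; a bound of zero
    degenerately forces the true count to zero.
    """
    if source not in SOURCES:
        raise ValueError(f"unknown source {source!r}")
    cells = table.cells.copy()
    others = [s for s in SOURCES if s != source]
    only = (cells[source] == 1) & (cells[others].sum(axis=1) == 0)
    cells.loc[only, "flag"] = FLAG_CENSORED
    return StratifiedContingencyTable(
        year=table.year, strata=table.strata, cells=cells, age_band=table.age_band
    )


# ----------------------------------------------------------------------
# serialisation


def write_table(table: StratifiedContingencyTable, path: str | Path) -> None:
    df = table.cells.copy()
    df.insert(0, "year", table.year)
    df.insert(1, "age_band", table.age_band)
    df.to_csv(path, index=False)


def read_table(path: str | Path) -> StratifiedContingencyTable:
    df = pd.read_csv(path)
    year = int(df["year"].iloc[0]) if df["year"].notna().all() else None
    age_band = str(df["age_band"].iloc[0]) if "age_band" in df.columns else "15+"
    strata = tuple(c for c in ("sex", "age_group", "county") if c in df.columns)
    cells = df.drop(columns=[c for c in ("year", "age_band") if c in df.columns])
    return StratifiedContingencyTable(
        year=year, strata=strata, cells=cells.reset_index(drop=True), age_band=age_band
    )


_ALIASES = {
    "year": "year",
    "sex": "sex",
    "gender": "sex",
    "age_group": "age_group",
    "age group": "age_group",
    "agegroup": "age_group",
    "county": "county",
    "county of residence": "county",
    "dr": "DR",
    "pb": "PB",
    "hif-t": "HIF-T",
    "hif_t": "HIF-T",
    "hift": "HIF-T",
    "hif-f": "HIF-F",
    "hif_f": "HIF-F",
    "hiff": "HIF-F",
    "count": "count",
    "frequency": "count",
    "freq": "count",
    "n": "count",
}


def read_capture_frequencies(path: str | Path) -> pd.DataFrame:
    """Ingest an externally published capture-frequency file.

    Accepts a CSV export of a frequency supplement laid out one row per
    (year, gender, age group, county, four registry indicators, count);
    column names are matched case-insensitively against common aliases.
    Returns a long DataFrame in canonical column names, from which
    :func:`table_from_frequencies` builds per-year tables.
    """
    df = pd.read_csv(path)
    renames = {}
    for col in df.columns:
        key = str(col).strip().lower()
        if key in _ALIASES:
            renames[col] = _ALIASES[key]
    df = df.rename(columns=renames)
    required = {"year", *SOURCES, "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"frequency file lacks columns: {sorted(missing)}")
    return df


def table_from_frequencies(
    freq: pd.DataFrame,
    year: int,
    strata_spec: tuple[str, ...] | None = None,
    filter_under15: bool = False,
) -> StratifiedContingencyTable:
    """Build a table for one year from ingested capture frequencies.

    ``filter_under15`` drops rows whose age-group column marks ages under
    15, for files to which the exclusion has not yet been applied.
    """
    strata = tuple(strata_spec) if strata_spec else ()
    sub = freq[freq["year"] == int(year)].copy()
    if filter_under15 and "age_group" in sub.columns:
        sub = sub[~sub["age_group"].astype(str).str.contains("<\\s*15|under", case=False)]
    grid = _empty_grid(strata)
    keys = list(strata) + list(SOURCES)
    counts = sub.groupby(keys, sort=False)["count"].sum().reset_index()
    grid = grid.merge(counts, on=keys, how="left", suffixes=("", "_in"))
    grid["count"] = np.where(
        grid["flag"] == FLAG_MISSING, np.nan, grid["count"] + grid["count_in"].fillna(0.0)
    )
    grid = grid.drop(columns="count_in")
    return StratifiedContingencyTable(year=int(year), strata=strata, cells=grid)
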