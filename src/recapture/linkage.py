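"""Deterministic record linkage of the four registry extracts.

Records are linked by a composite study ID built from date of birth, sex
and initials.  For each calendar year the linked data yield one capture
history per person: four binary indicators (DR, PB, HIF-T, HIF-F),
mid-year age with the under-15 exclusion, and county of residence set by
the first appearance of the person in any registry that year.

Two registries (DR, PB) carry a registry-internal person identifier, so
distinct people sharing a study ID are distinguishable there; exactly one
of them is cross-linked to the other sources (the one with the earliest
event date, ties broken by internal ID), while the others still count in
their own source's totals.  The insurance registries have no internal
identifier, so study-ID collisions there collapse to one person — a
known limitation of the linkage design.

Events dated after a linked person's death are dropped with a warning,
and no capture history is produced for years after the death year.
"""

from __future__ import annotations

import datetime as dt
import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .config import COUNTIES, SOURCES

logger = logging.getLogger(__name__)

#: tie-break priority when several same-day records disagree on county
SOURCE_PRIORITY = {src: rank for rank, src in enumerate(SOURCES)}

HISTORY_COLUMNS = [
    "study_id",
    "year",
    *SOURCES,
    "age_midyear",
    "age_group",
    "sex",
    "county",
]


def make_study_id(dob, sex: str, initials: str) -> str:
    """Canonical composite identifier ``YYYYMMDD_S_II``.

    Case- and whitespace-insensitive in the initials; sex is normalised
    to ``M``/``F``.  Raises ``ValueError`` on a missing or unparseable
    field (such records are rejected upstream and logged).
    """
    if dob is None or (isinstance(dob, float) and np.isnan(dob)):
        raise ValueError("missing date of birth")
    if isinstance(dob, str):
        dob = dt.date.fromisoformat(dob.strip())
    elif isinstance(dob, pd.Timestamp):
        dob = dob.date()
    elif not isinstance(dob, dt.date):
        raise ValueError(f"unparseable date of birth: {dob!r}")
    if not isinstance(sex, str) or sex.strip().upper()[:1] not in ("M", "F"):
        raise ValueError(f"missing or invalid sex: {sex!r}")
    if not isinstance(initials, str) or not initials.strip():
        raise ValueError("missing initials")
    return f"{dob.strftime('%Y%m%d')}_{sex.strip().upper()[0]}_{initials.strip().upper()}"


def compute_age_midyear(dob, year: int) -> tuple[int, str]:
    """Completed years of age at July 1 of ``year`` and the age group.

    Returns ``(age, group)`` with group in ``{"<15", "15-44", "45+"}``;
    person-years with group ``"<15"`` are excluded from tabulation.
    Raises ``ValueError`` if the date of birth is after mid-year.
    """
    if isinstance(dob, str):
        dob = dt.date.fromisoformat(dob)
    elif isinstance(dob, pd.Timestamp):
        dob = dob.date()
    mid = dt.date(int(year), 7, 1)
    if dob > mid:
        raise ValueError(f"date of birth {dob} after mid-year {mid}")
    age = mid.year - dob.year - ((mid.month, mid.day) < (dob.month, dob.day))
    group = "<15" if age < 15 else ("15-44" if age <= 44 else "45+")
    return age, group


def canonical_county(raw) -> str | None:
    """Map a raw county name onto the 3-level factor Harju/Ida-Viru/other."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    name = str(raw).strip()
    if not name:
        return None
    return name if name in COUNTIES[:2] else "other"


def assign_county(records: pd.DataFrame) -> str:
    """County of the earliest-dated record of the year for one person.

    ``records`` needs columns ``event_date``, ``county`` and ``source``.
    Same-day ties are broken by a fixed source priority DR > PB > HIF-T >
    HIF-F; a missing county on the winning record falls back to the next
    record in order (logged).
    """
    if records.empty:
        raise ValueError("no records for county assignment")
    recs = records.copy()
    recs["_prio"] = recs["source"].map(SOURCE_PRIORITY)
    recs = recs.sort_values(["event_date", "_prio"], kind="stable")
    for _, row in recs.iterrows():
        county = canonical_county(row["county"])
        if county is not None:
            return county
    logger.warning("no usable county for one person-year; assigning 'other'")
    return "other"


# ----------------------------------------------------------------------


def _normalise_extract(df: pd.DataFrame, source: str) -> pd.DataFrame:
    """Parse dates, build study IDs, reject and log incomplete records."""
    recs = df.copy()
    recs["source"] = source
    if "internal_id" not in recs.columns:
        recs["internal_id"] = None
    ids = []
    keep = []
    for i, row in enumerate(recs.itertuples(index=False)):
        try:
            ids.append(make_study_id(row.dob, row.sex, row.initials))
            keep.append(i)
        except ValueError as err:
            logger.warning("%s: rejected record (%s)", source, err)
    recs = recs.iloc[keep].copy()
    recs["study_id"] = ids
    recs["event_date"] = pd.to_datetime(recs["event_date"]).dt.date
    recs["dob"] = pd.to_datetime(recs["dob"]).dt.date
    return recs


def _split_duplicate_identities(recs: pd.DataFrame, source: str) -> pd.DataFrame:
    """Resolve study-ID collisions in a source with internal identifiers.

    When two or more internal IDs share a study ID, the person with the
    earliest event (ties by internal ID) keeps the study ID and is the
    only one cross-linked; the others receive a source-local pseudo-ID so
    that they still count in this source's totals but never link.
    """
    if recs["internal_id"].isna().all():
        return recs
    recs = recs.copy()
    first = (
        recs.groupby(["study_id", "internal_id"], sort=True)["event_date"]
        .min()
        .reset_index()
        .sort_values(["study_id", "event_date", "internal_id"], kind="stable")
    )
    linked = first.groupby("study_id", sort=False)["internal_id"].first()
    n_dup = int((first.groupby("study_id")["internal_id"].nunique() > 1).sum())
    if n_dup:
        logger.info("%s: %d study IDs shared by more than one person", source, n_dup)
    is_linked = recs["internal_id"].to_numpy() == linked.loc[recs["study_id"]].to_numpy()
    recs.loc[~is_linked, "study_id"] = (
        recs.loc[~is_linked, "study_id"] + "#" + recs.loc[~is_linked, "internal_id"].astype(str)
    )
    recs.loc[~is_linked, "_local_only"] = True
    return recs


def link_records(
    extracts: Mapping[str, pd.DataFrame],
    years: Iterable[int] | None = None,
) -> pd.DataFrame:
    """Link the four extracts into one capture history per person-year.

    Parameters
    ----------
    extracts
        Mapping source name -> extract with columns ``dob``, ``sex``,
        ``initials``, ``event_date``, ``county`` and (DR, PB) ``internal_id``.
    years
        Calendar years to link; defaults to every year present.

    Returns
    -------
    DataFrame with one row per (study_id, year): the four capture
    indicators, mid-year age and age group, sex and assigned county.
    Person-years younger than 15 at mid-year are excluded (logged), as
    are events after a linked person's death and entire person-years
    after the death year.
    """
    unknown = set(extracts) - set(SOURCES)
    if unknown:
        raise ValueError(f"unknown sources: {sorted(unknown)}")
    frames = []
    for src in SOURCES:
        df = extracts.get(src)
        if df is None or df.empty:
            continue
        recs = _normalise_extract(df, src)
        if src in ("DR", "PB"):
            recs = _split_duplicate_identities(recs, src)
        frames.append(recs)
    if not frames:
        return pd.DataFrame(columns=HISTORY_COLUMNS)
    recs = pd.concat(frames, ignore_index=True)

    # death ordering: the linked DR person defines the death date
    deaths = (
        recs.loc[(recs["source"] == "DR") & ~recs["study_id"].str.contains("#"), :]
        .groupby("study_id")["event_date"]
        .min()
    )
    death = recs["study_id"].map(deaths)
    after_death = death.notna() & (recs["event_date"] > death)
    if after_death.any():
        logger.warning(
            "dropping %d events dated after the linked person's death",
            int(after_death.sum()),
        )
        recs = recs.loc[~after_death]

    recs = recs.copy()
    recs["year"] = pd.to_datetime(recs["event_date"]).dt.year
    if years is not None:
        years = [int(y) for y in years]
        recs = recs[recs["year"].isin(years)]

    rows = []
    n_underage = 0
    for (study_id, year), grp in recs.groupby(["study_id", "year"], sort=True):
        dob = grp["dob"].iloc[0]
        sex = grp["sex"].iloc[0]
        try:
            age, age_group = compute_age_midyear(dob, year)
        except ValueError as err:
            logger.warning("rejected person-year %s/%s: %s", study_id, year, err)
            continue
        if age_group == "<15":
            n_underage += 1
            continue
        pattern = {src: int((grp["source"] == src).any()) for src in SOURCES}
        rows.append(
            {
                "study_id": study_id,
                "year": int(year),
                **pattern,
                "age_midyear": age,
                "age_group": age_group,
                "sex": str(sex).strip().upper()[0],
                "county": assign_county(grp),
            }
        )
    if n_underage:
        logger.info("excluded %d person-years younger than 15 at mid-year", n_underage)
    out = pd.DataFrame(rows, columns=HISTORY_COLUMNS)
    assert (out[list(SOURCES)].sum(axis=1) > 0).all() if len(out) else True
    return out


def histories_from_truth(truth: pd.DataFrame) -> pd.DataFrame:
    """Capture histories taken directly from simulation truth.

    Bypasses study-ID linkage (useful for estimator tests where linkage
    noise is not under study).  Uncaptured person-years are dropped, as
    is anyone younger than 15 at mid-year.
    """
    t = truth.copy()
    t = t[t[list(SOURCES)].sum(axis=1) > 0]
    t = t[t["age_midyear"] >= 15]
    out = pd.DataFrame(
        {
            "study_id": t["person_id"].astype(str),
            "year": t["year"].astype(int),
            **{src: t[src].astype(int) for src in SOURCES},
            "age_midyear": t["age_midyear"].astype(int),
            "age_group": t["age_group"],
            "sex": t["sex"],
            "county": t["county"],
        }
    )
    return out.reset_index(drop=True)
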